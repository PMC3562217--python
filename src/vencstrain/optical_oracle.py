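"""Independent strain measurement from grid-marked video.

Replicates an optical validation pipeline for deforming specimens marked
with a regular grid of pen dots: every video frame is matched-filtered
with a dot-sized template, each point is predicted from its previous
position (plus any known rig motion) and snapped to the nearest local
maximum of the filtered image, the sparse dot displacements are up-sampled
by cubic interpolation to a dense regular displacement field, and the
strain tensor follows by numerical differentiation.

This pipeline is the package's independent gold standard: it shares no
code with the velocity-tracking strain path except the Green-Lagrange
formula itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.signal import fftconvolve

from .strain import green_lagrange  # the shared tensor formula, nothing else

__all__ = [
    "GridTrajectories",
    "DenseDisplacement",
    "matched_filter_response",
    "find_grid_points",
    "track_grid_points",
    "dense_displacement",
    "strain_from_displacement",
    "optical_strain_pipeline",
]


class OpticalError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# matched filtering
# --------------------------------------------------------------------------


def _dot_template(dot_size_px: float) -> np.ndarray:
    """Antialiased disk template of the given diameter, zero-mean, unit norm."""
    r = dot_size_px / 2.0
    n = int(np.ceil(r)) * 2 + 3
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    cover = np.clip(r - np.hypot(xx - c, yy - c) + 0.5, 0.0, 1.0)
    t = cover - cover.mean()
    return t / np.linalg.norm(t)


def matched_filter_response(frame: np.ndarray, dot_size_px: float = 8.0) -> np.ndarray:
    """Correlate a frame with a dot-sized template; maxima sit at dot centers.

    The template is a zero-mean normalized disk of the given diameter;
    dots are assumed dark on a light background, so the frame is negated
    before correlation.  A blank (constant) frame gives zero response.
    """
    frame = np.asarray(frame, dtype=float)
    if dot_size_px < 2:
        raise ValueError("dot size must be at least 2 px")
    t = _dot_template(dot_size_px)
    if t.shape[0] > min(frame.shape):
        raise ValueError("dot size larger than the image")
    return fftconvolve(-(frame - frame.mean()), t[::-1, ::-1], mode="same")


def _quadratic_subpixel(resp: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Separable 1D quadratic peak refinement around an integer maximum."""

    def refine(vm, v0, vp):
        denom = vm - 2 * v0 + vp
        if denom >= 0:  # not a maximum; stay put
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    dr = dc = 0.0
    if 0 < r < resp.shape[0] - 1:
        dr = refine(resp[r - 1, c], resp[r, c], resp[r + 1, c])
    if 0 < c < resp.shape[1] - 1:
        dc = refine(resp[r, c - 1], resp[r, c], resp[r, c + 1])
    return dr, dc


def find_grid_points(
    response: np.ndarray, threshold: float, min_distance: int = 5
) -> np.ndarray:
    """Detect dot centers: response local maxima above a threshold.

    A helper for initializing tracking on real video (with simulated video
    the exact reference dot positions are available instead).  Returns
    (K, 2) positions as (x, y) with sub-pixel refinement.
    """
    footprint = np.ones((2 * min_distance + 1,) * 2, dtype=bool)
    is_max = (response == ndimage.maximum_filter(response, footprint=footprint)) & (
        response > threshold
    )
    rows, cols = np.nonzero(is_max)
    out = []
    for r, c in zip(rows, cols):
        dr, dc = _quadratic_subpixel(response, r, c)
        out.append((c + dc, r + dr))
    return np.asarray(out, dtype=float).reshape(-1, 2)


# --------------------------------------------------------------------------
# point tracking
# --------------------------------------------------------------------------


@dataclass
class GridTrajectories:
    """Per-frame positions of each grid dot (px; x = column, y = row)."""

    points: np.ndarray  # (T, K, 2)
    valid: np.ndarray  # (T, K) bool
    mm_per_px: float | None = None

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        t, k = self.points.shape[:2]
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(t), k),
                "point": np.tile(np.arange(k), t),
                "x_px": self.points[..., 0].ravel(),
                "y_px": self.points[..., 1].ravel(),
                "valid": self.valid.ravel(),
            }
        )


def _snap_to_maximum(
    response: np.ndarray,
    predicted: np.ndarray,
    radius: float,
    refine: bool,
    min_peak: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    h, w = response.shape
    x0, y0 = predicted
    c0 = int(round(np.clip(x0, 0, w - 1)))
    r0 = int(round(np.clip(y0, 0, h - 1)))
    rad = int(np.ceil(radius))
    rs = slice(max(0, r0 - rad), min(h, r0 + rad + 1))
    cs = slice(max(0, c0 - rad), min(w, c0 + rad + 1))
    win = response[rs, cs]
    if win.size == 0:
        return predicted, False
    yy, xx = np.mgrid[rs, cs]
    mask = np.hypot(xx - x0, yy - y0) <= radius
    if not mask.any():
        return predicted, False
    masked = np.where(mask, win, -np.inf)
    if masked.max() <= min_peak:  # no dot-like maximum in reach
        return predicted, False
    r, c = np.unravel_index(int(np.argmax(masked)), masked.shape)
    r += rs.start
    c += cs.start
    if refine:
        dr, dc = _quadratic_subpixel(response, r, c)
        return np.array([c + dc, r + dr]), True
    return np.array([float(c), float(r)]), True


def track_grid_points(
    frames: np.ndarray,
    initial_points: np.ndarray,
    motion_prior: np.ndarray | None = None,
    dot_size_px: float = 8.0,
    search_radius: float | None = None,
    refine_subpixel: bool = True,
) -> GridTrajectories:
    """Track grid dots through a video by predict-and-snap.

    Each point's position is predicted from its position in the previous
    frame plus the ``motion_prior`` displacement (knowledge of the rig
    motion; zero if omitted), then moved to the nearest local maximum of
    the matched-filter response within ``search_radius`` px (default: one
    dot diameter); with ``refine_subpixel`` the maximum is refined by a
    quadratic fit (switch off for strict pixel snapping).  Points with no
    maximum in reach are marked invalid and frozen.
    """
    frames = np.asarray(frames, dtype=float)
    pts0 = np.atleast_2d(np.asarray(initial_points, dtype=float))
    t_frames, k = frames.shape[0], pts0.shape[0]
    if search_radius is None:
        search_radius = float(dot_size_px)
    if motion_prior is None:
        prior = np.zeros((t_frames, k, 2))
    else:
        prior = np.broadcast_to(
            np.asarray(motion_prior, dtype=float).reshape(t_frames, -1, 2), (t_frames, k, 2)
        )
    points = np.zeros((t_frames, k, 2))
    valid = np.ones((t_frames, k), dtype=bool)
    prev = pts0.copy()
    for t in range(t_frames):
        resp = matched_filter_response(frames[t], dot_size_px)
        pred = prev + prior[t] if t > 0 else prev
        for i in range(k):
            snapped, ok = _snap_to_maximum(resp, pred[i], search_radius, refine_subpixel)
            points[t, i] = snapped if ok else pred[i]
            valid[t, i] = ok
        prev = points[t]
    return GridTrajectories(points=points, valid=valid)


# --------------------------------------------------------------------------
# dense displacement and strain
# --------------------------------------------------------------------------


@dataclass
class DenseDisplacement:
    """Displacement field on a regular grid in the reference frame (px)."""

    grid_x: np.ndarray  # (W',)
    grid_y: np.ndarray  # (H',)
    u: np.ndarray  # (H', W', 2) displacement, px
    valid: np.ndarray  # (H', W') bool (inside the dot hull)


def dense_displacement(
    trajectories: GridTrajectories,
    frame: int,
    reference_frame: int = 0,
    grid_step_px: float = 4.0,
) -> DenseDisplacement:
    """Up-sample sparse dot displacements to a dense regular field.

    Displacements ``u = position(frame) - position(reference)`` at the dot
    locations are interpolated with a C1 cubic (Clough-Tocher) scheme onto
    a regular grid over the reference dot hull; cubic interpolation
    reproduces affine fields exactly and is marked invalid outside the
    hull (no extrapolation).
    """
    ok = trajectories.valid[frame] & trajectories.valid[reference_frame]
    if ok.sum() < 16:
        raise OpticalError("too few valid points: need at least a 4x4 grid")
    ref = trajectories.points[reference_frame, ok]
    u = trajectories.points[frame, ok] - ref
    xmin, ymin = ref.min(axis=0)
    xmax, ymax = ref.max(axis=0)
    gx = np.arange(xmin, xmax + 1e-9, grid_step_px)
    gy = np.arange(ymin, ymax + 1e-9, grid_step_px)
    xx, yy = np.meshgrid(gx, gy)
    interp = CloughTocher2DInterpolator(ref, u, fill_value=np.nan)
    dense = interp(np.column_stack([xx.ravel(), yy.ravel()])).reshape(len(gy), len(gx), 2)
    valid = np.isfinite(dense[..., 0]) & np.isfinite(dense[..., 1])
    return DenseDisplacement(grid_x=gx, grid_y=gy, u=dense, valid=valid)


def strain_from_displacement(
    dense: DenseDisplacement, long_axis: tuple[float, float] = (0.0, 1.0)
) -> dict:
    """Strain tensor field from a dense displacement field.

    ``F = I + du/dX`` by central differences on the regular grid;
    ``E = (F^T F - I)/2``; the longitudinal direction (e.g. the phantom
    limb axis) must be supplied.  Returns a dict with ``F``, ``E``,
    ``e_long`` and a validity mask (cells touching the hull boundary are
    masked out).
    """
    if not dense.valid.any():
        raise OpticalError("dense field has no valid region")
    u = np.where(dense.valid[..., None], dense.u, np.nan)
    du = np.stack(np.gradient(u, dense.grid_y, dense.grid_x, axis=(0, 1)), axis=-1)
    # du[..., i, j] = d u_i / d X_j with X = (y, x); reorder to (x, y)
    grad = np.empty(u.shape[:2] + (2, 2))
    grad[..., 0, 0] = du[..., 0, 1]  # du_x/dx
    grad[..., 0, 1] = du[..., 0, 0]  # du_x/dy
    grad[..., 1, 0] = du[..., 1, 1]  # du_y/dx
    grad[..., 1, 1] = du[..., 1, 0]  # du_y/dy
    f = np.eye(2) + grad
    valid = np.all(np.isfinite(grad), axis=(-2, -1))
    f = np.where(valid[..., None, None], f, np.nan)
    e = green_lagrange(f)
    d = np.asarray(long_axis, dtype=float)
    d = d / np.linalg.norm(d)
    e_long = np.einsum("i,...ij,j->...", d, e, d)
    return {"F": f, "E": e, "e_long": e_long, "valid": valid}


def optical_strain_pipeline(
    frames: np.ndarray,
    initial_points: np.ndarray,
    mm_per_px: float,
    rois_mm: dict[str, tuple[float, float, float, float]],
    long_axis: tuple[float, float] = (0.0, 1.0),
    reference_frame: int = 0,
    dot_size_px: float = 8.0,
    motion_prior: np.ndarray | None = None,
    grid_step_px: float = 4.0,
    search_radius: float | None = None,
) -> pd.DataFrame:
    """Full optical pipeline: track, up-sample, differentiate, ROI-average.

    ``rois_mm`` maps ROI names to ``(x0, y0, x1, y1)`` rectangles in mm
    (reference configuration).  Returns a tidy frame/roi/strain table of
    mean longitudinal strain per ROI per timeframe.
    """
    traj = track_grid_points(
        frames,
        initial_points,
        motion_prior=motion_prior,
        dot_size_px=dot_size_px,
        search_radius=search_radius,
    )
    traj.mm_per_px = mm_per_px
    rows = []
    for t in range(traj.n_frames):
        dense = dense_displacement(
            traj, t, reference_frame=reference_frame, grid_step_px=grid_step_px
        )
        strain = strain_from_displacement(dense, long_axis=long_axis)
        xx, yy = np.meshgrid(dense.grid_x, dense.grid_y)
        for name, (x0, y0, x1, y1) in rois_mm.items():
            sel = (
                (xx * mm_per_px >= x0)
                & (xx * mm_per_px <= x1)
                & (yy * mm_per_px >= y0)
                & (yy * mm_per_px <= y1)
                & strain["valid"]
            )
            val = float(np.nanmean(strain["e_long"][sel])) if sel.any() else np.nan
            rows.append({"frame": t, "roi": name, "e_long": val})
    return pd.DataFrame(rows)
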