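"""Velocity-driven tracking of the myocardial model through the cycle.

The in-plane deformation rate is modelled as a weighted sum of a small set
of local basis functions distributed along the myocardial centerline
(default 7).  At each timeframe the 2D coefficient of every basis function
is found by linear least squares against the measured velocity sampled at
the current (Lagrangian) positions of the material points, with

* a smoothness penalty on differences between neighboring basis
  coefficients (a discrete surrogate for a diffusion-type regularizer),
* an optional correction term pulling chosen boundary nodes toward
  manually placed target positions.

Tracked points are then advected with the fitted velocity field and the
process repeats for every frame of the cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import MyocardialModel, interior_displacement, polyline_arclength_coordinate
from .pc_io import CorrectionPoint, VelocityCineSeries

log = logging.getLogger(__name__)

__all__ = [
    "BasisSet",
    "DeformationTrajectory",
    "build_basis",
    "fit_frame_coefficients",
    "advect",
    "track_cycle",
    "closure_error",
    "sample_velocity",
]

#: unit conversion: velocity [cm/s] x time [ms] -> displacement [mm]
MM_PER_CMS_MS = 0.01


class TrackingError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# basis
# --------------------------------------------------------------------------


@dataclass
class BasisSet:
    """Local basis functions along the reference centerline.

    Each basis is a compactly supported bump in arc-length distance along
    the centerline: a piecewise-linear "hat" of half-width one center
    spacing, with centers equally distributed at ``s = k / (n_basis - 1)``
    so the first and last basis sit on the band's basal ends.  The hats
    form an exact partition of unity with *linear precision*: constant and
    uniform-strain (linear-in-arc-length) velocity profiles are
    represented exactly, and each coefficient only influences its two
    neighboring inter-center cells — the sharpest localization a
    partition-of-unity family allows.
    """

    n_basis: int
    centers_s: np.ndarray  # (n,)
    centers_xy: np.ndarray  # (n, 2)
    width_mm: float  # center spacing along the centerline
    centerline: np.ndarray  # reference centerline polyline
    centerline_length: float

    def weights_from_s(self, s: np.ndarray) -> np.ndarray:
        """Partition-of-unity weights (N, n_basis) at arc-length positions."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        delta = self.centers_s[1] - self.centers_s[0]
        w = np.clip(1.0 - np.abs(s[:, None] - self.centers_s[None, :]) / delta, 0.0, None)
        return w / w.sum(axis=1, keepdims=True)

    def weights_at_points(self, points: np.ndarray) -> np.ndarray:
        """Weights at spatial positions: evaluated through the arc-length
        coordinate of each point's nearest foot on the reference centerline."""
        s = polyline_arclength_coordinate(self.centerline, points)
        return self.weights_from_s(s)


def build_basis(model: MyocardialModel, n_basis: int = 7) -> BasisSet:
    """Distribute ``n_basis`` local basis functions equally along the centerline."""
    if n_basis < 2:
        raise ValueError("n_basis must be at least 2")
    centers_s = np.arange(n_basis) / (n_basis - 1)
    length = model.centerline_length
    centers_xy = np.column_stack(
        [np.interp(centers_s, model.centerline_s, model.centerline[:, k]) for k in range(2)]
    )
    return BasisSet(
        n_basis=n_basis,
        centers_s=centers_s,
        centers_xy=centers_xy,
        width_mm=length / (n_basis - 1),
        centerline=model.centerline,
        centerline_length=length,
    )


def _chain_laplacian(n: int) -> np.ndarray:
    lap = np.zeros((n, n))
    idx = np.arange(n - 1)
    lap[idx, idx] += 1
    lap[idx + 1, idx + 1] += 1
    lap[idx, idx + 1] -= 1
    lap[idx + 1, idx] -= 1
    return lap


# --------------------------------------------------------------------------
# sampling and fitting
# --------------------------------------------------------------------------


def sample_velocity(
    series: VelocityCineSeries, frame: int, positions_mm: np.ndarray
) -> np.ndarray:
    """Bilinear sample of both velocity components at positions (mm).

    Positions outside the image are clamped to the border (and logged).
    Returns an (N, 2) array in cm/s.
    """
    dx, dy = series.pixel_spacing
    pos = np.atleast_2d(positions_mm)
    cols = pos[:, 0] / dx
    rows = pos[:, 1] / dy
    nrow, ncol = series.shape
    outside = (cols < 0) | (cols > ncol - 1) | (rows < 0) | (rows > nrow - 1)
    if np.any(outside):
        log.warning(
            "%d tracked point(s) left the image bounds at frame %d; sampling clamped",
            int(outside.sum()),
            frame,
        )
    coords = np.vstack([rows, cols])
    vx = ndimage.map_coordinates(series.velocity_x[frame], coords, order=1, mode="nearest")
    vy = ndimage.map_coordinates(series.velocity_y[frame], coords, order=1, mode="nearest")
    return np.column_stack([vx, vy])


def fit_frame_coefficients(
    series: VelocityCineSeries,
    frame: int,
    positions: np.ndarray,
    basis: BasisSet,
    corrections: tuple[CorrectionPoint, ...] = (),
    boundary_positions: np.ndarray | None = None,
    dt: float | None = None,
    lam_smooth: float = 0.003,
    lam_corr: float = 10.0,
) -> tuple[np.ndarray, float]:
    """Fit per-basis 2D velocity coefficients for one frame.

    Minimizes, in closed form (normal equations),

        J(a) = sum_x ||v_meas(x) - sum_i a_i phi_i(x)||^2
             + lam_smooth * sum_{i~j} ||a_i - a_j||^2
             + lam_corr * sum_k ||p_node_k + dt * v_fit(p_node_k) - p_corr_k||^2

    where ``x`` ranges over the current positions of the tracked material
    points, neighbor pairs ``i~j`` are adjacent basis functions along the
    centerline, and the correction term applies only at frames with
    correction points.  Both penalty weights are made dimensionless by
    scaling with the mean diagonal of the data normal matrix.

    Returns ``(coefficients (n_basis, 2), residual RMS in cm/s)``.
    """
    positions = np.atleast_2d(positions)
    if positions.shape[0] == 0:
        raise TrackingError("no support: no sample points inside the band")
    phi = basis.weights_at_points(positions)
    v = sample_velocity(series, frame, positions)
    ata = phi.T @ phi
    scale = np.trace(ata) / basis.n_basis
    if not scale > 1e-12:
        raise TrackingError("no support: basis has no weight at the sample points")
    m = ata + lam_smooth * scale * _chain_laplacian(basis.n_basis)
    rhs = phi.T @ v
    for corr in corrections:
        if boundary_positions is None:
            raise ValueError("corrections given but no boundary node positions")
        if not (0 <= corr.node_id < len(boundary_positions)):
            raise ValueError(f"correction node {corr.node_id} out of range")
        if dt is None:
            raise ValueError("corrections require the frame time step dt")
        p_node = boundary_positions[corr.node_id]
        w_row = basis.weights_at_points(p_node[None, :])[0]
        v_target = (np.asarray(corr.target) - p_node) / (MM_PER_CMS_MS * dt)
        m += lam_corr * scale * np.outer(w_row, w_row)
        rhs += lam_corr * scale * np.outer(w_row, v_target)
    try:
        coef = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as exc:
        raise TrackingError("no support: singular normal equations") from exc
    resid = v - phi @ coef
    return coef, float(np.sqrt(np.mean(resid**2) * 2))  # RMS of the 2D residual norm


def advect(
    positions: np.ndarray,
    basis: BasisSet,
    coefficients: np.ndarray,
    dt_ms: float,
    method: str = "euler",
) -> np.ndarray:
    """Move points through the fitted velocity field for one time step.

    ``euler``: p + dt * v(p).  ``midpoint``: evaluates the field again at
    the half-step position (second-order for spatially varying fields).
    Velocities are cm/s, dt in ms, positions in mm.
    """
    positions = np.atleast_2d(positions)
    v1 = basis.weights_at_points(positions) @ coefficients
    if method == "euler":
        return positions + MM_PER_CMS_MS * dt_ms * v1
    if method == "midpoint":
        half = positions + 0.5 * MM_PER_CMS_MS * dt_ms * v1
        v2 = basis.weights_at_points(half) @ coefficients
        return positions + MM_PER_CMS_MS * dt_ms * v2
    raise ValueError(f"unknown integrator {method!r}")


# --------------------------------------------------------------------------
# whole-cycle tracking
# --------------------------------------------------------------------------


@dataclass
class DeformationTrajectory:
    """Per-frame basis coefficients and tracked positions of all points.

    ``positions`` stacks the boundary nodes first (2 * n_s rows) and then
    the flattened (n_s x n_d) material grid.  Positions at the reference
    frame equal the model's reference positions exactly.
    """

    coefficients: np.ndarray  # (T, n_basis, 2), cm/s
    positions: np.ndarray  # (T, P, 2), mm
    reference_frame: int
    residuals: np.ndarray  # (T,), cm/s RMS
    frame_times: np.ndarray  # (T,), ms
    frame_intervals: np.ndarray  # (T,), ms
    n_boundary: int
    grid_shape: tuple[int, int]
    wrapped_positions: np.ndarray | None = None  # final frame advected once more
    n_corrections: int = 0
    drift_compensated: bool = False

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def boundary_positions(self) -> np.ndarray:
        return self.positions[:, : self.n_boundary]

    @property
    def material_positions(self) -> np.ndarray:
        t = self.n_frames
        ns, nd = self.grid_shape
        return self.positions[:, self.n_boundary :].reshape(t, ns, nd, 2)


def track_cycle(
    series: VelocityCineSeries,
    model: MyocardialModel,
    basis: BasisSet | None = None,
    corrections: list[CorrectionPoint] | tuple[CorrectionPoint, ...] = (),
    lam_smooth: float = 0.003,
    lam_corr: float = 10.0,
    integrator: str = "euler",
    interior_mode: str = "basis",
    drift_compensation: bool = False,
) -> DeformationTrajectory:
    """Track the myocardial model through the whole cardiac cycle.

    Starting at the reference (delineation) frame, per-frame coefficients
    are fitted and all tracked points advected, wrapping around the cycle
    back to the reference frame.  ``interior_mode='boundary'`` slaves the
    interior points to the boundary motion through the transmural material
    model instead of advecting them directly.

    The once-more-advected final positions are stored for the cycle-closure
    metric; with ``drift_compensation`` a linearly growing share of the
    closure drift is subtracted from every frame (off by default — the raw
    closure error is a useful quality indicator).
    """
    if basis is None:
        basis = build_basis(model)
    if model.contours.reference_frame >= series.frames:
        raise ValueError("reference frame outside series")
    ref = model.contours.reference_frame
    t_frames = series.frames
    dts = series.frame_intervals()
    ref_points = model.all_points()
    n_boundary = model.boundary_nodes.shape[0]

    by_frame: dict[int, list[CorrectionPoint]] = {}
    for c in corrections:
        if not (0 <= c.frame < t_frames):
            raise ValueError(f"correction frame {c.frame} outside series")
        by_frame.setdefault(c.frame, []).append(c)
    n_corr = sum(len(v) for v in by_frame.values())
    if n_corr:
        log.info("tracking with %d correction point(s)", n_corr)

    n_pts = ref_points.shape[0]
    positions = np.zeros((t_frames, n_pts, 2))
    coefficients = np.zeros((t_frames, basis.n_basis, 2))
    residuals = np.zeros(t_frames)

    order = [(ref + k) % t_frames for k in range(t_frames)]
    current = ref_points.copy()
    wrapped = None
    for step, f in enumerate(order):
        positions[f] = current
        coef, res = fit_frame_coefficients(
            series,
            f,
            current,
            basis,
            corrections=tuple(by_frame.get(f, ())),
            boundary_positions=current[:n_boundary],
            dt=dts[f],
            lam_smooth=lam_smooth,
            lam_corr=lam_corr,
        )
        coefficients[f] = coef
        residuals[f] = res
        nxt = advect(current, basis, coef, dts[f], method=integrator)
        if interior_mode == "boundary":
            bnd = nxt[:n_boundary]
            interior = model.material_points + interior_displacement(
                model, bnd - model.boundary_nodes
            )
            nxt = np.vstack([bnd, interior.reshape(-1, 2)])
        elif interior_mode != "basis":
            raise ValueError(f"unknown interior mode {interior_mode!r}")
        if step == t_frames - 1:
            wrapped = nxt
        else:
            current = nxt

    traj = DeformationTrajectory(
        coefficients=coefficients,
        positions=positions,
        reference_frame=ref,
        residuals=residuals,
        frame_times=series.frame_times.copy(),
        frame_intervals=dts,
        n_boundary=n_boundary,
        grid_shape=(model.n_s, model.n_d),
        wrapped_positions=wrapped,
        n_corrections=n_corr,
    )
    if drift_compensation:
        drift = wrapped - ref_points
        cum = np.concatenate([[0.0], np.cumsum(dts)])[:t_frames]
        frac = np.zeros(t_frames)
        for k, f in enumerate(order):
            frac[f] = cum[k] / dts.sum()
        positions -= frac[:, None, None] * drift[None, :, :]
        positions[ref] = ref_points
        traj.positions = positions
        traj.drift_compensated = True
    closure = closure_error(traj)
    log.info("cycle closure error: %.4f mm RMS over boundary nodes", closure)
    return traj


def closure_error(trajectory: DeformationTrajectory) -> float:
    """RMS distance (mm, over boundary nodes) between the reference
    positions and the final-frame positions advected once more around the
    cycle.  Reported, never silently corrected."""
    if trajectory.wrapped_positions is None:
        raise ValueError("trajectory does not span the full cycle")
    ref = trajectory.positions[trajectory.reference_frame, : trajectory.n_boundary]
    wrapped = trajectory.wrapped_positions[: trajectory.n_boundary]
    return float(np.sqrt(np.mean(np.sum((wrapped - ref) ** 2, axis=1))))


def save_trajectory_csv(trajectory: DeformationTrajectory, path) -> None:
    """Per-frame boundary node positions as tidy CSV."""
    import pandas as pd

    t, nb = trajectory.n_frames, trajectory.n_boundary
    frames = np.repeat(np.arange(t), nb)
    nodes = np.tile(np.arange(nb), t)
    bp = trajectory.boundary_positions.reshape(t * nb, 2)
    pd.DataFrame(
        {"frame": frames, "node": nodes, "x_mm": bp[:, 0], "y_mm": bp[:, 1]}
    ).to_csv(path, index=False)
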