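"""Synthetic velocity-encoded data from analytic ground-truth deformations.

Emulates the package's validation setup: a U-shaped deformable phantom
(outer envelope 100 x 70 mm, longitudinally compressed 15 mm at peak by
default) and a U-shaped long-axis ventricle model.  From one closed-form
motion the simulator renders

* velocity-encoded image series (1.5 mm pixels, VENC 20 cm/s, additive
  Gaussian phase noise, phase wrapping — all matching the acquisition
  physics of phase-contrast imaging), and
* grid-dot videos of the same deformation for the optical oracle,

together with exported analytic ground truth (positions, velocities,
deformation gradient and longitudinal strain per material point).

The temporal profile of all motions is a raised cosine 0 -> peak -> 0 over
the cycle: periodic, differentiable and cycle-closing.  The simulation is
purely 2D in-plane, consistent with the strain method's own assumption;
the real phantom's 15 mm thickness plays no role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import LinearNDInterpolator

from . import geometry as geo
from .pc_io import ContourSet, VelocityCineSeries, phase_to_velocity, velocity_to_phase

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "analytic_motion",
    "phantom_contours",
    "render_velocity_series",
    "render_grid_video",
    "make_synthetic_ventricle",
    "ventricle_contours",
]


class SimulationError(ValueError):
    pass


# --------------------------------------------------------------------------
# specification
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parameters of a simulated phantom acquisition.

    Defaults are the package's reference validation conditions: a U-shaped
    phantom with a 100 x 70 mm outer envelope compressed 15 mm along the
    limb axis, imaged at 1.5 x 1.5 mm with VENC 20 cm/s over 20 frames,
    with Gaussian phase noise of 0.05*pi radians SD.
    """

    geometry: str = "U_PHANTOM"  # U_PHANTOM | STRIP
    outer_width: float = 70.0  # mm
    outer_height: float = 100.0  # mm (limb axis)
    limb_width: float = 20.0  # mm
    motion: str = "compression"  # compression | translation | rotation | static
    peak_compression: float = 15.0  # mm, along the limb axis
    mode: str = "incompressible"  # incompressible (area-preserving) | uniaxial
    translation: tuple[float, float] = (3.0, -2.0)  # mm, peak
    rotation_angle: float = 5e-4  # rad, peak
    frames: int = 20
    pixel_spacing: tuple[float, float] = (1.5, 1.5)  # mm
    venc: float = 20.0  # cm/s
    noise_sd: float = 0.05 * np.pi  # radians, phase noise SD
    cycle_ms: float = 1000.0
    margin: float = 12.0  # mm of background around the phantom
    seed: int = 0

    # derived placement (image coords, y down, base at the bottom)
    @property
    def width(self) -> float:
        return self.outer_width if self.geometry == "U_PHANTOM" else self.limb_width

    @property
    def x_center(self) -> float:
        return self.margin + self.width / 2.0

    @property
    def y_top(self) -> float:
        return self.margin

    @property
    def y_base(self) -> float:
        return self.margin + self.outer_height

    def frame_times(self) -> np.ndarray:
        return np.arange(self.frames) * self.cycle_ms / self.frames


@dataclass
class GroundTruth:
    """Analytic positions/velocities/strain per material point per frame."""

    frame_times: np.ndarray  # (T,)
    s_grid: np.ndarray
    d_grid: np.ndarray
    positions: np.ndarray  # (T, ns, nd, 2) mm
    velocities: np.ndarray  # (T, ns, nd, 2) cm/s
    F: np.ndarray  # (T, ns, nd, 2, 2)
    E: np.ndarray  # (T, ns, nd, 2, 2)
    e_long: np.ndarray  # (T, ns, nd)
    sector_targets: dict[int, float] | None = None


def time_weight(t_ms: float | np.ndarray, cycle_ms: float) -> np.ndarray:
    """Raised-cosine activation: 0 at t=0, 1 at mid-cycle, 0 at t=cycle."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.asarray(t_ms, dtype=float) / cycle_ms))


def time_weight_rate(t_ms: float | np.ndarray, cycle_ms: float) -> np.ndarray:
    """d/dt of :func:`time_weight`, per ms."""
    return (np.pi / cycle_ms) * np.sin(2.0 * np.pi * np.asarray(t_ms, dtype=float) / cycle_ms)


# --------------------------------------------------------------------------
# analytic affine motions (U phantom / strip)
# --------------------------------------------------------------------------


def _affine_at(spec: PhantomSpec, t_ms: float):
    """Homogeneous motion x = A X + b and its time derivative (per ms)."""
    w = float(time_weight(t_ms, spec.cycle_ms))
    wd = float(time_weight_rate(t_ms, spec.cycle_ms))
    if spec.motion == "static":
        return np.eye(2), np.zeros(2), np.zeros((2, 2)), np.zeros(2)
    if spec.motion == "translation":
        b = w * np.asarray(spec.translation, dtype=float)
        return np.eye(2), b, np.zeros((2, 2)), wd * np.asarray(spec.translation, dtype=float)
    if spec.motion == "rotation":
        c = np.array([spec.x_center, 0.5 * (spec.y_top + spec.y_base)])
        th = spec.rotation_angle * w
        thd = spec.rotation_angle * wd
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        drot = thd * np.array([[-np.sin(th), -np.cos(th)], [np.cos(th), -np.sin(th)]])
        return rot, c - rot @ c, drot, -drot @ c
    if spec.motion == "compression":
        c_frac = spec.peak_compression / spec.outer_height
        lam = 1.0 - c_frac * w
        lamd = -c_frac * wd
        if lam <= 0:
            raise SimulationError("non-physical motion: compression exceeds phantom length")
        if spec.mode == "incompressible":
            mu, mud = 1.0 / lam, -lamd / lam**2
        elif spec.mode == "uniaxial":
            mu, mud = 1.0, 0.0
        else:
            raise SimulationError(f"unknown transverse mode {spec.mode!r}")
        anchor = np.array([spec.x_center, spec.y_base])
        a = np.diag([mu, lam])
        ad = np.diag([mud, lamd])
        return a, anchor - a @ anchor, ad, -ad @ anchor
    raise SimulationError(f"unknown motion {spec.motion!r}")


def analytic_motion(spec: PhantomSpec, t_ms: float):
    """Closed-form motion of an affine phantom spec at time ``t_ms``.

    Returns ``(map_fn, vel_fn, F)`` where ``map_fn(X)`` maps reference
    points (mm) to deformed positions, ``vel_fn(x)`` gives the Eulerian
    velocity in cm/s at spatial positions, and ``F`` is the (spatially
    constant) deformation gradient.
    """
    if spec.geometry not in ("U_PHANTOM", "STRIP"):
        raise SimulationError(
            "analytic_motion covers the affine phantom geometries; "
            "use make_synthetic_ventricle for the ventricle"
        )
    a, b, ad, bd = _affine_at(spec, t_ms)
    if np.linalg.det(a) <= 0:
        raise SimulationError("non-physical motion: det F <= 0")
    a_inv = np.linalg.inv(a)

    def map_fn(ref_points):
        return np.asarray(ref_points, dtype=float) @ a.T + b

    def vel_fn(points):
        x = np.asarray(points, dtype=float)
        # v [mm/ms] = Adot A^-1 (x - b) + bdot; 1 mm/ms = 100 cm/s
        return 100.0 * ((x - b) @ (ad @ a_inv).T + bd)

    return map_fn, vel_fn, a.copy()


# --------------------------------------------------------------------------
# geometry: contours and membership
# --------------------------------------------------------------------------


def _u_polyline(
    x_c: float, y_top: float, arc_center_y: float, radius: float, n: int
) -> np.ndarray:
    """Open U-shaped polyline (y down): left limb down, arc, right limb up."""
    limb = arc_center_y - y_top
    arc = np.pi * radius
    total = 2 * limb + arc
    n_limb = max(8, int(round(n * limb / total)))
    n_arc = max(8, n - 2 * n_limb)
    left = np.column_stack(
        [np.full(n_limb, x_c - radius), np.linspace(y_top, arc_center_y, n_limb, endpoint=False)]
    )
    theta = np.linspace(np.pi, 0.0, n_arc, endpoint=False)
    arc_pts = np.column_stack(
        [x_c + radius * np.cos(theta), arc_center_y + radius * np.sin(theta)]
    )
    right = np.column_stack(
        [np.full(n_limb, x_c + radius), np.linspace(arc_center_y, y_top, n_limb)]
    )
    return np.vstack([left, arc_pts, right])


def phantom_contours(spec: PhantomSpec, n_points: int = 200) -> ContourSet:
    """Inner ('endo') and outer ('epi') boundary of the phantom band."""
    if spec.geometry == "STRIP":
        y = np.linspace(spec.y_top, spec.y_base, n_points)
        endo = np.column_stack([np.full(n_points, spec.x_center - spec.limb_width / 2), y])
        epi = np.column_stack([np.full(n_points, spec.x_center + spec.limb_width / 2), y])
        return ContourSet(endo=endo, epi=epi, reference_frame=0)
    if spec.geometry == "U_PHANTOM":
        r_out = spec.outer_width / 2.0
        r_in = r_out - spec.limb_width
        if r_in <= 0:
            raise SimulationError("limb width too large for the outer envelope")
        arc_y = spec.y_base - r_out
        endo = _u_polyline(spec.x_center, spec.y_top, arc_y, r_in, n_points)
        epi = _u_polyline(spec.x_center, spec.y_top, arc_y, r_out, n_points)
        return ContourSet(endo=endo, epi=epi, reference_frame=0)
    raise SimulationError(f"no contour generator for geometry {spec.geometry!r}")


def reference_membership(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Boolean membership of reference points in the undeformed phantom."""
    p = np.atleast_2d(points)
    x, y = p[:, 0], p[:, 1]
    if spec.geometry == "STRIP":
        return (
            (np.abs(x - spec.x_center) <= spec.limb_width / 2)
            & (y >= spec.y_top)
            & (y <= spec.y_base)
        )
    r_out = spec.outer_width / 2.0
    r_in = r_out - spec.limb_width
    arc_y = spec.y_base - r_out
    dx = np.abs(x - spec.x_center)
    in_limbs = (dx >= r_in) & (dx <= r_out) & (y >= spec.y_top) & (y <= arc_y)
    r = np.hypot(x - spec.x_center, y - arc_y)
    in_arc = (y >= arc_y) & (r >= r_in) & (r <= r_out)
    return in_limbs | in_arc


def _pixel_grid(spec: PhantomSpec):
    dx, dy = spec.pixel_spacing
    width = spec.width + 2 * spec.margin
    height = spec.outer_height + 2 * spec.margin
    ncol = int(np.ceil(width / dx)) + 1
    nrow = int(np.ceil(height / dy)) + 1
    xs = np.arange(ncol) * dx
    ys = np.arange(nrow) * dy
    xx, yy = np.meshgrid(xs, ys)  # (nrow, ncol)
    return xx, yy


def _encode_with_noise(
    velocity: np.ndarray, venc: float, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocity -> wrapped phase (+ Gaussian phase noise) -> velocity.

    Velocities beyond VENC alias exactly as in the scanner reconstruction.
    """
    phase = velocity_to_phase(velocity, venc, wrap=True)
    if noise_sd > 0:
        phase = np.angle(np.exp(1j * (phase + rng.normal(0.0, noise_sd, velocity.shape))))
    return phase_to_velocity(phase, venc)


# --------------------------------------------------------------------------
# velocity-encoded rendering (affine phantoms)
# --------------------------------------------------------------------------


def render_velocity_series(
    spec: PhantomSpec, n_s: int = 64, n_d: int = 8
) -> tuple[VelocityCineSeries, GroundTruth, ContourSet]:
    """Render a velocity-encoded cine of the phantom plus its ground truth.

    Per frame the magnitude is the (supersampled, soft-edged) phantom mask
    and the velocity images hold the analytic Eulerian velocity evaluated
    at pixel centers — the affine motions are globally defined, so the
    field is its own analytic continuation outside the phantom, which keeps
    bilinear sampling at boundary nodes free of partial-volume bias.  The
    velocity is encoded to wrapped phase, Gaussian phase noise is added
    (seeded) and the phase decoded back, exactly as a scanner
    reconstruction would.
    """
    contours = phantom_contours(spec)
    model = geo.build_model(contours, n_s=n_s, n_d=n_d)
    times = spec.frame_times()
    xx, yy = _pixel_grid(spec)
    pix = np.column_stack([xx.ravel(), yy.ravel()])
    rng = np.random.default_rng(spec.seed)

    # 3x3 supersampling offsets for soft mask edges
    offs = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])
    dx, dy = spec.pixel_spacing

    t_frames = len(times)
    mag = np.zeros((t_frames,) + xx.shape)
    vel_x = np.zeros_like(mag)
    vel_y = np.zeros_like(mag)

    x_ref = model.material_points
    gt_pos = np.zeros((t_frames,) + x_ref.shape)
    gt_vel = np.zeros_like(gt_pos)
    gt_f = np.zeros((t_frames,) + x_ref.shape[:2] + (2, 2))

    for k, t in enumerate(times):
        map_fn, vel_fn, f_mat = analytic_motion(spec, t)
        a, b, _, _ = _affine_at(spec, t)
        a_inv = np.linalg.inv(a)
        acc = np.zeros(xx.size)
        for ox in offs:
            for oy in offs:
                sub = pix + np.array([ox * dx, oy * dy])
                ref = (sub - b) @ a_inv.T
                acc += reference_membership(spec, ref)
        mag[k] = (acc / 9.0).reshape(xx.shape)
        v = vel_fn(pix)
        vel_x[k] = v[:, 0].reshape(xx.shape)
        vel_y[k] = v[:, 1].reshape(xx.shape)
        gt_pos[k] = map_fn(x_ref.reshape(-1, 2)).reshape(x_ref.shape)
        gt_vel[k] = vel_fn(gt_pos[k].reshape(-1, 2)).reshape(x_ref.shape)
        gt_f[k] = f_mat

    vel_x = _encode_with_noise(vel_x, spec.venc, spec.noise_sd, rng)
    vel_y = _encode_with_noise(vel_y, spec.venc, spec.noise_sd, rng)

    gt_e = 0.5 * (np.einsum("...ji,...jk->...ik", gt_f, gt_f) - np.eye(2))
    ldirs = model.longitudinal_dirs[None]
    gt_e_long = np.einsum("...i,...ij,...j->...", ldirs, gt_e, ldirs)

    series = VelocityCineSeries(
        magnitude=mag,
        velocity_x=vel_x,
        velocity_y=vel_y,
        pixel_spacing=spec.pixel_spacing,
        frame_times=times,
        venc=spec.venc,
        view_label="PHANTOM",
    )
    gt = GroundTruth(
        frame_times=times,
        s_grid=model.s_grid,
        d_grid=model.d_grid,
        positions=gt_pos,
        velocities=gt_vel,
        F=gt_f,
        E=gt_e,
        e_long=gt_e_long,
    )
    return series, gt, contours


# --------------------------------------------------------------------------
# grid-dot video rendering
# --------------------------------------------------------------------------


def render_grid_video(
    spec: PhantomSpec,
    dot_spacing: float = 5.0,  # mm
    dot_radius: float = 1.0,  # mm
    resolution: tuple[int, int] = (1080, 720),  # (width, height) px
    n_video_frames: int | None = None,
):
    """Render the deforming phantom as a grid-dot video.

    Dark dots on a light background are placed on a regular ``dot_spacing``
    grid in the reference phantom, advected by the analytic motion and
    rendered with antialiased edges.  Returns
    ``(frames (T, H, W) float, dot_trajectories_px (T, K, 2),
    mm_per_px, dot_reference_mm (K, 2))``; trajectories are exact dot
    centers in pixel units (x = column, y = row).
    """
    if dot_spacing <= 2 * dot_radius:
        raise SimulationError("dot spacing must exceed the dot diameter")
    wpx, hpx = resolution
    width = spec.width + 2 * spec.margin
    height = spec.outer_height + 2 * spec.margin
    px_per_mm = min((wpx - 1) / width, (hpx - 1) / height)

    # reference dot grid, fully inside the phantom (center + rim check)
    gx = np.arange(spec.margin, spec.margin + spec.width + 1e-9, dot_spacing)
    gy = np.arange(spec.y_top, spec.y_base + 1e-9, dot_spacing)
    cx, cy = np.meshgrid(gx, gy)
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    keep = reference_membership(spec, centers)
    ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    rim = np.column_stack([np.cos(ang), np.sin(ang)]) * dot_radius
    for r in rim:
        keep &= reference_membership(spec, centers + r)
    dots_ref = centers[keep]
    if len(dots_ref) < 4:
        raise SimulationError("too few dots fit inside the phantom")

    n_t = n_video_frames or spec.frames
    times = np.arange(n_t) * spec.cycle_ms / n_t
    frames = np.full((n_t, hpx, wpx), 0.95, dtype=np.float32)
    traj_px = np.zeros((n_t, len(dots_ref), 2))
    r_px = dot_radius * px_per_mm
    pad = int(np.ceil(r_px)) + 2
    for k, t in enumerate(times):
        map_fn, _, _ = analytic_motion(spec, t)
        pos = map_fn(dots_ref) * px_per_mm
        if np.any(
            (pos[:, 0] < r_px)
            | (pos[:, 0] > wpx - 1 - r_px)
            | (pos[:, 1] < r_px)
            | (pos[:, 1] > hpx - 1 - r_px)
        ):
            raise SimulationError("dots out of frame")
        traj_px[k] = pos
        img = frames[k]
        for x, y in pos:
            c0 = max(0, int(x) - pad)
            r0 = max(0, int(y) - pad)
            c1 = min(wpx, int(x) + pad + 1)
            r1 = min(hpx, int(y) + pad + 1)
            yy, xx = np.mgrid[r0:r1, c0:c1]
            dist = np.hypot(xx - x, yy - y)
            cover = np.clip(r_px - dist + 0.5, 0.0, 1.0)
            img[r0:r1, c0:c1] -= 0.85 * cover
        np.clip(img, 0.0, 1.0, out=img)
    return frames, traj_px, 1.0 / px_per_mm, dots_ref


def save_video_frames(frames: np.ndarray, directory) -> list:
    """Write video frames as 8-bit PNGs ``frame_0000.png`` etc."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, fr in enumerate(frames):
        p = directory / f"frame_{k:04d}.png"
        iio.imwrite(p, (np.clip(fr, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


# --------------------------------------------------------------------------
# synthetic ventricle with prescribed per-sector strain
# --------------------------------------------------------------------------


def ventricle_contours(
    endo_radius: float = 22.0,
    wall_thickness: float = 10.0,
    limb_length: float = 45.0,
    margin: float = 10.0,
    n_points: int = 200,
) -> ContourSet:
    """U-shaped long-axis ventricle contours (endo inside epi)."""
    r_epi = endo_radius + wall_thickness
    x_c = margin + r_epi
    y_top = margin
    arc_y = y_top + limb_length
    endo = _u_polyline(x_c, y_top, arc_y, endo_radius, n_points)
    epi = _u_polyline(x_c, y_top, arc_y, r_epi, n_points)
    return ContourSet(endo=endo, epi=epi, reference_frame=0)


@dataclass
class SimulatedView:
    """One rendered long-axis view of the synthetic ventricle."""

    view_label: str
    series: VelocityCineSeries
    ground_truth: GroundTruth
    contours: ContourSet


def _fill_nearest(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by their nearest valid neighbor's value."""
    if valid.all():
        return values
    idx = ndimage.distance_transform_edt(~valid, return_distances=False, return_indices=True)
    return values[tuple(idx)]


def make_synthetic_ventricle(
    target_map: dict[int, float],
    views: tuple[str, ...] = ("2CH", "3CH", "4CH"),
    frames: int = 20,
    pixel_spacing: tuple[float, float] = (1.5, 1.5),
    venc: float = 20.0,
    noise_sd: float = 0.05 * np.pi,
    cycle_ms: float = 1000.0,
    seed: int = 0,
    n_s: int = 64,
    n_d: int = 8,
    endo_radius: float = 22.0,
    wall_thickness: float = 10.0,
    limb_length: float = 45.0,
    margin: float = 10.0,
) -> dict[str, SimulatedView]:
    """Render long-axis views whose motion hits per-sector strain targets.

    ``target_map`` gives the requested peak longitudinal strain per AHA
    segment (1..17).  Within each view, every arc-length station carries
    the longitudinal stretch ``lambda(s) = sqrt(1 + 2 e_target(segment(s)))``,
    and the deformed configuration is built by integrating the stretched
    tangent of each transmural fiber line from the (fixed) apex outward —
    so the longitudinal fiber stretch equals lambda(s) *exactly* at every
    point and depth, and the ground-truth peak strain per sector equals
    the target by construction.  The base moves toward the apex, as in
    systole.

    The Eulerian velocity needed for rendering is interpolated from the
    (dense) deformed material grid; pixels outside the deformed band take
    the value of their nearest in-band neighbor, avoiding partial-volume
    bias at boundary nodes.
    """
    targets = {int(k): float(v) for k, v in target_map.items()}
    missing = set(range(1, 18)) - set(targets)
    if missing:
        raise ValueError(f"target map must cover all 17 segments; missing {sorted(missing)}")
    for seg, e in targets.items():
        if abs(e) >= 0.5:
            raise SimulationError(f"unreachable target: |e|={abs(e)} >= 0.5 in segment {seg}")

    contours = ventricle_contours(endo_radius, wall_thickness, limb_length, margin)
    r_epi = endo_radius + wall_thickness
    spec_like = PhantomSpec(
        geometry="U_PHANTOM",
        outer_width=2 * r_epi,
        outer_height=limb_length + r_epi,
        limb_width=wall_thickness,
        frames=frames,
        pixel_spacing=pixel_spacing,
        venc=venc,
        noise_sd=noise_sd,
        cycle_ms=cycle_ms,
        margin=margin,
        seed=seed,
    )
    times = spec_like.frame_times()
    xx, yy = _pixel_grid(spec_like)
    pix = np.column_stack([xx.ravel(), yy.ravel()])

    # dense material grid; the coarse model grid is an exact subsample
    refine = 8
    n_sf = refine * (n_s - 1) + 1
    band = geo._BandParam(contours, n_dense=n_sf)
    s_f = np.linspace(0.0, 1.0, n_sf)
    d_grid = np.linspace(0.0, 1.0, n_d)
    ss, dd = np.meshgrid(s_f, d_grid, indexing="ij")
    x_fine = band.position(ss.ravel(), dd.ravel()).reshape(n_sf, n_d, 2)

    out: dict[str, SimulatedView] = {}
    rng = np.random.default_rng(seed)
    for view in views:
        seg_of_s = geo.segment_of_s(s_f, view)
        lam_target = np.sqrt(
            1.0 + 2.0 * np.array([targets[int(seg)] for seg in seg_of_s])
        )
        dxds = np.gradient(x_fine, s_f, axis=0)
        integrand = (lam_target - 1.0)[:, None, None] * dxds
        cumulative = cumulative_trapezoid(integrand, s_f, axis=0, initial=0.0)
        apex = n_sf // 2  # s = 0.5 exactly (n_sf odd)
        disp = cumulative - cumulative[apex]  # full-activation displacement

        t_frames = len(times)
        mag = np.zeros((t_frames,) + xx.shape)
        vel_x = np.zeros_like(mag)
        vel_y = np.zeros_like(mag)
        sub = slice(None, None, refine)
        gt_pos = np.zeros((t_frames, n_s, n_d, 2))
        gt_vel = np.zeros_like(gt_pos)
        gt_f = np.zeros((t_frames, n_s, n_d, 2, 2))
        gt_e_long = np.zeros((t_frames, n_s, n_d))

        s_coarse = s_f[sub]
        b_ref = np.stack(
            np.gradient(x_fine[sub], s_coarse, d_grid, axis=(0, 1), edge_order=2), axis=-1
        )
        b_inv = np.linalg.inv(b_ref)

        for k, t in enumerate(times):
            w = float(time_weight(t, cycle_ms))
            wd = float(time_weight_rate(t, cycle_ms))
            pos_fine = x_fine + w * disp
            vel_fine = 100.0 * wd * disp  # cm/s

            # magnitude and masked velocity images
            endo_line = pos_fine[:, 0, :]
            epi_line = pos_fine[:, -1, :]
            poly = MplPath(np.vstack([endo_line, epi_line[::-1]]))
            inside = poly.contains_points(pix).reshape(xx.shape)
            flat = pos_fine.reshape(-1, 2)
            interp = LinearNDInterpolator(flat, vel_fine.reshape(-1, 2), fill_value=np.nan)
            v = interp(pix).reshape(xx.shape + (2,))
            valid = inside & np.isfinite(v[..., 0])
            vel_x[k] = _fill_nearest(np.where(valid, v[..., 0], 0.0), valid)
            vel_y[k] = _fill_nearest(np.where(valid, v[..., 1], 0.0), valid)
            mag[k] = ndimage.gaussian_filter(inside.astype(float), 0.7)

            gt_pos[k] = pos_fine[sub]
            gt_vel[k] = vel_fine[sub]
            a = np.stack(
                np.gradient(gt_pos[k], s_coarse, d_grid, axis=(0, 1), edge_order=2), axis=-1
            )
            gt_f[k] = np.einsum("...ij,...jk->...ik", a, b_inv)
            lam_t = 1.0 + (lam_target[sub] - 1.0) * w
            gt_e_long[k] = ((lam_t**2 - 1.0) / 2.0)[:, None]

        vel_x = _encode_with_noise(vel_x, venc, noise_sd, rng)
        vel_y = _encode_with_noise(vel_y, venc, noise_sd, rng)

        gt_e = 0.5 * (np.einsum("...ji,...jk->...ik", gt_f, gt_f) - np.eye(2))
        series = VelocityCineSeries(
            magnitude=mag,
            velocity_x=vel_x,
            velocity_y=vel_y,
            pixel_spacing=pixel_spacing,
            frame_times=times,
            venc=venc,
            view_label=view,
        )
        gt = GroundTruth(
            frame_times=times,
            s_grid=s_coarse,
            d_grid=d_grid,
            positions=gt_pos,
            velocities=gt_vel,
            F=gt_f,
            E=gt_e,
            e_long=gt_e_long,
            sector_targets=targets,
        )
        out[view] = SimulatedView(
            view_label=view, series=series, ground_truth=gt, contours=contours
        )
    return out
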