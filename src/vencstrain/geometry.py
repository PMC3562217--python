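"""Myocardial geometry: centerline, material coordinates and AHA sectors.

In a long-axis view the left-ventricular myocardium appears as a U-shaped
band between the endocardial and epicardial contours.  The band is
parameterized by *material coordinates* ``(s, d)``:

* ``s`` in [0, 1] — normalized arc-length along the matched contour
  parameterization, running base -> apex -> base;
* ``d`` in [0, 1] — transmural depth, 0 at the endocardium, 1 at the
  epicardium.

The centerline is the mid-wall curve ``(endo(s) + epi(s)) / 2``; the local
longitudinal direction is its unit tangent and the radial direction is the
orthogonal unit vector pointing endo -> epi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pc_io import ContourSet

__all__ = [
    "MyocardialModel",
    "SectorMap",
    "build_model",
    "compute_centerline",
    "material_coordinates",
    "band_position",
    "direction_field",
    "assign_aha_segments",
    "interior_displacement",
    "resample_polyline",
    "polyline_arclength_coordinate",
    "AHA_VIEW_SEGMENTS",
    "AHA_REGION_EDGES",
]

# Default mapping from the seven arc-length regions of each long-axis view
# (base -> apex -> base) to AHA 17-segment labels.  The union over the three
# views covers all 17 segments; segments 14, 16 and 17 are shared.
AHA_VIEW_SEGMENTS = {
    "2CH": (1, 7, 13, 17, 15, 10, 4),
    "3CH": (2, 8, 14, 17, 16, 11, 5),
    "4CH": (3, 9, 14, 17, 16, 12, 6),
}

# Arc-length edges of the seven regions: basal/mid/apical thirds of each
# wall (walls span s in [0, 0.45] and [0.55, 1]) plus the apex cap
# s in [0.45, 0.55].
AHA_REGION_EDGES = (0.0, 0.15, 0.30, 0.45, 0.55, 0.70, 0.85, 1.0)


class GeometryError(ValueError):
    pass


# --------------------------------------------------------------------------
# polyline utilities
# --------------------------------------------------------------------------


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline at ``n`` equally spaced arc-length stations."""
    points = np.asarray(points, dtype=float)
    arc = _cumulative_arclength(points)
    if arc[-1] <= 0:
        raise GeometryError("degenerate contour: zero total length")
    t = np.linspace(0.0, arc[-1], n)
    return np.column_stack([np.interp(t, arc, points[:, k]) for k in range(2)])


def polyline_arclength_coordinate(polyline: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Normalized arc-length of each query point's nearest foot on a polyline.

    Vectorized point-to-segment projection over all polyline segments;
    returns values in [0, 1].  Used by the tracking module to evaluate
    basis weights at arbitrary (moving) point positions.
    """
    polyline = np.asarray(polyline, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = polyline[:-1]  # (M, 2)
    b = polyline[1:]
    ab = b - a
    ab2 = np.maximum((ab**2).sum(axis=1), 1e-300)
    # (N, M, 2) differences
    ap = pts[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2[None, :], 0.0, 1.0)
    foot = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d2 = ((pts[:, None, :] - foot) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    arc = _cumulative_arclength(polyline)
    seg_len = np.sqrt(ab2)
    s = arc[best] + t[np.arange(len(pts)), best] * seg_len[best]
    s /= arc[-1]
    return s if np.asarray(points).ndim == 2 else float(s[0])


def _align_contours(endo: np.ndarray, epi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip the epicardial contour if it runs opposite to the endocardial one."""
    same = np.linalg.norm(endo[0] - epi[0]) + np.linalg.norm(endo[-1] - epi[-1])
    flipped = np.linalg.norm(endo[0] - epi[-1]) + np.linalg.norm(endo[-1] - epi[0])
    if flipped < same:
        epi = epi[::-1]
    return endo, epi


# --------------------------------------------------------------------------
# band parameterization
# --------------------------------------------------------------------------


class _BandParam:
    """Piecewise-bilinear parameterization of the endo-epi band.

    Both contours are resampled at a common dense set of normalized
    arc-length stations; the band point at ``(s, d)`` is the transmural
    blend ``(1-d) * endo(s) + d * epi(s)`` with the contours interpolated
    linearly in ``s``.  The inverse map is solved patchwise by Newton
    iteration, making position <-> (s, d) an exact round trip for band
    points.
    """

    def __init__(self, contours: ContourSet, n_dense: int = 505):
        endo, epi = _align_contours(contours.endo, contours.epi)
        self.s = np.linspace(0.0, 1.0, n_dense)
        self.endo = resample_polyline(endo, n_dense)
        self.epi = resample_polyline(epi, n_dense)
        chords = self.epi - self.endo
        lens = np.linalg.norm(chords, axis=1)
        if np.any(lens < 1e-9):
            raise GeometryError("invalid myocardium: endo and epi contours touch or cross")
        u = chords / lens[:, None]
        if np.any((u[:-1] * u[1:]).sum(axis=1) < 0):
            raise GeometryError("invalid myocardium: matched transmural chords cross")

    def position(self, s, d):
        s = np.asarray(s, dtype=float)
        d = np.asarray(d, dtype=float)
        e = np.column_stack([np.interp(s, self.s, self.endo[:, k]) for k in range(2)])
        p = np.column_stack([np.interp(s, self.s, self.epi[:, k]) for k in range(2)])
        out = (1.0 - d)[..., None] * e + d[..., None] * p
        return out if out.shape[0] > 1 or np.asarray(s).ndim else out[0]

    def _solve_patch(self, i: int, p: np.ndarray) -> tuple[float, float, float]:
        """Newton-solve (a, d) in patch [s_i, s_{i+1}]; returns (a, d, residual)."""
        e0, e1 = self.endo[i], self.endo[i + 1]
        p0, p1 = self.epi[i], self.epi[i + 1]
        a, d = 0.5, 0.5
        for _ in range(25):
            ea = (1 - a) * e0 + a * e1
            pa = (1 - a) * p0 + a * p1
            f = (1 - d) * ea + d * pa - p
            if np.dot(f, f) < 1e-24:
                break
            J = np.column_stack([(1 - d) * (e1 - e0) + d * (p1 - p0), pa - ea])
            det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
            if abs(det) < 1e-300:
                return a, d, np.inf
            da = (J[1, 1] * f[0] - J[0, 1] * f[1]) / det
            dd = (-J[1, 0] * f[0] + J[0, 0] * f[1]) / det
            a -= da
            d -= dd
            a = min(max(a, -1.0), 2.0)
            d = min(max(d, -1.0), 2.0)
        ea = (1 - a) * e0 + a * e1
        pa = (1 - a) * p0 + a * p1
        res = float(np.linalg.norm((1 - d) * ea + d * pa - p))
        return a, d, res

    def inverse(self, point: np.ndarray, tol: float = 1e-6) -> tuple[float, float]:
        p = np.asarray(point, dtype=float)
        # candidate patch from the nearest transmural chord (point-to-segment)
        chord = self.epi - self.endo
        denom = np.maximum((chord**2).sum(axis=1), 1e-300)
        t = np.clip(((p - self.endo) * chord).sum(axis=1) / denom, 0.0, 1.0)
        foot = self.endo + t[:, None] * chord
        i0 = int(np.argmin(((foot - p) ** 2).sum(axis=1)))
        best = None
        for i in range(max(0, i0 - 3), min(len(self.s) - 1, i0 + 4)):
            a, d, res = self._solve_patch(i, p)
            if res < tol and -1e-7 <= a <= 1 + 1e-7:
                s = self.s[i] + np.clip(a, 0.0, 1.0) * (self.s[i + 1] - self.s[i])
                cand = (float(s), float(d), res)
                if best is None or res < best[2]:
                    best = cand
        if best is None:
            raise GeometryError("outside myocardium: point not in the endo-epi band")
        s, d, _ = best
        if not (-1e-7 <= d <= 1 + 1e-7):
            raise GeometryError("outside myocardium: transmural depth outside [0, 1]")
        return s, float(np.clip(d, 0.0, 1.0))


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def compute_centerline(contours: ContourSet, n_samples: int = 200) -> np.ndarray:
    """Mid-wall centerline: midpoints of endo/epi at matched arc-length.

    Ordered base -> apex -> base like the contours themselves.
    """
    band = _BandParam(contours)
    s = np.linspace(0.0, 1.0, n_samples)
    return band.position(s, np.full(n_samples, 0.5))


def band_position(contours: ContourSet, s, d) -> np.ndarray:
    """Forward material map: band point at material coordinates ``(s, d)``."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    return _BandParam(contours).position(s, d)


def material_coordinates(contours: ContourSet, point) -> tuple[float, float]:
    """Inverse material map: ``(s, d)`` of a point inside the band.

    Raises ``GeometryError('outside myocardium...')`` for points outside
    the endo-epi band.
    """
    return _BandParam(contours).inverse(point)


@dataclass
class MyocardialModel:
    """Discretized myocardial band: material grid, directions, boundary nodes."""

    contours: ContourSet
    s_grid: np.ndarray  # (ns,)
    d_grid: np.ndarray  # (nd,)
    material_points: np.ndarray  # (ns, nd, 2) reference positions, mm
    centerline: np.ndarray  # (nc, 2) dense mid-wall curve
    centerline_s: np.ndarray  # (nc,)
    longitudinal_dirs: np.ndarray  # (ns, nd, 2) unit tangents
    radial_dirs: np.ndarray  # (ns, nd, 2) unit normals, endo -> epi
    boundary_nodes: np.ndarray  # (2*ns, 2): endo nodes then epi nodes
    boundary_node_s: np.ndarray  # (2*ns,)

    _band: _BandParam | None = None

    @property
    def n_s(self) -> int:
        return len(self.s_grid)

    @property
    def n_d(self) -> int:
        return len(self.d_grid)

    @property
    def centerline_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())

    def all_points(self) -> np.ndarray:
        """Boundary nodes followed by the flattened material grid, (P, 2)."""
        return np.vstack([self.boundary_nodes, self.material_points.reshape(-1, 2)])

    def band(self) -> _BandParam:
        if self._band is None:
            self._band = _BandParam(self.contours, n_dense=8 * (self.n_s - 1) + 1)
        return self._band


def _centerline_tangents(centerline: np.ndarray) -> np.ndarray:
    d = np.gradient(centerline, axis=0)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise GeometryError("degenerate centerline: repeated points give no tangent")
    return d / norms[:, None]


def build_model(
    contours: ContourSet,
    n_s: int = 64,
    n_d: int = 8,
    n_centerline: int | None = None,
) -> MyocardialModel:
    """Build the discrete myocardial model from end-diastolic contours.

    The material grid has ``n_s`` arc-length stations by ``n_d`` transmural
    stations (``d = 0`` on the endocardium).  Boundary nodes are placed at
    the same ``n_s`` stations on both contours so that boundary-driven
    interior interpolation is exact at grid points.
    """
    band = _BandParam(contours, n_dense=8 * (n_s - 1) + 1)
    s_grid = np.linspace(0.0, 1.0, n_s)
    d_grid = np.linspace(0.0, 1.0, n_d)
    ss, dd = np.meshgrid(s_grid, d_grid, indexing="ij")
    pts = band.position(ss.ravel(), dd.ravel()).reshape(n_s, n_d, 2)

    nc = n_centerline or 8 * (n_s - 1) + 1
    c_s = np.linspace(0.0, 1.0, nc)
    centerline = band.position(c_s, np.full(nc, 0.5))
    tangents = _centerline_tangents(centerline)

    # longitudinal = tangent at each grid s; radial = 90-degree rotation
    # oriented endo -> epi
    t_grid = np.column_stack(
        [np.interp(s_grid, c_s, tangents[:, k]) for k in range(2)]
    )
    t_grid /= np.linalg.norm(t_grid, axis=1)[:, None]
    normal = np.column_stack([-t_grid[:, 1], t_grid[:, 0]])
    endo_pts = band.position(s_grid, np.zeros(n_s))
    epi_pts = band.position(s_grid, np.ones(n_s))
    flip = np.sign(((epi_pts - endo_pts) * normal).sum(axis=1))
    flip[flip == 0] = 1.0
    normal *= flip[:, None]

    long_dirs = np.broadcast_to(t_grid[:, None, :], (n_s, n_d, 2)).copy()
    rad_dirs = np.broadcast_to(normal[:, None, :], (n_s, n_d, 2)).copy()

    model = MyocardialModel(
        contours=contours,
        s_grid=s_grid,
        d_grid=d_grid,
        material_points=pts,
        centerline=centerline,
        centerline_s=c_s,
        longitudinal_dirs=long_dirs,
        radial_dirs=rad_dirs,
        boundary_nodes=np.vstack([endo_pts, epi_pts]),
        boundary_node_s=np.concatenate([s_grid, s_grid]),
        _band=band,
    )
    return model


def direction_field(model: MyocardialModel) -> tuple[np.ndarray, np.ndarray]:
    """Unit longitudinal (centerline tangent) and radial (endo->epi normal)
    direction per material point, in the reference configuration."""
    return model.longitudinal_dirs, model.radial_dirs


@dataclass
class SectorMap:
    """AHA 17-segment label per material point for one long-axis view."""

    labels: np.ndarray  # (ns, nd) int
    view_label: str

    def segments_present(self) -> set[int]:
        return set(int(v) for v in np.unique(self.labels))

    def to_dataframe(self, model: MyocardialModel) -> pd.DataFrame:
        ns, nd = self.labels.shape
        ss, dd = np.meshgrid(model.s_grid, model.d_grid, indexing="ij")
        return pd.DataFrame(
            {
                "point": np.arange(ns * nd),
                "s": ss.ravel(),
                "d": dd.ravel(),
                "segment": self.labels.ravel(),
            }
        )


def segment_of_s(s, view_label: str):
    """AHA segment label(s) for arc-length position(s) ``s`` in a view."""
    if view_label not in AHA_VIEW_SEGMENTS:
        raise GeometryError(f"no AHA map for {view_label}")
    segs = np.asarray(AHA_VIEW_SEGMENTS[view_label])
    region = np.clip(
        np.searchsorted(np.asarray(AHA_REGION_EDGES[1:-1]), np.asarray(s), side="right"),
        0,
        6,
    )
    return segs[region]


def assign_aha_segments(model: MyocardialModel, view_label: str) -> SectorMap:
    """Label every material point with its AHA segment for the given view.

    Each wall (s in [0, 0.45] and [0.55, 1]) is split into basal/mid/apical
    thirds by arc-length; the apex cap (s in [0.45, 0.55]) is segment 17.
    """
    labels_s = segment_of_s(model.s_grid, view_label)
    labels = np.broadcast_to(labels_s[:, None], (model.n_s, model.n_d)).copy()
    return SectorMap(labels=labels.astype(int), view_label=view_label)


def interior_displacement(
    model: MyocardialModel, boundary_displacements: np.ndarray
) -> np.ndarray:
    """Displace interior material points from boundary-node displacements.

    The transmural blend is linear in depth:
    ``u(s, d) = (1 - d) * u_endo(s) + d * u_epi(s)`` with the endo/epi node
    displacements interpolated continuously along arc-length.  Any affine
    boundary motion is therefore reproduced exactly at the material grid.
    """
    u = np.asarray(boundary_displacements, dtype=float)
    n = model.n_s
    if u.shape != (2 * n, 2):
        raise ValueError(
            f"node/displacement count mismatch: expected ({2 * n}, 2), got {u.shape}"
        )
    u_endo, u_epi = u[:n], u[n:]
    s, d = model.s_grid, model.d_grid
    ue = np.column_stack([np.interp(s, s, u_endo[:, k]) for k in range(2)])
    up = np.column_stack([np.interp(s, s, u_epi[:, k]) for k in range(2)])
    return (1.0 - d)[None, :, None] * ue[:, None, :] + d[None, :, None] * up[:, None, :]
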