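"""Reading and writing velocity-encoded cine data, contours and reports.

Phase-contrast MR stores in-plane velocity in the image phase: a stored
phase of +/- pi corresponds to +/- VENC (the velocity-encoding limit, in
cm/s).  This module owns that conversion, the package's native array
container (a ``.npz`` archive of named arrays plus a JSON metadata block),
and plain JSON/CSV round-trips for contours, correction points and strain
reports.

Coordinate conventions used throughout the package:

* images are indexed ``[frame, row, col]``; 0-based pixel indices;
* physical position (mm) = pixel index x pixel spacing, with x = column
  and y = row (positive x rightward, positive y downward);
* velocities are in cm/s, times in ms, geometry in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VIEW_LABELS = ("2CH", "3CH", "4CH", "PHANTOM")

__all__ = [
    "VelocityCineSeries",
    "ContourSet",
    "CorrectionPoint",
    "phase_to_velocity",
    "velocity_to_phase",
    "load_velocity_series",
    "save_velocity_series",
    "save_contours",
    "load_contours",
    "save_corrections",
    "load_corrections",
    "save_report",
    "load_report",
]


class SeriesFormatError(ValueError):
    """Raised when a stored series is incomplete or inconsistent."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class VelocityCineSeries:
    """A cine of magnitude + two in-plane velocity component images.

    Attributes
    ----------
    magnitude, velocity_x, velocity_y
        Arrays of shape ``(frames, rows, cols)``; velocities in cm/s.
    pixel_spacing
        ``(dx, dy)`` in mm (column spacing, row spacing).
    frame_times
        Time of each frame from the R-wave, ms, strictly increasing.
    venc
        Velocity-encoding limit in cm/s.
    view_label
        One of ``2CH, 3CH, 4CH, PHANTOM``.
    """

    magnitude: np.ndarray
    velocity_x: np.ndarray
    velocity_y: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_times: np.ndarray
    venc: float
    view_label: str = "PHANTOM"

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.velocity_x = np.asarray(self.velocity_x, dtype=float)
        self.velocity_y = np.asarray(self.velocity_y, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.validate()

    @property
    def frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single image."""
        return self.magnitude.shape[1:]

    def frame_intervals(self) -> np.ndarray:
        """Per-frame time step dt_k (ms), the last one wrapping the cycle.

        The frames cover one cardiac cycle (retrospective gating), so the
        interval that carries the last frame back to the first is taken as
        the mean of the measured intervals.
        """
        dts = np.diff(self.frame_times)
        return np.append(dts, dts.mean())

    def cycle_duration(self) -> float:
        """Total duration of the cycle in ms (sum of frame intervals)."""
        return float(self.frame_intervals().sum())

    def validate(self) -> None:
        if self.magnitude.ndim != 3:
            raise SeriesFormatError("inconsistent geometry: magnitude must be (frames, rows, cols)")
        if not (self.magnitude.shape == self.velocity_x.shape == self.velocity_y.shape):
            raise SeriesFormatError("inconsistent geometry: image arrays must share one shape")
        if self.frames < 2:
            raise SeriesFormatError("series must contain at least 2 frames")
        if not self.venc > 0:
            raise SeriesFormatError("venc required: venc must be a positive velocity in cm/s")
        if self.frame_times.shape != (self.frames,):
            raise SeriesFormatError("inconsistent geometry: one frame time per frame required")
        if not np.all(np.diff(self.frame_times) > 0):
            raise SeriesFormatError("frame_times must be strictly increasing")
        if self.view_label not in VIEW_LABELS:
            raise SeriesFormatError(f"unknown view label {self.view_label!r}")
        vmax = max(np.abs(self.velocity_x).max(), np.abs(self.velocity_y).max())
        if vmax > self.venc * (1 + 1e-9):
            raise SeriesFormatError("decoded velocity exceeds venc; phase not in [-pi, pi]?")


@dataclass
class ContourSet:
    """End-diastolic endocardial and epicardial contours.

    Both contours are open, ordered point lists in mm (image coordinates),
    running base -> apex -> base with consistent orientation; the
    endocardium lies inside the epicardium along the matched
    parameterization.
    """

    endo: np.ndarray
    epi: np.ndarray
    reference_frame: int = 0

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=float)
        self.epi = np.asarray(self.epi, dtype=float)
        for name, c in (("endo", self.endo), ("epi", self.epi)):
            if c.ndim != 2 or c.shape[1] != 2:
                raise ValueError(f"{name} contour must be an (N, 2) point list")
            if c.shape[0] < 16:
                raise ValueError(f"too few points: {name} contour has {c.shape[0]} < 16 points")


@dataclass(frozen=True)
class CorrectionPoint:
    """A manually placed target for one boundary node at one frame."""

    frame: int
    node_id: int
    target: tuple[float, float]


# --------------------------------------------------------------------------
# phase <-> velocity
# --------------------------------------------------------------------------


def phase_to_velocity(phase: np.ndarray, venc: float) -> np.ndarray:
    """Convert stored phase (radians, in [-pi, pi]) to velocity in cm/s.

    Uses the standard linear phase-contrast convention ``v = venc * phi / pi``,
    so full-scale phase maps to +/- VENC.
    """
    if not venc > 0:
        raise ValueError("venc required: venc must be positive")
    phase = np.asarray(phase, dtype=float)
    if np.any(np.abs(phase) > np.pi * (1 + 1e-12)):
        raise ValueError("phase out of range: |phi| must not exceed pi")
    return venc * phase / np.pi


def velocity_to_phase(velocity: np.ndarray, venc: float, wrap: bool = True) -> np.ndarray:
    """Encode velocity (cm/s) as phase; velocities beyond VENC wrap.

    Wrapping maps the nominal phase ``pi * v / venc`` back into ``(-pi, pi]``
    exactly as the scanner's phase reconstruction would (aliasing).
    """
    if not venc > 0:
        raise ValueError("venc required: venc must be positive")
    phi = np.pi * np.asarray(velocity, dtype=float) / venc
    if wrap:
        phi = np.angle(np.exp(1j * phi))
    return phi


# --------------------------------------------------------------------------
# native container
# --------------------------------------------------------------------------

_CONTAINER_KEYS = ("magnitude", "phase_x", "phase_y")


def save_velocity_series(series: VelocityCineSeries, path: str | Path) -> Path:
    """Write a series to the native ``.npz`` container.

    Velocities are stored as phase images (the acquisition-native quantity)
    together with a JSON metadata block; loading converts back through
    :func:`phase_to_velocity`, so a round trip is bit-exact for any series
    whose velocities lie within VENC.
    """
    path = Path(path)
    meta = {
        "pixel_spacing": list(series.pixel_spacing),
        "frame_times": series.frame_times.tolist(),
        "venc": series.venc,
        "view_label": series.view_label,
        "format": "vencstrain-container-v1",
    }
    np.savez(
        path,
        magnitude=series.magnitude,
        phase_x=velocity_to_phase(series.velocity_x, series.venc, wrap=False),
        phase_y=velocity_to_phase(series.velocity_y, series.venc, wrap=False),
        meta=np.array(json.dumps(meta)),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def _load_container(path: Path) -> VelocityCineSeries:
    with np.load(path, allow_pickle=False) as arc:
        missing = [k for k in _CONTAINER_KEYS if k not in arc.files]
        if missing:
            raise SeriesFormatError(f"incomplete series: container lacks {', '.join(missing)}")
        if "meta" not in arc.files:
            raise SeriesFormatError("venc required: container lacks metadata block")
        meta = json.loads(str(arc["meta"]))
        if "venc" not in meta:
            raise SeriesFormatError("venc required: metadata lacks venc")
        venc = float(meta["venc"])
        return VelocityCineSeries(
            magnitude=arc["magnitude"],
            velocity_x=phase_to_velocity(arc["phase_x"], venc),
            velocity_y=phase_to_velocity(arc["phase_y"], venc),
            pixel_spacing=tuple(meta["pixel_spacing"]),
            frame_times=np.asarray(meta["frame_times"], dtype=float),
            venc=venc,
            view_label=meta.get("view_label", "PHANTOM"),
        )


# --------------------------------------------------------------------------
# NIfTI
# --------------------------------------------------------------------------


def save_velocity_series_nifti(series: VelocityCineSeries, stem: str | Path) -> list[Path]:
    """Write a series as three NIfTI files plus a JSON sidecar.

    ``<stem>_mag.nii``, ``<stem>_velx.nii``, ``<stem>_vely.nii`` hold the
    magnitude and decoded velocity components (frames along the third axis);
    ``<stem>_meta.json`` holds venc, frame times and the view label. Pixel
    spacing is carried in the NIfTI affine.
    """
    import nibabel as nib

    stem = Path(stem)
    dx, dy = series.pixel_spacing
    affine = np.diag([dx, dy, 1.0, 1.0])
    paths = []
    for suffix, arr in (
        ("_mag", series.magnitude),
        ("_velx", series.velocity_x),
        ("_vely", series.velocity_y),
    ):
        p = stem.parent / (stem.name + suffix + ".nii")
        # store as (col, row, frame) so the affine's first axis is x
        nib.save(nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), affine), p)
        paths.append(p)
    meta_path = stem.parent / (stem.name + "_meta.json")
    meta_path.write_text(
        json.dumps(
            {
                "venc": series.venc,
                "frame_times": series.frame_times.tolist(),
                "view_label": series.view_label,
                "pixel_spacing": list(series.pixel_spacing),
            }
        )
    )
    paths.append(meta_path)
    return paths


def _load_nifti(stem: Path) -> VelocityCineSeries:
    import nibabel as nib

    files = {s: stem.parent / (stem.name + f"_{s}.nii") for s in ("mag", "velx", "vely")}
    missing = [s for s, p in files.items() if not p.exists()]
    if missing:
        raise SeriesFormatError(f"incomplete series: missing NIfTI component(s) {', '.join(missing)}")
    meta_path = stem.parent / (stem.name + "_meta.json")
    if not meta_path.exists():
        raise SeriesFormatError("venc required: NIfTI sidecar metadata not found")
    meta = json.loads(meta_path.read_text())
    arrays = {}
    for s, p in files.items():
        img = nib.load(p)
        arrays[s] = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
    spacing = meta.get("pixel_spacing")
    if spacing is None:
        zooms = nib.load(files["mag"]).header.get_zooms()
        spacing = [float(zooms[0]), float(zooms[1])]
    return VelocityCineSeries(
        magnitude=arrays["mag"],
        velocity_x=arrays["velx"],
        velocity_y=arrays["vely"],
        pixel_spacing=tuple(spacing),
        frame_times=np.asarray(meta["frame_times"], dtype=float),
        venc=float(meta["venc"]),
        view_label=meta.get("view_label", "PHANTOM"),
    )


# --------------------------------------------------------------------------
# DICOM
# --------------------------------------------------------------------------


def _load_dicom_dir(path: Path) -> VelocityCineSeries:
    """Read a directory of phase-contrast DICOM files.

    Convention (documented in the README): SeriesNumber 1 = magnitude,
    2 = x phase, 3 = y phase; frames ordered by TriggerTime; phase images
    decode to radians through RescaleSlope/RescaleIntercept. VENC is read
    from a ``venc.json`` sidecar in the directory (``{"venc": <cm/s>}``) —
    vendor private VENC tags are out of scope.
    """
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        raise SeriesFormatError("incomplete series: no DICOM files in directory")
    venc_path = path / "venc.json"
    if not venc_path.exists():
        raise SeriesFormatError("venc required: provide a venc.json sidecar")
    venc = float(json.loads(venc_path.read_text())["venc"])

    groups: dict[int, list] = {1: [], 2: [], 3: []}
    for f in files:
        ds = pydicom.dcmread(f)
        sn = int(ds.SeriesNumber)
        if sn in groups:
            groups[sn].append(ds)
    names = {1: "magnitude", 2: "x phase", 3: "y phase"}
    for sn, dss in groups.items():
        if not dss:
            raise SeriesFormatError(f"incomplete series: missing {names[sn]} series")
        dss.sort(key=lambda d: float(getattr(d, "TriggerTime", d.InstanceNumber)))

    def stack(dss):
        out = []
        for ds in dss:
            arr = ds.pixel_array.astype(float)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            out.append(arr * slope + intercept)
        return np.stack(out)

    mag = stack(groups[1])
    phx = stack(groups[2])
    phy = stack(groups[3])
    if not (mag.shape == phx.shape == phy.shape):
        raise SeriesFormatError("inconsistent geometry: DICOM series shapes differ")
    ds0 = groups[1][0]
    # PixelSpacing is (row spacing, col spacing)
    ps = [float(v) for v in ds0.PixelSpacing]
    times = np.array([float(getattr(d, "TriggerTime", i)) for i, d in enumerate(groups[1])])
    return VelocityCineSeries(
        magnitude=mag,
        velocity_x=phase_to_velocity(phx, venc),
        velocity_y=phase_to_velocity(phy, venc),
        pixel_spacing=(ps[1], ps[0]),
        frame_times=times,
        venc=venc,
        view_label="PHANTOM",
    )


def load_velocity_series(path: str | Path, format_hint: str | None = None) -> VelocityCineSeries:
    """Load a velocity-encoded cine series.

    Parameters
    ----------
    path
        ``.npz`` container, a NIfTI stem (``<stem>_mag.nii`` etc. must
        exist), or a DICOM directory.
    format_hint
        One of ``container``, ``nifti``, ``dicom``; inferred from the path
        when omitted.
    """
    path = Path(path)
    if format_hint is None:
        if path.is_dir():
            format_hint = "dicom"
        elif path.suffix == ".npz":
            format_hint = "container"
        else:
            format_hint = "nifti"
    if format_hint == "container":
        if not path.exists():
            raise FileNotFoundError(path)
        return _load_container(path)
    if format_hint == "nifti":
        return _load_nifti(path)
    if format_hint == "dicom":
        return _load_dicom_dir(path)
    raise ValueError(f"unknown format hint {format_hint!r}")


# --------------------------------------------------------------------------
# contours / corrections / reports
# --------------------------------------------------------------------------


def save_contours(contours: ContourSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "endo": contours.endo.tolist(),
                "epi": contours.epi.tolist(),
                "reference_frame": int(contours.reference_frame),
            },
            indent=1,
        )
    )
    return path


def load_contours(path: str | Path) -> ContourSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed contour file {path}: {exc}") from exc
    for key in ("endo", "epi"):
        if key not in doc:
            raise ValueError(f"malformed contour file {path}: missing record {key!r}")
    return ContourSet(
        endo=np.asarray(doc["endo"], dtype=float),
        epi=np.asarray(doc["epi"], dtype=float),
        reference_frame=int(doc.get("reference_frame", 0)),
    )


def save_corrections(corrections: list[CorrectionPoint], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            [
                {"frame": c.frame, "node_id": c.node_id, "target": list(c.target)}
                for c in corrections
            ],
            indent=1,
        )
    )
    return path


def load_corrections(path: str | Path) -> list[CorrectionPoint]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed corrections file {path}: {exc}") from exc
    out = []
    for i, rec in enumerate(doc):
        try:
            out.append(
                CorrectionPoint(
                    frame=int(rec["frame"]),
                    node_id=int(rec["node_id"]),
                    target=(float(rec["target"][0]), float(rec["target"][1])),
                )
            )
        except (KeyError, IndexError, TypeError) as exc:
            raise ValueError(f"malformed corrections file {path}: record {i}: {exc}") from exc
    return out


def save_report(report_df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> Path:
    """Write a sector strain report as CSV (with an optional JSON sidecar)."""
    path = Path(path)
    report_df.to_csv(path, index=False, float_format="%.8g")
    if metadata is not None:
        Path(str(path) + ".meta.json").write_text(json.dumps(metadata, indent=1))
    return path


def load_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
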