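"""I/O layer: phase decoding, containers, contours and reports."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vencstrain import pc_io
from vencstrain.pc_io import (
    ContourSet,
    CorrectionPoint,
    SeriesFormatError,
    VelocityCineSeries,
    load_velocity_series,
    phase_to_velocity,
    save_velocity_series,
    velocity_to_phase,
)


def _tiny_series(frames=3, shape=(6, 5), venc=20.0):
    rng = np.random.default_rng(7)
    return VelocityCineSeries(
        magnitude=rng.uniform(0, 1, (frames,) + shape),
        velocity_x=rng.uniform(-venc, venc, (frames,) + shape),
        velocity_y=rng.uniform(-venc, venc, (frames,) + shape),
        pixel_spacing=(1.5, 1.5),
        frame_times=np.arange(frames) * 50.0,
        venc=venc,
    )


class TestPhaseVelocity:
    @pytest.mark.parametrize(
        "phase, venc, expected",
        [(0.0, 20.0, 0.0), (np.pi, 20.0, 20.0), (-np.pi / 2, 20.0, -10.0)],
    )
    def test_linear_convention(self, phase, venc, expected):
        assert phase_to_velocity(np.array(phase), venc) == pytest.approx(expected)

    def test_out_of_range_phase_rejected(self):
        with pytest.raises(ValueError, match="phase out of range"):
            phase_to_velocity(np.array([3.5]), 20.0)

    def test_nonpositive_venc_rejected(self):
        with pytest.raises(ValueError, match="venc"):
            phase_to_velocity(np.array([0.0]), 0.0)

    @given(
        phi=st.floats(-np.pi, np.pi, allow_nan=False),
        venc=st.floats(1.0, 200.0, allow_nan=False),
    )
    def test_odd_and_invertible(self, phi, venc):
        v = phase_to_velocity(np.array(phi), venc)
        assert phase_to_velocity(np.array(-phi), venc) == pytest.approx(-v)
        assert abs(v) <= venc * (1 + 1e-12)
        assert velocity_to_phase(v, venc, wrap=False) == pytest.approx(phi, abs=1e-9)

    def test_wrapping_aliases_beyond_venc(self):
        # 25 cm/s at VENC 20 aliases to -15 cm/s
        phi = velocity_to_phase(np.array(25.0), 20.0, wrap=True)
        assert phase_to_velocity(phi, 20.0) == pytest.approx(-15.0)


class TestSeriesValidation:
    def test_valid_series_passes(self):
        s = _tiny_series()
        assert s.frames == 3 and s.shape == (6, 5)

    @pytest.mark.parametrize(
        "mutation, message",
        [
            (lambda d: d.update(velocity_y=d["velocity_y"][:, :4]), "inconsistent geometry"),
            (lambda d: d.update(frame_times=np.array([0.0, 50.0, 40.0])), "increasing"),
            (lambda d: d.update(venc=-1.0), "venc"),
            (lambda d: d.update(velocity_x=d["velocity_x"] * 10), "exceeds venc"),
        ],
    )
    def test_invariant_violations_rejected(self, mutation, message):
        s = _tiny_series()
        kwargs = dict(
            magnitude=s.magnitude,
            velocity_x=s.velocity_x,
            velocity_y=s.velocity_y,
            pixel_spacing=s.pixel_spacing,
            frame_times=s.frame_times,
            venc=s.venc,
        )
        mutation(kwargs)
        with pytest.raises(SeriesFormatError, match=message):
            VelocityCineSeries(**kwargs)

    def test_cycle_duration_sums_intervals(self):
        s = _tiny_series(frames=4)
        assert s.cycle_duration() == pytest.approx(200.0)


class TestContainer:
    def test_round_trip_bit_exact(self, tmp_path):
        s = _tiny_series()
        path = save_velocity_series(s, tmp_path / "series.npz")
        loaded = load_velocity_series(path)
        np.testing.assert_array_equal(loaded.magnitude, s.magnitude)
        np.testing.assert_allclose(loaded.velocity_x, s.velocity_x, atol=1e-12)
        np.testing.assert_allclose(loaded.velocity_y, s.velocity_y, atol=1e-12)
        assert loaded.venc == s.venc
        assert loaded.view_label == s.view_label
        np.testing.assert_array_equal(loaded.frame_times, s.frame_times)

    def test_missing_component_reported(self, tmp_path):
        s = _tiny_series()
        p = tmp_path / "bad.npz"
        np.savez(
            p,
            magnitude=s.magnitude,
            phase_x=velocity_to_phase(s.velocity_x, s.venc, wrap=False),
            meta=np.array(json.dumps({"venc": 20.0, "pixel_spacing": [1.5, 1.5], "frame_times": [0, 50, 100]})),
        )
        with pytest.raises(SeriesFormatError, match="incomplete series"):
            load_velocity_series(p)

    def test_missing_venc_reported(self, tmp_path):
        s = _tiny_series()
        p = tmp_path / "novenc.npz"
        np.savez(
            p,
            magnitude=s.magnitude,
            phase_x=velocity_to_phase(s.velocity_x, s.venc, wrap=False),
            phase_y=velocity_to_phase(s.velocity_y, s.venc, wrap=False),
            meta=np.array(json.dumps({"pixel_spacing": [1.5, 1.5], "frame_times": [0, 50, 100]})),
        )
        with pytest.raises(SeriesFormatError, match="venc required"):
            load_velocity_series(p)


class TestNifti:
    def test_round_trip(self, tmp_path):
        s = _tiny_series()
        pc_io.save_velocity_series_nifti(s, tmp_path / "phantom")
        loaded = load_velocity_series(tmp_path / "phantom", format_hint="nifti")
        np.testing.assert_allclose(loaded.velocity_x, s.velocity_x, atol=1e-6)
        np.testing.assert_allclose(loaded.magnitude, s.magnitude, atol=1e-6)
        assert loaded.pixel_spacing == s.pixel_spacing

    def test_missing_component(self, tmp_path):
        s = _tiny_series()
        paths = pc_io.save_velocity_series_nifti(s, tmp_path / "phantom")
        paths[1].unlink()  # remove the x velocity component
        with pytest.raises(SeriesFormatError, match="incomplete series"):
            load_velocity_series(tmp_path / "phantom", format_hint="nifti")


class TestDicom:
    def _write_dicom_dir(self, tmp_path, series):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        slope = 2 * np.pi / 65535.0
        intercept = -np.pi
        inst = 0
        for sn, arr, is_phase in (
            (1, series.magnitude, False),
            (2, velocity_to_phase(series.velocity_x, series.venc, wrap=False), True),
            (3, velocity_to_phase(series.velocity_y, series.venc, wrap=False), True),
        ):
            for k in range(series.frames):
                meta = FileMetaDataset()
                meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
                meta.MediaStorageSOPInstanceUID = generate_uid()
                meta.TransferSyntaxUID = ExplicitVRLittleEndian
                ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
                ds.SOPClassUID = meta.MediaStorageSOPClassUID
                ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
                ds.SeriesNumber = sn
                inst += 1
                ds.InstanceNumber = inst
                ds.TriggerTime = series.frame_times[k]
                ds.PixelSpacing = [series.pixel_spacing[1], series.pixel_spacing[0]]
                ds.Rows, ds.Columns = series.shape
                ds.SamplesPerPixel = 1
                ds.PhotometricInterpretation = "MONOCHROME2"
                ds.BitsAllocated = 16
                ds.BitsStored = 16
                ds.HighBit = 15
                ds.PixelRepresentation = 0
                if is_phase:
                    stored = np.round((arr[k] - intercept) / slope).astype(np.uint16)
                    ds.RescaleSlope = slope
                    ds.RescaleIntercept = intercept
                else:
                    stored = np.round(arr[k] * 1000).astype(np.uint16)
                    ds.RescaleSlope = 0.001
                    ds.RescaleIntercept = 0.0
                ds.PixelData = stored.tobytes()
                ds.save_as(tmp_path / f"img_{sn}_{k}.dcm", enforce_file_format=True)
        (tmp_path / "venc.json").write_text(json.dumps({"venc": series.venc}))

    def test_directory_read(self, tmp_path):
        s = _tiny_series()
        self._write_dicom_dir(tmp_path, s)
        loaded = load_velocity_series(tmp_path)
        # 16-bit quantization of phase limits the velocity precision
        np.testing.assert_allclose(loaded.velocity_x, s.velocity_x, atol=1e-2)
        np.testing.assert_allclose(loaded.velocity_y, s.velocity_y, atol=1e-2)
        assert loaded.pixel_spacing == s.pixel_spacing

    def test_missing_venc_sidecar(self, tmp_path):
        s = _tiny_series()
        self._write_dicom_dir(tmp_path, s)
        (tmp_path / "venc.json").unlink()
        with pytest.raises(SeriesFormatError, match="venc required"):
            load_velocity_series(tmp_path)


class TestContoursCorrections:
    def _contours(self):
        y = np.linspace(0, 50, 30)
        endo = np.column_stack([np.full(30, 10.0), y]) + 0.123456789
        epi = np.column_stack([np.full(30, 20.0), y])
        return ContourSet(endo=endo, epi=epi, reference_frame=2)

    def test_contour_round_trip(self, tmp_path):
        c = self._contours()
        p = pc_io.save_contours(c, tmp_path / "c.json")
        loaded = pc_io.load_contours(p)
        np.testing.assert_allclose(loaded.endo, c.endo, atol=1e-6)
        np.testing.assert_allclose(loaded.epi, c.epi, atol=1e-6)
        assert loaded.reference_frame == 2

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="too few points"):
            ContourSet(endo=np.zeros((3, 2)), epi=np.zeros((30, 2)))

    def test_malformed_file_names_record(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            pc_io.load_contours(p)

    def test_corrections_round_trip(self, tmp_path):
        corr = [CorrectionPoint(frame=5, node_id=12, target=(10.5, 20.25))]
        p = pc_io.save_corrections(corr, tmp_path / "k.json")
        loaded = pc_io.load_corrections(p)
        assert loaded == corr

    def test_malformed_correction_record(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps([{"frame": 1}]))
        with pytest.raises(ValueError, match="record 0"):
            pc_io.load_corrections(p)


def test_report_round_trip(tmp_path):
    import pandas as pd

    rows = [{"sector": s, "e_long_peak": -0.18, "label": ""} for s in range(1, 18)]
    rows.append({"sector": "GLOBAL", "e_long_peak": -0.18, "label": ""})
    df = pd.DataFrame(rows)
    p = pc_io.save_report(df, tmp_path / "report.csv", metadata={"seed": 1})
    loaded = pc_io.load_report(p)
    assert len(loaded) == 18
    assert (tmp_path / "report.csv.meta.json").exists()
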