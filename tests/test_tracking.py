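"""Basis construction, velocity fitting, advection and cycle tracking."""

import numpy as np
import pytest

import vencstrain as vs
from vencstrain import phantom_sim as ps
from vencstrain import tracking as T
from vencstrain.pc_io import CorrectionPoint, VelocityCineSeries


def constant_velocity_series(model_like_spec, vx=5.0, vy=0.0, frames=8):
    """A series whose velocity images are spatially/temporally constant."""
    spec = model_like_spec
    series, _, contours = ps.render_velocity_series(
        ps.PhantomSpec(geometry=spec.geometry, motion="static", frames=frames, noise_sd=0.0)
    )
    return (
        VelocityCineSeries(
            magnitude=series.magnitude,
            velocity_x=np.full_like(series.velocity_x, vx),
            velocity_y=np.full_like(series.velocity_y, vy),
            pixel_spacing=series.pixel_spacing,
            frame_times=series.frame_times,
            venc=series.venc,
        ),
        contours,
    )


class TestBasis:
    def test_centers_equally_spaced_spanning_centerline(self, u_model):
        basis = vs.build_basis(u_model, n_basis=7)
        np.testing.assert_allclose(np.diff(basis.centers_s), 1.0 / 6.0, atol=1e-12)
        assert basis.centers_s[0] == 0.0 and basis.centers_s[-1] == 1.0
        assert basis.width_mm == pytest.approx(u_model.centerline_length / 6.0)

    def test_single_basis_rejected(self, u_model):
        with pytest.raises(ValueError, match="at least 2"):
            vs.build_basis(u_model, n_basis=1)

    def test_partition_of_unity_on_band(self, u_model):
        basis = vs.build_basis(u_model)
        rng = np.random.default_rng(3)
        pts = u_model.material_points.reshape(-1, 2)
        sample = pts[rng.choice(len(pts), 100, replace=False)]
        w = basis.weights_at_points(sample)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_linear_precision_in_arc_length(self, u_model):
        # hat weights reproduce linear functions of s exactly
        basis = vs.build_basis(u_model)
        s = np.linspace(0, 1, 57)
        w = basis.weights_from_s(s)
        np.testing.assert_allclose(w @ basis.centers_s, s, atol=1e-12)


class TestFit:
    def test_zero_field_gives_zero_coefficients(self, u_model, u_spec):
        series, _, _ = ps.render_velocity_series(
            ps.PhantomSpec(motion="static", noise_sd=0.0)
        )
        basis = vs.build_basis(u_model)
        coef, res = T.fit_frame_coefficients(series, 0, u_model.all_points(), basis)
        np.testing.assert_allclose(coef, 0.0, atol=1e-12)
        assert res == pytest.approx(0.0, abs=1e-12)

    def test_constant_field_reproduced_exactly(self, u_spec):
        series, contours = constant_velocity_series(u_spec, vx=3.0, vy=-1.0)
        model = vs.build_model(contours)
        basis = vs.build_basis(model)
        coef, res = T.fit_frame_coefficients(
            series, 0, model.all_points(), basis, lam_smooth=0.0
        )
        np.testing.assert_allclose(coef, np.tile([3.0, -1.0], (7, 1)), atol=1e-9)
        assert res < 1e-9

    def test_recovers_synthesized_coefficients_vs_lstsq_oracle(self, u_model, u_spec):
        # velocity images synthesized from known coefficients a*; the
        # closed-form fit must match both a* and an independent lstsq solve
        rng = np.random.default_rng(5)
        basis = vs.build_basis(u_model)
        a_star = rng.normal(0, 3, (7, 2))
        spec = ps.PhantomSpec(motion="static", noise_sd=0.0)
        series, _, _ = ps.render_velocity_series(spec)
        xx, yy = ps._pixel_grid(spec)
        pix = np.column_stack([xx.ravel(), yy.ravel()])
        v = basis.weights_at_points(pix) @ a_star
        series = VelocityCineSeries(
            magnitude=series.magnitude,
            velocity_x=np.broadcast_to(v[:, 0].reshape(xx.shape), series.magnitude.shape).copy(),
            velocity_y=np.broadcast_to(v[:, 1].reshape(xx.shape), series.magnitude.shape).copy(),
            pixel_spacing=series.pixel_spacing,
            frame_times=series.frame_times,
            venc=series.venc,
        )
        pts = u_model.all_points()
        coef, res = T.fit_frame_coefficients(series, 0, pts, basis, lam_smooth=0.0)
        phi = basis.weights_at_points(pts)
        v_meas = T.sample_velocity(series, 0, pts)
        oracle, *_ = np.linalg.lstsq(phi, v_meas, rcond=None)
        np.testing.assert_allclose(coef, oracle, atol=1e-9)
        np.testing.assert_allclose(coef, a_star, atol=5e-3)  # bilinear sampling error only

    def test_empty_support_rejected(self, u_model, u_spec):
        series, _, _ = ps.render_velocity_series(ps.PhantomSpec(motion="static", frames=2))
        basis = vs.build_basis(u_model)
        with pytest.raises(T.TrackingError, match="no support"):
            T.fit_frame_coefficients(series, 0, np.zeros((0, 2)), basis)

    def test_out_of_range_correction_node_rejected(self, u_model):
        series, _, _ = ps.render_velocity_series(ps.PhantomSpec(motion="static", frames=2))
        basis = vs.build_basis(u_model)
        corr = CorrectionPoint(frame=0, node_id=10_000, target=(0.0, 0.0))
        with pytest.raises(ValueError, match="out of range"):
            T.fit_frame_coefficients(
                series,
                0,
                u_model.all_points(),
                basis,
                corrections=(corr,),
                boundary_positions=u_model.boundary_nodes,
                dt=50.0,
            )

    def test_satisfied_corrections_leave_solution_unchanged(self, u_model):
        # a correction placed exactly where the unconstrained solution puts
        # the node must not change the fit, however large lam_corr becomes
        series, contours = constant_velocity_series(ps.PhantomSpec(), vx=2.0, vy=1.0)
        model = vs.build_model(contours)
        basis = vs.build_basis(model)
        pts = model.all_points()
        dt = 50.0
        coef0, _ = T.fit_frame_coefficients(series, 0, pts, basis, lam_smooth=0.0)
        node = 5
        v_node = basis.weights_at_points(model.boundary_nodes[node][None])[0] @ coef0
        target = model.boundary_nodes[node] + T.MM_PER_CMS_MS * dt * v_node
        for lam_corr in (1.0, 100.0, 1e4):
            coef, _ = T.fit_frame_coefficients(
                series,
                0,
                pts,
                basis,
                corrections=(CorrectionPoint(0, node, tuple(target)),),
                boundary_positions=model.boundary_nodes,
                dt=dt,
                lam_smooth=0.0,
                lam_corr=lam_corr,
            )
            np.testing.assert_allclose(coef, coef0, atol=1e-8)

    def test_correction_pulls_node_toward_target(self, u_model, u_spec):
        series, _, _ = ps.render_velocity_series(
            ps.PhantomSpec(motion="static", noise_sd=0.0)
        )
        basis = vs.build_basis(u_model)
        node = 3
        target = u_model.boundary_nodes[node] + np.array([2.0, 0.0])
        dt = 50.0
        dists = []
        for lam_corr in (0.1, 10.0, 1000.0):
            coef, _ = T.fit_frame_coefficients(
                series,
                0,
                u_model.all_points(),
                basis,
                corrections=(CorrectionPoint(0, node, tuple(target)),),
                boundary_positions=u_model.boundary_nodes,
                dt=dt,
                lam_corr=lam_corr,
            )
            new = T.advect(u_model.boundary_nodes[node][None], basis, coef, dt)[0]
            dists.append(np.linalg.norm(new - target))
        assert dists[0] > dists[1] > dists[2]
        assert dists[2] < 0.05  # strong weight nearly satisfies the correction


class TestAdvect:
    def test_zero_coefficients_identity(self, u_model):
        basis = vs.build_basis(u_model)
        pts = u_model.boundary_nodes
        np.testing.assert_array_equal(T.advect(pts, basis, np.zeros((7, 2)), 50.0), pts)

    def test_unit_conversion(self, u_model):
        # 10 cm/s = 0.1 mm/ms, so 50 ms moves every point by 5 mm
        basis = vs.build_basis(u_model)
        coef = np.tile([10.0, 0.0], (7, 1))
        pts = u_model.boundary_nodes
        moved = T.advect(pts, basis, coef, 50.0)
        np.testing.assert_allclose(moved - pts, [[5.0, 0.0]] * len(pts), atol=1e-9)

    def test_midpoint_beats_euler_on_rotating_field(self, u_model):
        basis = vs.build_basis(u_model)
        center = np.array([47.0, 60.0])
        coef = np.zeros((7, 2))
        for i, xy in enumerate(basis.centers_xy):
            r = xy - center
            coef[i] = 20.0 * np.array([-r[1], r[0]]) / np.linalg.norm(r)
        pts = u_model.boundary_nodes[:10]
        p_e = T.advect(T.advect(pts, basis, coef, 100.0), basis, coef, 100.0)
        p_m = T.advect(
            T.advect(pts, basis, coef, 100.0, method="midpoint"),
            basis,
            coef,
            100.0,
            method="midpoint",
        )
        p_ref = pts.copy()
        for _ in range(400):  # fine-step reference integration
            p_ref = T.advect(p_ref, basis, coef, 0.5)
        err_e = np.linalg.norm(p_e - p_ref, axis=1).mean()
        err_m = np.linalg.norm(p_m - p_ref, axis=1).mean()
        assert err_m / err_e < 0.5

    def test_unknown_integrator(self, u_model):
        basis = vs.build_basis(u_model)
        with pytest.raises(ValueError, match="integrator"):
            T.advect(u_model.boundary_nodes, basis, np.zeros((7, 2)), 50.0, method="rk9")


class TestTrackCycle:
    def test_zero_velocity_series_static(self, u_model):
        series, _, _ = ps.render_velocity_series(
            ps.PhantomSpec(motion="static", noise_sd=0.0)
        )
        traj = vs.track_cycle(series, u_model)
        assert np.all(traj.positions == traj.positions[0])
        np.testing.assert_allclose(traj.residuals, 0.0, atol=1e-12)
        assert T.closure_error(traj) == pytest.approx(0.0, abs=1e-12)

    def test_reference_frame_positions_exact(self, strip_clean):
        traj = strip_clean["traj"]
        model = strip_clean["model"]
        np.testing.assert_array_equal(
            traj.positions[traj.reference_frame], model.all_points()
        )

    def test_rigid_translation_preserves_distances(self):
        spec = ps.PhantomSpec(motion="translation", translation=(3.0, -2.0), noise_sd=0.0)
        series, _, contours = ps.render_velocity_series(spec)
        model = vs.build_model(contours)
        traj = vs.track_cycle(series, model)
        bp = traj.boundary_positions
        ref_d = np.linalg.norm(bp[0, :-5] - bp[0, 5:], axis=-1)
        for k in range(series.frames):
            d = np.linalg.norm(bp[k, :-5] - bp[k, 5:], axis=-1)
            np.testing.assert_allclose(d, ref_d, atol=1e-6)

    def test_tracks_phantom_compression_boundary(self):
        # pure uniaxial compression (fully within the deformation-model span);
        # 32 frames keep the forward-Euler temporal truncation transient small
        spec = ps.PhantomSpec(geometry="STRIP", mode="uniaxial", frames=32, noise_sd=0.0)
        series, _, contours = ps.render_velocity_series(spec)
        model = vs.build_model(contours)
        traj = vs.track_cycle(series, model)
        for k in range(series.frames):
            map_fn, _, _ = ps.analytic_motion(spec, series.frame_times[k])
            true_b = map_fn(model.boundary_nodes)
            err = np.sqrt(np.mean(np.sum((traj.boundary_positions[k] - true_b) ** 2, axis=1)))
            assert err < 0.5, f"frame {k}: boundary RMS {err:.3f} mm"

    def test_interior_boundary_slaving_mode(self, strip_clean):
        series, model = strip_clean["series"], strip_clean["model"]
        traj = vs.track_cycle(series, model, interior_mode="boundary")
        field = vs.compute_strain_field(traj, model)
        peak = field.global_curve().min()
        assert peak == pytest.approx((0.85**2 - 1) / 2, abs=0.01)

    def test_correction_frame_out_of_range(self, strip_clean):
        with pytest.raises(ValueError, match="outside series"):
            vs.track_cycle(
                strip_clean["series"],
                strip_clean["model"],
                corrections=[CorrectionPoint(99, 0, (0.0, 0.0))],
            )


class TestClosure:
    def test_constant_velocity_drift(self, u_spec):
        series, contours = constant_velocity_series(u_spec, vx=4.0, vy=0.0, frames=10)
        model = vs.build_model(contours)
        traj = vs.track_cycle(series, model)
        expected = 4.0 * T.MM_PER_CMS_MS * series.cycle_duration()
        assert T.closure_error(traj) == pytest.approx(expected, abs=1e-6)

    def test_fine_sampling_periodic_motion_closes(self):
        spec = ps.PhantomSpec(geometry="STRIP", frames=64, noise_sd=0.0)
        series, _, contours = ps.render_velocity_series(spec)
        model = vs.build_model(contours)
        traj = vs.track_cycle(series, model)
        assert T.closure_error(traj) < 0.2

    def test_drift_compensation_removes_linear_drift(self, u_spec):
        series, contours = constant_velocity_series(u_spec, vx=4.0, vy=0.0, frames=10)
        model = vs.build_model(contours)
        traj = vs.track_cycle(series, model, drift_compensation=True)
        assert traj.drift_compensated
        # compensated positions return to the reference at wrap-around
        np.testing.assert_array_equal(
            traj.positions[traj.reference_frame], model.all_points()
        )


def test_sample_velocity_clamps_and_warns(u_spec, caplog):
    series, _, _ = ps.render_velocity_series(ps.PhantomSpec(motion="static", frames=2))
    import logging

    with caplog.at_level(logging.WARNING, logger="vencstrain.tracking"):
        v = T.sample_velocity(series, 0, np.array([[-50.0, -50.0]]))
    assert v.shape == (1, 2)
    assert any("left the image bounds" in r.message for r in caplog.records)
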