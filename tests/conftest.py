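"""Shared fixtures: simulated phantom acquisitions tracked once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vencstrain as vs
from vencstrain import phantom_sim as ps

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def strip_clean():
    """Noise-free uniaxial-analogue compression of a straight strip phantom,
    tracked with default settings (incompressible transverse bulge)."""
    spec = ps.PhantomSpec(geometry="STRIP", noise_sd=0.0)
    series, gt, contours = ps.render_velocity_series(spec)
    model = vs.build_model(contours)
    basis = vs.build_basis(model)
    traj = vs.track_cycle(series, model, basis)
    field = vs.compute_strain_field(traj, model)
    return {
        "spec": spec,
        "series": series,
        "gt": gt,
        "contours": contours,
        "model": model,
        "basis": basis,
        "traj": traj,
        "field": field,
    }


@pytest.fixture(scope="session")
def u_spec():
    return ps.PhantomSpec()


@pytest.fixture(scope="session")
def u_contours(u_spec):
    return ps.phantom_contours(u_spec)


@pytest.fixture(scope="session")
def u_model(u_contours):
    return vs.build_model(u_contours)


@pytest.fixture(scope="session")
def cross_method():
    """The full velocity-vs-optical U-phantom comparison (seeded)."""
    from vencstrain import validation

    return validation.phantom_cross_method_experiment(seed=1)


def make_trajectory_stub(material_positions, model, frame_times=None):
    """Minimal trajectory-like object for feeding positions to the strain
    module directly (e.g. analytic ground-truth trajectories)."""
    material_positions = np.asarray(material_positions, dtype=float)

    class _Stub:
        pass

    stub = _Stub()
    stub.material_positions = material_positions
    stub.n_frames = material_positions.shape[0]
    stub.grid_shape = (model.n_s, model.n_d)
    stub.reference_frame = 0
    stub.frame_times = (
        np.arange(stub.n_frames, dtype=float) if frame_times is None else frame_times
    )
    stub.n_boundary = 0
    return stub
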