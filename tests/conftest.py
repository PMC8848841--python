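"""Shared fixtures: one synthetic elbow reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from elbowaxis import synthetic_data as synth
from elbowaxis.axis_estimation import EstimatorConfig, estimate_instantaneous_axis

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def params() -> synth.ElbowParams:
    return synth.ElbowParams()


@pytest.fixture(scope="session")
def humerus(params):
    return synth.make_distal_humerus(params)


@pytest.fixture(scope="session")
def ulna(params):
    return synth.make_proximal_ulna(params)


@pytest.fixture(scope="session")
def fixed_sequence(ulna, humerus):
    """30-frame hinge sequence about the fixed transcondylar axis."""
    _, humerus_truth = humerus
    traj = synth.fixed_axis_trajectory()
    return synth.pose_sequence(ulna, traj, humerus_truth)


@pytest.fixture(scope="session")
def estimator_config():
    return EstimatorConfig()


@pytest.fixture(scope="session")
def fixed_axes(fixed_sequence, estimator_config):
    """Estimated per-frame axes of the noiseless fixed-axis sequence."""
    meshes, landmarks, _ = fixed_sequence
    return [
        estimate_instantaneous_axis(m, l, estimator_config, frame_index=i)
        for i, (m, l) in enumerate(zip(meshes, landmarks))
    ]


@pytest.fixture(scope="session")
def drifting_fixture_dir(tmp_path_factory):
    from elbowaxis.pipeline import make_fixture

    out = tmp_path_factory.mktemp("drifting_fixture")
    make_fixture("drifting_axis", out, seed=11)
    return out


@pytest.fixture(scope="session")
def drifting_result(drifting_fixture_dir):
    from elbowaxis.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(input_dir=drifting_fixture_dir))


def direction_error_deg(d1: np.ndarray, d2: np.ndarray) -> float:
    """Angle between two axis directions, sign-insensitive."""
    return float(np.rad2deg(np.arccos(np.clip(abs(np.dot(d1, d2)), -1.0, 1.0))))
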