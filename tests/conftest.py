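import numpy as np
import pytest

from kneesquat.pipeline import ScenarioConfig, run_release_comparison
from kneesquat.solver import KneeModel


@pytest.fixture(scope="session")
def release_report():
    """Full default 3-scenario PCL-release comparison (0 / 50 / 75 %).

    This is the expensive end-to-end run shared by the acceptance tests:
    30 load steps, 150 mm hip drop, 1.5 mm contact resolution, GRF control.
    """
    return run_release_comparison(ScenarioConfig(), (0.0, 50.0, 75.0))


@pytest.fixture(scope="session")
def release_frames(release_report):
    return {r: tr.to_frame() for r, tr in release_report.traces.items()}


@pytest.fixture(scope="session")
def coarse_model():
    """Coarsely discretized model for fast single-step solver tests."""
    return KneeModel.build_default(contact_spacing=2.5)


@pytest.fixture(scope="session")
def coarse_first_step(coarse_model):
    state = coarse_model.initial_state()
    return coarse_model.solve_load_step(state, 0.0, 60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
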