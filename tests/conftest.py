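import numpy as np
import pytest

from prebound import synthetic_data as sd


@pytest.fixture(scope="session")
def template_complex():
    """The synthetic two-chain complex in the bound pose (r = 2.65 nm)."""
    return sd.make_template_complex()


@pytest.fixture(scope="session")
def template_spec():
    return sd.template_reference_spec()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture(scope="session")
def small_two_state():
    """A small generated two-state trajectory with ground truth (shared)."""
    plan = sd.TwoStateTrajectoryPlan.defaults(n_frames_per_state=40, seed=11)
    return sd.generate_two_state_trajectory(plan)
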