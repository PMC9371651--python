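import warnings

import numpy as np
import pytest

import dgpop


@pytest.fixture(autouse=True)
def _quiet_clipping():
    # strongly tuned fixtures intentionally saturate the per-frame event
    # probability; the warning is part of the contract but noisy in tests
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*clipping p to 1")
        yield


@pytest.fixture(scope="session")
def of_trajectory():
    """Short default-parameter open-field trajectory (300 s at 3 Hz)."""
    return dgpop.simulate_of_trajectory(duration=300.0, seed=11)


@pytest.fixture(scope="session")
def of_state(of_trajectory):
    kin = dgpop.compute_kinematics(of_trajectory)
    return kin, dgpop.discretize_states(kin, of_trajectory)


@pytest.fixture(scope="session")
def tuned_recording(of_trajectory):
    """Strongly tuned 20-neuron population on the short trajectory."""
    spec = dgpop.make_tuning_spec(
        n_neurons=20,
        seed=12,
        baseline_rate=0.1,
        gain_ranges={"place_gain_max": 20.0},
    )
    return dgpop.generate_events(of_trajectory, spec, seed=13), spec


@pytest.fixture(scope="session")
def tmaze_session():
    """50-trial T-maze session with LR-tuned neurons."""
    spec = dgpop.make_tuning_spec(n_neurons=30, seed=21, baseline_rate=0.1)
    return dgpop.simulate_tmaze_session(spec=spec, seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
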