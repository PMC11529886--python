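import numpy as np
import pytest

from menotaxis import BehaviorPolicy, NoiseModel, build_schedule, simulate_fly


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise-off limit: huge concentration, no stops."""
    return NoiseModel(kappa=1e6, stop_rate_per_min=0.0)


@pytest.fixture(scope="session")
def long_constant_schedule():
    return build_schedule("long_constant", seed=11)


@pytest.fixture(scope="session")
def maintain_trace(long_constant_schedule):
    """One well-behaved fly on the 20 min constant-LED paradigm."""
    trace, truth = simulate_fly(
        BehaviorPolicy(kind="maintain_relative"),
        NoiseModel(kappa=4.0, stop_rate_per_min=0.0),
        long_constant_schedule,
        seed=77,
    )
    return trace, truth
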