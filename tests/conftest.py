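import numpy as np
import pytest

from acudyn import synthio


@pytest.fixture(scope="session")
def small_dimer():
    """A 500-frame three-state dimer run with ground truth (session-cached)."""
    spec = synthio.DimerSpec(n_frames=500, seed=321)
    return synthio.gen_dimer_trajectory(spec)


@pytest.fixture(scope="session")
def complex_runs():
    """Bound-complex trajectories for two contrasting conditions."""
    conditions = {
        "apo": synthio.ComplexCondition(sigma=3.0),
        "AMP": synthio.ComplexCondition(sigma=0.75),
    }
    return synthio.gen_complex_trajectory(conditions, n_frames=1500, seed=99)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
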