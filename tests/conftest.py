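import numpy as np
import pytest

from mutburden import SimulationConfig, run


@pytest.fixture(scope="session")
def birth_death_state():
    """One full-tracking birth-death realisation (beta=2/3, mu=2, N=80)."""
    cfg = SimulationConfig(
        beta=2 / 3, mu=2.0, stop=("size", 80), track_matrix=True
    )
    return run(cfg, rng=np.random.default_rng(2024)).state


@pytest.fixture(scope="session")
def pure_birth_state():
    """One full-tracking pure-birth realisation (mu=2, N=120)."""
    cfg = SimulationConfig(beta=1.0, mu=2.0, stop=("size", 120), track_matrix=True)
    return run(cfg, rng=np.random.default_rng(7)).state
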