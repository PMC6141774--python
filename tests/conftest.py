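import numpy as np
import pytest
from hypothesis import settings

from cyclekinetics import PhaseDurations, PopulationConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def phases():
    """Reference kinetics: T_G1=5, T_S=4, T_G2=1.5, T_M=0.5 (T_C=11 h)."""
    return PhaseDurations(5.0, 4.0, 1.5, 0.5)


@pytest.fixture
def make_config():
    def _make(n_cells=10_000, seed=0, **kw):
        return PopulationConfig(n_cells=n_cells, seed=seed, **kw)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
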