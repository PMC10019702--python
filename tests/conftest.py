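import numpy as np
import pytest

from hopfstrat.connectome import StructuralConnectome, normalize_rows
from hopfstrat.oscillator import SimulationConfig, draw_intrinsic_frequencies


def random_connectome(n: int, seed: int) -> StructuralConnectome:
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    np.fill_diagonal(w, 0.0)
    return StructuralConnectome(normalize_rows(w))


@pytest.fixture(scope="session")
def conn12() -> StructuralConnectome:
    return random_connectome(12, seed=123)


@pytest.fixture(scope="session")
def omega12() -> np.ndarray:
    return draw_intrinsic_frequencies(12, seed=124)


@pytest.fixture(scope="session")
def short_config() -> SimulationConfig:
    """Short but valid run: 70 s with 10 s burn-in -> 31 samples at TR 2."""
    return SimulationConfig(dt=0.05, duration=70.0, burn_in=10.0,
                            sample_interval=2.0, seed=7)
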