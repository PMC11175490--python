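import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from finestrat import StratifiedPopulation, Stratum

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)


@pytest.fixture
def two_stratum_population():
    """Tiny two-stratum frame with integer y, suitable for exact enumeration."""
    return StratifiedPopulation(
        [
            Stratum(id="a", x=0.5, y=[1.0, 2.0, 3.0, 4.0]),
            Stratum(id="b", x=1.0, y=[5.0, 7.0, 9.0]),
        ]
    )


def toy_population(H: int, seed: int = 0, max_size: int = 4) -> StratifiedPopulation:
    """Random small population: H strata on the grid x_i = i/H, integer y."""
    rng = np.random.default_rng(seed)
    return StratifiedPopulation(
        [
            Stratum(
                id=i,
                x=i / H,
                y=rng.integers(0, 10, size=int(rng.integers(2, max_size + 1))).astype(float),
            )
            for i in range(1, H + 1)
        ]
    )
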