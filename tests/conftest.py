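import numpy as np
import pytest

from pulsechase import RateSet


@pytest.fixture(scope="session")
def reference_rates() -> RateSet:
    """The HeLa-protein reference rates used throughout (1/min)."""
    return RateSet(kappa10=0.0109, kappa12=0.0189, kappa20=0.0002)


@pytest.fixture(scope="session")
def chase_grid() -> np.ndarray:
    """Default chase census grid: 0..480 min in steps of 40."""
    return np.arange(0.0, 481.0, 40.0)


def random_rates(rng: np.random.Generator, degenerate_every: int = 0, i: int = 0) -> RateSet:
    """Log-uniform rates over the calibration box; optionally near-degenerate."""
    k = 10.0 ** rng.uniform(-5, 0, size=3)
    if degenerate_every and i % degenerate_every == 0:
        gap = 10.0 ** rng.uniform(-14, -6)
        k[2] = (k[0] + k[1]) * (1.0 + gap)
    return RateSet(*map(float, k))
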