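import numpy as np
import pytest

from cgtree import SurvivalSample, TwoSampleData


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def random_sample(rng, n, censor_frac=0.4, tie_prob=0.0) -> SurvivalSample:
    """Random right-censored sample; optional ties via rounding."""
    x = rng.exponential(size=n)
    if tie_prob > 0:
        round_mask = rng.random(n) < tie_prob
        x = np.where(round_mask, np.round(x, 1), x)
        x = np.maximum(x, 1e-3)
    delta = (rng.random(n) > censor_frac).astype(int)
    return SurvivalSample(x, delta)


def random_two_sample(rng, n1, n2, shift=1.0, **kw) -> TwoSampleData:
    g1 = random_sample(rng, n1, **kw)
    g2 = random_sample(rng, n2, **kw)
    return TwoSampleData(g1, SurvivalSample(g2.x * shift, g2.delta))


@pytest.fixture
def small_two_sample(rng):
    return random_two_sample(rng, 8, 9)
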