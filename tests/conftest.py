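import numpy as np
import pytest

from lookmix import LookingMixture, TrialSeries, example_infant


@pytest.fixture
def example_series() -> TrialSeries:
    return example_infant()


@pytest.fixture
def fig_long_model() -> LookingMixture:
    """Archetypal long-looker: bands hugging the range boundaries."""
    return LookingMixture(a=-130, f=130, b=-119, e=118, lam=0.5, pi=0.0)


def random_mixture(rng: np.random.Generator) -> LookingMixture:
    """A random valid mixture, occasionally with an absent band."""
    a = rng.uniform(-130, -10)
    f = rng.uniform(10, 130)
    b = rng.uniform(a, -1)
    e = rng.uniform(1, f)
    lam = rng.uniform()
    pi = rng.uniform()
    kind = rng.integers(0, 10)
    if kind == 0:
        return LookingMixture(a=a, f=f, b=b, e=None, lam=1.0, pi=pi)
    if kind == 1:
        return LookingMixture(a=a, f=f, b=None, e=e, lam=0.0, pi=pi)
    return LookingMixture(a=a, f=f, b=b, e=e, lam=lam, pi=pi)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230914)
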