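import numpy as np
import pytest
from hypothesis import settings
from scipy import stats

from vitalcentiles.distributions import VALUE_BINS, AgeGroupDistribution, ValueHistogram

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def discretized_gaussian_pmf(mean: float, sd: float) -> np.ndarray:
    """Exact pmf of a gaussian rounded to the integer bins 1..299."""
    pmf = stats.norm.cdf(VALUE_BINS + 0.5, mean, sd) - stats.norm.cdf(
        VALUE_BINS - 0.5, mean, sd
    )
    return pmf / pmf.sum()


def group_dist(pmf: np.ndarray, variable: str = "HR", age_group: str = "0-3 months"):
    return AgeGroupDistribution(
        age_group=age_group, variable=variable, pmf=pmf, n_patients=1
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def gaussian_group():
    """Mesokurtic HR-like group distribution, mean 120, sd 10."""
    return group_dist(discretized_gaussian_pmf(120.0, 10.0))


@pytest.fixture(scope="session")
def leptokurtic_group(rng):
    """Right-skewed heavy-tailed mean-BP-like group distribution."""
    n = 200_000
    z = rng.standard_normal(n)
    x = 70.0 + 8.0 * np.sinh((np.arcsinh(z) + 0.6) / 0.55)
    x = np.clip(np.round(x), 1, 299).astype(int)
    return group_dist(ValueHistogram.from_values("MBP", x).pmf, variable="MBP")
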