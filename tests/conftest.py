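import numpy as np
import pandas as pd
import pytest

from mmtrend import CommunitySeries, TruthSpec, simulate_dataset


@pytest.fixture()
def rng():
    """Fresh, identically seeded generator per test (order-independent)."""
    return np.random.default_rng(20240930)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two communities, one country, 30 years, known constant MMT of 20 C."""
    spec = TruthSpec(
        n_countries=1,
        communities_per_country=2,
        seed=11,
        country_mean_range=(14.0, 14.0),
        community_mean_sd=0.0,
        mmt_offset=6.0,
        mmt_slope=0.0,
        baseline_deaths=25.0,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def five_year_series():
    """One synthetic 5-year community series with a U-shaped signal."""
    gen = np.random.default_rng(7)
    dates = pd.date_range("1986-01-01", "1990-12-31", freq="D")
    n = len(dates)
    t = np.arange(n)
    tmean = 14.0 + 8.0 * np.sin(2 * np.pi * t / 365.25) + gen.normal(0, 2, n)
    lam = 25.0 * np.exp(0.002 * (tmean - 20.0) ** 2)
    deaths = gen.poisson(lam).astype(float)
    return CommunitySeries(
        community_id="X01-M01",
        country_id="X01",
        region="East Asia",
        climate_zone="temperate",
        dates=dates,
        deaths=deaths,
        tmean=tmean,
    )
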