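"""Synthetic multicountry daily mortality-temperature data with known truth.

The generator emulates the statistical structure the two-stage analysis
assumes: each community has a seasonal daily mean temperature with a linear
warming trend and AR(1) noise, and overdispersed daily death counts whose
log rate is a baseline plus seasonality, day-of-week effects, and a
U-shaped lag-distributed temperature term

    log lam_t = log(b) + seasonality + dow + sum_l w(l) * kappa * (x_{t-l} - MMT*_w)^2

with exponential lag decay w(l) (normalized to sum 1 over lags 0..L) and a
true minimum mortality temperature MMT*_w that is constant within each
5-year subperiod and moves linearly across subperiods.  Counts are drawn
from a negative binomial with mean lam_t and variance phi * lam_t, so the
quasi-Poisson first stage sees genuine overdispersion.  Country- and
community-level deviations of the MMT intercept and slope provide the
heterogeneity the second-stage meta-regression estimates.

Every quantity the pipeline later estimates (true MMT and its percentile
per community and subperiod, the true trend slope, the true random-effect
variances) is emitted alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .first_stage import CommunitySeries, mmt_to_percentile

_REGIONS = (
    "North America", "Central America", "South America", "North Europe",
    "Central Europe", "South Europe", "South Africa", "Middle East",
    "East Asia", "South-East Asia", "Australia",
)


@dataclass
class TruthSpec:
    """Ground-truth parameters of the synthetic study."""

    n_countries: int = 10
    communities_per_country: int = 5
    start_year: int = 1986
    end_year: int = 2015
    subperiod_width: int = 5
    # temperature model
    country_mean_range: tuple[float, float] = (6.0, 24.0)
    community_mean_sd: float = 1.5
    seasonal_amplitude: float = 8.0
    warming_per_decade: float = 0.3
    ar1_rho: float = 0.6
    ar1_sd: float = 2.0
    # mortality model
    baseline_deaths: float = 30.0
    mortality_seasonal_amplitude: float = 0.10
    dow_log_effects: tuple[float, ...] = (0.0, -0.01, -0.01, 0.0, 0.01, 0.03, 0.02)
    overdispersion: float = 1.5
    # exposure-response truth
    mmt_offset: float = 6.0          # true MMT at w=1, deg C above community mean
    mmt_slope: float = 0.0           # deg C per subperiod
    curvature: float = 0.004         # log-RR per deg C^2, cumulated over lags
    lag_half_life: float = 3.0       # days
    max_lag: int = 21
    # heterogeneity (SDs of random deviations in the true MMT model)
    country_intercept_sd: float = 0.0
    country_slope_sd: float = 0.0
    community_intercept_sd: float = 0.0
    community_slope_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_deaths <= 0:
            raise ValueError("baseline_deaths must be positive")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")
        if self.curvature < 0:
            raise ValueError("curvature must be >= 0 (U-shape)")


def _dates(spec: TruthSpec) -> pd.DatetimeIndex:
    return pd.date_range(
        f"{spec.start_year}-01-01", f"{spec.end_year}-12-31", freq="D"
    )


def simulate_temperature(
    spec: TruthSpec,
    community_mean: float,
    dates: pd.DatetimeIndex,
    rng: np.random.Generator,
) -> np.ndarray:
    """Daily mean temperature: mean + annual sinusoid + warming + AR(1)."""
    doy = dates.dayofyear.values.astype(float)
    years_elapsed = (dates - dates[0]).days.values / 365.25
    seasonal = spec.seasonal_amplitude * np.sin(2.0 * np.pi * (doy - 114.0) / 365.25)
    warming = spec.warming_per_decade / 10.0 * years_elapsed
    eps = rng.standard_normal(len(dates)) * spec.ar1_sd * np.sqrt(
        1.0 - spec.ar1_rho**2
    )
    noise = lfilter([1.0], [1.0, -spec.ar1_rho], eps)
    return community_mean + seasonal + warming + noise


def _lag_weights(spec: TruthSpec) -> np.ndarray:
    w = np.exp(-np.arange(spec.max_lag + 1) * np.log(2.0) / spec.lag_half_life)
    return w / w.sum()


def _subperiod_index(dates: pd.DatetimeIndex, spec: TruthSpec) -> np.ndarray:
    return (dates.year.values - spec.start_year) // spec.subperiod_width + 1


def simulate_mortality(
    temps: np.ndarray,
    dates: pd.DatetimeIndex,
    spec: TruthSpec,
    mmt_by_period: dict[int, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Daily death counts from the U-shaped lagged exposure-response.

    The series start is padded with the first temperature so lagged
    exposures are defined from day 0.
    """
    temps = np.asarray(temps, dtype=float)
    n = len(temps)
    w_l = _lag_weights(spec)
    wvec = _subperiod_index(dates, spec)
    mmt_t = np.array([mmt_by_period[w] for w in wvec])

    padded = np.r_[np.full(spec.max_lag, temps[0]), temps]
    excess = np.zeros(n)
    for lag in range(spec.max_lag + 1):
        xl = padded[spec.max_lag - lag : spec.max_lag - lag + n]
        excess += w_l[lag] * spec.curvature * (xl - mmt_t) ** 2

    doy = dates.dayofyear.values.astype(float)
    seasonal = spec.mortality_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - 15.0) / 365.25
    )
    dow = np.asarray(spec.dow_log_effects)[dates.weekday.values]
    lam = spec.baseline_deaths * np.exp(seasonal + dow + excess)

    phi = spec.overdispersion
    if phi <= 1.0 + 1e-12:
        return rng.poisson(lam).astype(float)
    size = lam / (phi - 1.0)  # NB with mean lam, variance phi*lam
    return rng.negative_binomial(size, 1.0 / phi).astype(float)


def _zone(mean_temp: float) -> str:
    if mean_temp >= 22.0:
        return "tropical"
    if mean_temp >= 18.0:
        return "dry"
    if mean_temp >= 10.0:
        return "temperate"
    return "continental"


def simulate_dataset(spec: TruthSpec) -> tuple[list[CommunitySeries], pd.DataFrame]:
    """Generate the full multicountry dataset plus its truth table.

    Returns the list of community series and a frame with one row per
    (community, subperiod) carrying the true MMT, its percentile under the
    simulated temperatures of that subperiod, and the labels.
    """
    dates = _dates(spec)
    wvec = _subperiod_index(dates, spec)
    n_periods = int(wvec.max())
    root = np.random.SeedSequence(spec.seed)
    struct_rng = np.random.default_rng(root.spawn(1)[0])

    country_means = struct_rng.uniform(*spec.country_mean_range, spec.n_countries)
    dataset: list[CommunitySeries] = []
    truth_rows: list[dict] = []
    for ci in range(spec.n_countries):
        country_id = f"C{ci + 1:02d}"
        region = _REGIONS[ci % len(_REGIONS)]
        c_int = struct_rng.normal(0.0, spec.country_intercept_sd)
        c_slope = struct_rng.normal(0.0, spec.country_slope_sd)
        for mj in range(spec.communities_per_country):
            community_id = f"{country_id}-M{mj + 1:02d}"
            a_int = struct_rng.normal(0.0, spec.community_intercept_sd)
            b_slope = struct_rng.normal(0.0, spec.community_slope_sd)
            mean_temp = country_means[ci] + struct_rng.normal(
                0.0, spec.community_mean_sd
            )
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed % 2**31, ci, mj, 7])
            )
            temps = simulate_temperature(spec, mean_temp, dates, rng)
            mmt_by_period = {
                w: mean_temp
                + spec.mmt_offset
                + c_int
                + a_int
                + (spec.mmt_slope + c_slope + b_slope) * (w - 1)
                for w in range(1, n_periods + 1)
            }
            deaths = simulate_mortality(temps, dates, spec, mmt_by_period, rng)
            zone = _zone(mean_temp)
            dataset.append(
                CommunitySeries(
                    community_id=community_id,
                    country_id=country_id,
                    region=region,
                    climate_zone=zone,
                    dates=dates,
                    deaths=deaths,
                    tmean=temps,
                )
            )
            for w in range(1, n_periods + 1):
                sub_temps = temps[wvec == w]
                truth_rows.append(
                    {
                        "community_id": community_id,
                        "country_id": country_id,
                        "region": region,
                        "climate_zone": zone,
                        "w": w,
                        "true_mmt": mmt_by_period[w],
                        "true_mmtp": mmt_to_percentile(mmt_by_period[w], sub_temps),
                        "true_slope": spec.mmt_slope + c_slope + b_slope,
                    }
                )
    return dataset, pd.DataFrame(truth_rows)


def write_dataset(
    dataset: list[CommunitySeries], truth: pd.DataFrame, outdir
) -> None:
    """Write per-community CSVs, a metadata CSV, and the truth table."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for s in dataset:
        pd.DataFrame(
            {"date": s.dates.strftime("%Y-%m-%d"), "deaths": s.deaths.astype(int),
             "tmean": s.tmean}
        ).to_csv(outdir / f"{s.community_id}.csv", index=False)
        meta.append(
            {
                "community_id": s.community_id,
                "country_id": s.country_id,
                "region": s.region,
                "climate_zone": s.climate_zone,
            }
        )
    pd.DataFrame(meta).to_csv(outdir / "metadata.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)


def read_dataset(indir) -> list[CommunitySeries]:
    """Read community CSVs + metadata.csv back into CommunitySeries."""
    from pathlib import Path

    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv")
    out = []
    for _, row in meta.iterrows():
        df = pd.read_csv(indir / f"{row.community_id}.csv")
        out.append(
            CommunitySeries(
                community_id=row.community_id,
                country_id=row.country_id,
                region=row.region,
                climate_zone=row.climate_zone,
                dates=pd.DatetimeIndex(pd.to_datetime(df["date"])),
                deaths=df["deaths"].to_numpy(dtype=float),
                tmean=df["tmean"].to_numpy(dtype=float),
            )
        )
    return out


def simulate_memr_records(
    n_countries: int = 10,
    communities_per_country: int = 4,
    n_periods: int = 6,
    alpha: float = 19.0,
    beta: float = 0.2,
    kappa: float = 0.0,
    psi_country: np.ndarray | None = None,
    psi_community: np.ndarray | None = None,
    sd_range: tuple[float, float] = (0.5, 1.5),
    at_base_range: tuple[float, float] = (8.0, 22.0),
    at_trend: float = 0.0,
    at_noise_sd: float = 0.3,
    region_labels: list[str] | None = None,
    region_slope_shift: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate SubperiodRecords directly from the pooling model.

    estimate = alpha + (beta + region shift + random slopes) * w
               + kappa * AT + random intercepts + N(0, sd^2)

    with AT_ijw = base_ij + at_trend*(w-1) + noise.  Used to exercise the
    second stage in isolation (heterogeneity tests, AT adjustment, CI
    coverage) with known truth.
    """
    rng = np.random.default_rng(seed)
    if psi_country is None:
        psi_country = np.zeros((2, 2))
    if psi_community is None:
        psi_community = np.zeros((2, 2))
    lc = np.linalg.cholesky(psi_country + 1e-12 * np.eye(2))
    lm = np.linalg.cholesky(psi_community + 1e-12 * np.eye(2))
    zones = ("tropical", "dry", "temperate", "continental")
    rows = []
    for ci in range(n_countries):
        country_id = f"C{ci + 1:02d}"
        region = (
            region_labels[ci]
            if region_labels is not None
            else _REGIONS[ci % len(_REGIONS)]
        )
        shift = (region_slope_shift or {}).get(region, 0.0)
        cdev = lc @ rng.standard_normal(2)
        for mj in range(communities_per_country):
            community_id = f"{country_id}-M{mj + 1:02d}"
            mdev = lm @ rng.standard_normal(2)
            at_base = rng.uniform(*at_base_range)
            ws = np.arange(1, n_periods + 1)
            at = at_base + at_trend * (ws - 1) + rng.normal(0, at_noise_sd, n_periods)
            sd = rng.uniform(*sd_range, n_periods)
            est = (
                alpha
                + cdev[0]
                + mdev[0]
                + (beta + shift + cdev[1] + mdev[1]) * ws
                + kappa * at
                + rng.normal(0.0, sd)
            )
            for k, w in enumerate(ws):
                rows.append(
                    {
                        "community_id": community_id,
                        "country_id": country_id,
                        "region": region,
                        "climate_zone": zones[(ci * communities_per_country + mj) % 4],
                        "w": int(w),
                        "metric": "MMT",
                        "estimate": est[k],
                        "sd": sd[k],
                        "AT": at[k],
                    }
                )
    df = pd.DataFrame(rows)
    df["TAT"] = df.groupby("community_id")["AT"].transform("mean")
    return df
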