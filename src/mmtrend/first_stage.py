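"""First-stage estimation: per community x subperiod DLNM quasi-Poisson fits
and Monte-Carlo minimum-mortality-temperature (MMT) estimation.

For each community and 5-year subperiod a quasi-Poisson GLM of daily death
counts is fitted on an intercept, a seasonal natural cubic spline of time
(8 df per year), day-of-week indicators, and the DLNM cross-basis of daily
mean temperature (lags 0..21).  The 20 cross-basis coefficients are reduced
to the 4 coefficients of the lag-cumulative exposure-response

    theta = M1 beta,   M1 = I_vx (x) (1' C),   V(theta) = M1 V(beta) M1',

and the MMT is the argmin of sum_k theta_k f_k(x) over a grid spanning the
25th-99th percentile window of the subperiod's temperatures.  Its standard
error is the sample SD of 1000 argmins computed from Monte-Carlo draws
theta_(s) ~ N(theta_hat, V(theta_hat)); the MMT percentile (MMTP) is the
proportion of observed daily temperatures <= MMT.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .basis import (
    CrossBasis,
    CrossBasisSpec,
    DataError,
    InvalidSpecError,
    SplineSpec,
    build_cross_basis,
    lag_spline_spec,
    natural_cubic_basis,
    temperature_spline_spec,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass
class CommunitySeries:
    """One community's daily all-cause deaths and mean temperature."""

    community_id: str
    country_id: str
    region: str
    climate_zone: str
    dates: pd.DatetimeIndex
    deaths: np.ndarray
    tmean: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.tmean = np.asarray(self.tmean, dtype=float)
        if not (len(self.dates) == len(self.deaths) == len(self.tmean)):
            raise ContractError("dates, deaths, tmean must have equal length")
        if len(self.dates) > 1:
            diffs = np.diff(self.dates.values).astype("timedelta64[D]")
            if not (diffs == np.timedelta64(1, "D")).all():
                raise ContractError("dates must be strictly consecutive days")
        fin = self.deaths[np.isfinite(self.deaths)]
        if (fin < 0).any():
            raise ContractError("death counts must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class ControlDesign:
    """Seasonality/trend spline and day-of-week indicators (ref. Monday)."""

    seasonal_basis: np.ndarray
    dow_indicators: np.ndarray
    df_seasonal: int

    @property
    def matrix(self) -> np.ndarray:
        n = self.seasonal_basis.shape[0]
        return np.hstack(
            [np.ones((n, 1)), self.seasonal_basis, self.dow_indicators]
        )


@dataclass
class FirstStageFit:
    beta: np.ndarray
    vbeta: np.ndarray
    control_coefs: np.ndarray
    dispersion: float
    n_used: int
    converged: bool


@dataclass
class ReducedCurve:
    """Lag-cumulative exposure-response: theta, V(theta), and its basis."""

    theta: np.ndarray
    vtheta: np.ndarray
    temp_basis: SplineSpec
    temp_range: tuple[float, float]


@dataclass
class MMTEstimate:
    mmt: float
    se: float
    mmtp: float
    samples: np.ndarray = field(repr=False)
    search_range: tuple[float, float] = (25.0, 99.0)
    converged: bool = True


def split_subperiods(
    series: CommunitySeries,
    start_year: int = 1986,
    end_year: int = 2015,
    width_years: int = 5,
) -> list[tuple[int, CommunitySeries]]:
    """Cut a series into nonoverlapping calendar-year blocks.

    Returns ``(w, block)`` pairs with w = 1 for the first block starting at
    ``start_year``; blocks with no overlap with the observed span are
    omitted and partial overlaps are truncated.  Lags never carry across
    block boundaries: each block is refit as an independent series.
    """
    if width_years < 1:
        raise ConfigError("width_years must be >= 1")
    if start_year > end_year:
        raise ConfigError("start_year must not exceed end_year")
    out: list[tuple[int, CommunitySeries]] = []
    years = series.dates.year
    w = 0
    for ys in range(start_year, end_year + 1, width_years):
        w += 1
        ye = min(ys + width_years - 1, end_year)
        mask = (years >= ys) & (years <= ye)
        if not mask.any():
            continue
        out.append(
            (
                w,
                CommunitySeries(
                    community_id=series.community_id,
                    country_id=series.country_id,
                    region=series.region,
                    climate_zone=series.climate_zone,
                    dates=series.dates[mask],
                    deaths=series.deaths[mask],
                    tmean=series.tmean[mask],
                ),
            )
        )
    return out


def build_control_design(
    dates: pd.DatetimeIndex, df_per_year: float = 8.0
) -> ControlDesign:
    """Seasonal spline (round(df_per_year * years) df, equally spaced knots)
    plus 6 day-of-week indicators with Monday as the reference level."""
    dates = pd.DatetimeIndex(dates)
    n = len(dates)
    if n < 365:
        logger.warning("control design built on fewer than 365 days (n=%d)", n)
    years = n / 365.25
    df = max(int(round(df_per_year * years)), 2)
    t = np.arange(n, dtype=float)
    # natural spline with df columns (no intercept) => df - 1 internal knots
    internal = np.linspace(0.0, n - 1.0, df + 1)[1:-1]
    spec = SplineSpec(tuple(internal), (0.0, n - 1.0), with_intercept=False)
    seasonal = natural_cubic_basis(t, spec)
    dow = np.zeros((n, 6))
    wd = dates.weekday.values  # Monday = 0
    for k in range(1, 7):
        dow[wd == k, k - 1] = 1.0
    return ControlDesign(seasonal_basis=seasonal, dow_indicators=dow, df_seasonal=df)


def _irls_poisson(
    y: np.ndarray, x: np.ndarray, maxiter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Poisson ML by Fisher-scoring IRLS with the log link.

    Returns (coefficients, unscaled covariance (X'WX)^{-1}, converged).
    """
    n, p = x.shape
    mu = np.maximum(y, 0.0) + np.mean(y) * 0.1 + 0.1
    eta = np.log(mu)
    dev_old = np.inf
    converged = False
    beta = np.zeros(p)
    xtwx = np.eye(p)
    for _ in range(maxiter):
        w = mu
        z = eta + (y - mu) / mu
        xw = x * w[:, None]
        xtwx = x.T @ xw
        xtwz = xw.T @ z
        try:
            cf = cho_factor(xtwx)
            beta = cho_solve(cf, xtwz)
        except np.linalg.LinAlgError:
            logger.warning("rank-deficient design; falling back to pseudoinverse")
            beta = np.linalg.pinv(xtwx) @ xtwz
        eta = np.clip(x @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        dev = 2.0 * dev_terms.sum()
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    try:
        cov_unscaled = cho_solve(cho_factor(xtwx), np.eye(p))
    except np.linalg.LinAlgError:
        cov_unscaled = np.linalg.pinv(xtwx)
    return beta, cov_unscaled, converged


def fit_quasi_poisson(
    y: np.ndarray,
    design: np.ndarray,
    valid_rows: np.ndarray | None = None,
    n_crossbasis: int | None = None,
    maxiter: int = 100,
) -> FirstStageFit:
    """Quasi-Poisson GLM: Poisson ML point estimates via IRLS, covariance
    scaled by the Pearson dispersion chi^2 / (n - p).

    ``n_crossbasis`` gives the number of trailing design columns belonging
    to the cross-basis; ``beta``/``vbeta`` are restricted to that block.
    """
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    if valid_rows is None:
        valid_rows = np.ones(len(y), dtype=bool)
    use = valid_rows & np.isfinite(y) & np.isfinite(design).all(axis=1)
    ysub, xsub = y[use], design[use]
    if n_crossbasis is None:
        n_crossbasis = xsub.shape[1]
    n, k = xsub.shape

    beta_all, cov_unscaled, converged = _irls_poisson(ysub, xsub, maxiter=maxiter)
    mu = np.exp(np.clip(xsub @ beta_all, -30.0, 30.0))
    pearson = float(np.sum((ysub - mu) ** 2 / mu))
    dispersion = pearson / max(n - k, 1)
    cov = dispersion * cov_unscaled

    sl = slice(k - n_crossbasis, k)
    return FirstStageFit(
        beta=beta_all[sl],
        vbeta=cov[sl, sl],
        control_coefs=beta_all[: k - n_crossbasis],
        dispersion=dispersion,
        n_used=int(use.sum()),
        converged=converged,
    )


def reduce_over_lags(fit: FirstStageFit, cb: CrossBasis) -> ReducedCurve:
    """Collapse the vx*vl cross-basis coefficients over lags.

    theta = M1 beta with M1 = I_vx kron (1' C); V(theta) = M1 V(beta) M1'.
    """
    spec = cb.spec
    vx, vl = spec.vx, spec.vl
    if fit.beta.size != vx * vl:
        raise ContractError(
            f"beta has length {fit.beta.size}, expected vx*vl = {vx * vl}"
        )
    csum = cb.lag_basis_matrix.sum(axis=0)  # 1' C, length vl
    m1 = np.kron(np.eye(vx), csum[None, :])  # vx x (vx*vl)
    theta = m1 @ fit.beta
    vtheta = m1 @ fit.vbeta @ m1.T
    vtheta = 0.5 * (vtheta + vtheta.T)
    return ReducedCurve(
        theta=theta,
        vtheta=vtheta,
        temp_basis=spec.temp_spline,
        temp_range=spec.temp_spline.boundary_knots,
    )


def cumulative_curve(curve: ReducedCurve, temps: np.ndarray) -> np.ndarray:
    """Lag-cumulative log relative rate sum_k theta_k f_k(x) at ``temps``."""
    f = natural_cubic_basis(np.asarray(temps, dtype=float), curve.temp_basis)
    return f @ curve.theta


def _psd_clip(v: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone by clipping eigenvalues."""
    v = 0.5 * (v + v.T)
    w, q = np.linalg.eigh(v)
    if w.min() >= 0:
        return v
    w = np.clip(w, 0.0, None)
    return (q * w) @ q.T


def estimate_mmt(
    curve: ReducedCurve,
    temps_subperiod: np.ndarray,
    search_percentiles: tuple[float, float] = (25.0, 99.0),
    n_sim: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
    grid_step: float = 0.1,
) -> MMTEstimate:
    """Point estimate and Monte-Carlo standard error of the MMT.

    The argmin is searched on a ``grid_step``-spaced grid covering the
    [p_lo, p_hi] percentile window of the subperiod's temperatures; ties
    break to the lowest temperature.  ``n_sim`` draws from
    N(theta, V(theta)) (PSD-clipped) give the sample SD used as se.
    """
    temps = np.asarray(temps_subperiod, dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size < 100:
        raise DataError("need >= 100 non-missing temperatures for MMT search")
    lo, hi = np.percentile(temps, search_percentiles)
    if not hi > lo:
        raise DataError("degenerate MMT search grid (constant temperatures)")
    grid = np.arange(lo, hi + grid_step * 0.5, grid_step)
    f = natural_cubic_basis(grid, curve.temp_basis)
    mmt = float(grid[np.argmin(f @ curve.theta)])

    v = _psd_clip(curve.vtheta)
    rng = np.random.default_rng(seed)
    # Cholesky of PSD (possibly singular) covariance via eigendecomposition
    w, q = np.linalg.eigh(v)
    root = q * np.sqrt(np.clip(w, 0.0, None))
    draws = curve.theta[None, :] + rng.standard_normal((n_sim, len(curve.theta))) @ root.T
    samples = grid[np.argmin(f @ draws.T, axis=0)]
    se = float(samples.std(ddof=1)) if n_sim > 1 else 0.0
    mmtp = mmt_to_percentile(mmt, temps)
    return MMTEstimate(
        mmt=mmt,
        se=se,
        mmtp=mmtp,
        samples=samples,
        search_range=(float(lo), float(hi)),
        converged=True,
    )


def mmt_to_percentile(mmt: float, temps_subperiod: np.ndarray) -> float:
    """MMT as a percentile of the empirical daily temperature distribution:
    100 x proportion of non-missing temperatures <= mmt."""
    temps = np.asarray(temps_subperiod, dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size == 0:
        raise DataError("no non-missing temperatures")
    return float(100.0 * np.mean(temps <= mmt))


@dataclass
class FirstStageConfig:
    start_year: int = 1986
    end_year: int = 2015
    width_years: int = 5
    max_lag: int = 21
    temp_knot_percentiles: tuple[float, float, float] = (10.0, 75.0, 90.0)
    n_lag_knots: int = 3
    df_per_year: float = 8.0
    search_percentiles: tuple[float, float] = (25.0, 99.0)
    n_sim: int = 1000
    grid_step: float = 0.1
    min_years: float = 2.0
    min_deaths: float = 500.0
    seed: int = 0


def _unit_seed(root_seed: int, community_id: str, w: int) -> np.random.SeedSequence:
    """Deterministic per-unit seed derived from the root seed."""
    return np.random.SeedSequence(
        [int(root_seed) % 2**31, zlib.crc32(community_id.encode()), int(w)]
    )


def fit_subperiod(
    sub: CommunitySeries, config: FirstStageConfig, w: int
) -> dict | None:
    """Fit one community x subperiod; None if it fails the usability filter."""
    n_days = len(sub)
    deaths_total = np.nansum(sub.deaths)
    if n_days < config.min_years * 365.25 or deaths_total < config.min_deaths:
        return None
    try:
        temp_spec = temperature_spline_spec(sub.tmean, config.temp_knot_percentiles)
        cb_spec = CrossBasisSpec(
            temp_spline=temp_spec,
            lag_spline=lag_spline_spec(config.max_lag, config.n_lag_knots),
            max_lag=config.max_lag,
        )
        cb = build_cross_basis(sub.tmean, cb_spec)
        control = build_control_design(sub.dates, config.df_per_year)
        design = np.hstack([control.matrix, cb.matrix])
        fit = fit_quasi_poisson(
            sub.deaths, design, cb.valid_rows, n_crossbasis=cb_spec.vx * cb_spec.vl
        )
        if not fit.converged:
            return None
        curve = reduce_over_lags(fit, cb)
        est = estimate_mmt(
            curve,
            sub.tmean,
            search_percentiles=config.search_percentiles,
            n_sim=config.n_sim,
            seed=_unit_seed(config.seed, sub.community_id, w),
            grid_step=config.grid_step,
        )
    except (DataError, InvalidSpecError, np.linalg.LinAlgError) as exc:
        logger.warning(
            "dropping %s w=%d: %s", sub.community_id, w, exc
        )
        return None
    temps = sub.tmean[np.isfinite(sub.tmean)]
    mmtp_samples = np.array([mmt_to_percentile(m, temps) for m in est.samples])
    return {
        "community_id": sub.community_id,
        "country_id": sub.country_id,
        "region": sub.region,
        "climate_zone": sub.climate_zone,
        "w": w,
        "mmt": est.mmt,
        "mmt_sd": est.se,
        "mmtp": est.mmtp,
        "mmtp_sd": float(mmtp_samples.std(ddof=1)),
        "AT": float(np.mean(temps)),
        "n_days": n_days,
        "dispersion": fit.dispersion,
        "converged": True,
    }


def run_first_stage(
    dataset: list[CommunitySeries], config: FirstStageConfig | None = None
) -> pd.DataFrame:
    """Fit every community x subperiod and assemble SubperiodRecords.

    Returns a long-format frame with one row per (community, w, metric)
    where metric is MMT or MMTP, carrying the estimate, its Monte-Carlo sd,
    the subperiod average temperature AT and its community time-average
    TAT, and the stratification labels.  Per-unit failures are logged and
    skipped; they never abort the run.
    """
    if config is None:
        config = FirstStageConfig()
    rows: list[dict] = []
    for series in dataset:
        subs = split_subperiods(
            series, config.start_year, config.end_year, config.width_years
        )
        community_rows = []
        for w, sub in subs:
            rec = fit_subperiod(sub, config, w)
            if rec is not None:
                community_rows.append(rec)
        if community_rows:
            tat = float(np.mean([r["AT"] for r in community_rows]))
            for r in community_rows:
                r["TAT"] = tat
            rows.extend(community_rows)

    if not rows:
        return pd.DataFrame(
            columns=[
                "community_id", "country_id", "w", "metric", "estimate", "sd",
                "AT", "TAT", "region", "climate_zone", "n_days", "converged",
            ]
        )
    wide = pd.DataFrame(rows)
    out = []
    for metric, est_col, sd_col in (("MMT", "mmt", "mmt_sd"), ("MMTP", "mmtp", "mmtp_sd")):
        part = wide[
            ["community_id", "country_id", "w", "AT", "TAT", "region",
             "climate_zone", "n_days", "converged"]
        ].copy()
        part["metric"] = metric
        part["estimate"] = wide[est_col].values
        part["sd"] = wide[sd_col].values
        out.append(part)
    cols = [
        "community_id", "country_id", "w", "metric", "estimate", "sd",
        "AT", "TAT", "region", "climate_zone", "n_days", "converged",
    ]
    return pd.concat(out, ignore_index=True)[cols].sort_values(
        ["metric", "country_id", "community_id", "w"], ignore_index=True
    )
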