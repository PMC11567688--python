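"""Second-stage pooling: two-level mixed-effects meta-regression (MEMR).

The first stage yields, for country i, community j and subperiod w, an
estimate y_ijw (MMT in deg C or MMTP in percentile points) with known
standard error sd_ijw.  The pooling model is a linear mixed model with
random intercepts and slopes at the country and community levels and known
heteroscedastic residual variances:

    y_ijw = (alpha + a_ij + c_i) + (beta + b_ij + d_i) * time_w [+ gamma * AT]
            + eps_ijw,
    (a_ij, b_ij)' ~ N(0, Psi2),  (c_i, d_i)' ~ N(0, Psi1),
    eps_ijw ~ N(0, sd_ijw^2).

Estimation maximizes the (restricted) likelihood over the two random-effect
covariances, parameterized by their log-Cholesky factors so that proposals
are always positive semidefinite; the fixed effects are profiled out by
generalized least squares at each objective evaluation.  The likelihood
factorizes over countries, so each evaluation solves one small dense system
per country.  BLUPs are the usual conditional means of the random effects
given the data and the estimated covariances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)


class ContractError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class RandomSpec:
    """Which random-effect columns enter at each level (None = level absent)."""

    country: tuple[str, ...] | None = ("intercept", "time")
    community: tuple[str, ...] | None = ("intercept", "time")

    @property
    def k_country(self) -> int:
        return 0 if self.country is None else len(self.country)

    @property
    def k_community(self) -> int:
        return 0 if self.community is None else len(self.community)

    @property
    def n_params(self) -> int:
        k1, k2 = self.k_country, self.k_community
        return k1 * (k1 + 1) // 2 + k2 * (k2 + 1) // 2


@dataclass
class MemrFit:
    """A fitted mixed-effects meta-regression."""

    fixed: pd.Series
    cov_fixed: pd.DataFrame
    psi_country: np.ndarray | None
    psi_community: np.ndarray | None
    loglik: float
    method: str
    aic: float
    bic: float
    n: int
    n_fixed: int
    n_varparams: int
    random: RandomSpec
    fixed_terms: tuple[str, ...]
    interaction: str | None
    blups_country: pd.DataFrame = field(default=None, repr=False)
    blups_community: pd.DataFrame = field(default=None, repr=False)
    converged: bool = True

    @property
    def fixed_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_fixed.values))
        z = self.fixed.values / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.fixed.values,
                "se": se,
                "z": z,
                "p": p,
                "ci_lo": self.fixed.values - 1.959963984540054 * se,
                "ci_hi": self.fixed.values + 1.959963984540054 * se,
            },
            index=self.fixed.index,
        )


@dataclass
class TrendSummary:
    """Pooled trajectory alpha + beta*w with Wald CIs and the linear slope."""

    table: pd.DataFrame
    slope: float
    slope_se: float
    slope_p: float


# ---------------------------------------------------------------------------
# design construction


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"estimate", "sd", "w", "country_id", "community_id"}
    missing = required - set(records.columns)
    if missing:
        raise ContractError(f"records missing columns: {sorted(missing)}")
    df = records.copy()
    bad = ~(df["sd"] > 0) | ~np.isfinite(df["estimate"])
    if bad.any():
        logger.warning("dropping %d records with sd <= 0 or non-finite estimate", bad.sum())
        df = df[~bad]
    if len(df) == 0:
        raise ContractError("no usable records")
    return df


def build_fixed_design(
    records: pd.DataFrame,
    fixed_terms: tuple[str, ...] = ("time",),
    interaction: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept + terms (+ stratum main effects and
    stratum:time interactions when ``interaction`` names a label column)."""
    n = len(records)
    time = records["w"].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for term in fixed_terms:
        if term == "time":
            cols.append(time)
            names.append("time")
        elif term == "AT":
            cols.append(records["AT"].to_numpy(dtype=float))
            names.append("AT")
        elif term == "AT_centered":
            cols.append(
                records["AT"].to_numpy(dtype=float)
                - records["TAT"].to_numpy(dtype=float)
            )
            names.append("AT_centered")
        else:
            raise ContractError(f"unknown fixed term: {term}")
    if interaction is not None:
        levels = sorted(records[interaction].astype(str).unique())
        for lev in levels[1:]:
            ind = (records[interaction].astype(str) == lev).to_numpy(dtype=float)
            cols.append(ind)
            names.append(f"{interaction}[{lev}]")
            cols.append(ind * time)
            names.append(f"{interaction}[{lev}]:time")
    return np.column_stack(cols), names


def _random_design(records: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    time = records["w"].to_numpy(dtype=float)
    mapping = {"intercept": np.ones(len(records)), "time": time}
    try:
        return np.column_stack([mapping[t] for t in terms])
    except KeyError as exc:
        raise ContractError(f"unknown random term: {exc}") from exc


@dataclass
class _CountryBlock:
    y: np.ndarray
    d: np.ndarray  # residual variances sd^2
    x: np.ndarray
    xy: np.ndarray  # [x | y], solved against V in one call
    zc: np.ndarray | None
    communities: list[tuple[slice, np.ndarray, str]]
    country_id: str


def _build_blocks(
    records: pd.DataFrame,
    x: np.ndarray,
    random: RandomSpec,
) -> list[_CountryBlock]:
    blocks = []
    order = np.lexsort(
        (records["w"].values, records["community_id"].values, records["country_id"].values)
    )
    records = records.iloc[order].reset_index(drop=True)
    x = x[order]
    for cid, gidx in records.groupby("country_id", sort=True).indices.items():
        g = records.iloc[gidx]
        zc = _random_design(g, random.country) if random.country else None
        comms = []
        for comm, cidx in g.groupby("community_id", sort=True).indices.items():
            sub = g.iloc[cidx]
            sl = slice(cidx[0], cidx[-1] + 1)
            zj = (
                _random_design(sub, random.community)
                if random.community
                else None
            )
            comms.append((sl, zj, str(comm)))
        yg = g["estimate"].to_numpy(dtype=float)
        xg = x[gidx]
        blocks.append(
            _CountryBlock(
                y=yg,
                d=g["sd"].to_numpy(dtype=float) ** 2,
                x=xg,
                xy=np.hstack([xg, yg[:, None]]),
                zc=zc,
                communities=comms,
                country_id=str(cid),
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# likelihood


def _chol_expand(params: np.ndarray, k: int) -> np.ndarray:
    """Lower-triangular Cholesky factor from log-Cholesky parameters."""
    L = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(params[idx])
            else:
                L[i, j] = params[idx]
            idx += 1
    return L


def _unpack_psis(
    params: np.ndarray, random: RandomSpec
) -> tuple[np.ndarray | None, np.ndarray | None]:
    k1, k2 = random.k_country, random.k_community
    q1 = k1 * (k1 + 1) // 2
    psi1 = psi2 = None
    if k1:
        L1 = _chol_expand(params[:q1], k1)
        psi1 = L1 @ L1.T
    if k2:
        L2 = _chol_expand(params[q1:], k2)
        psi2 = L2 @ L2.T
    return psi1, psi2


def _profile(
    blocks: list[_CountryBlock],
    psi1: np.ndarray | None,
    psi2: np.ndarray | None,
    p: int,
):
    """GLS quantities at given variance components.

    Returns (logdet, xtvx, xtvy, ytvy, n).
    """
    logdet = 0.0
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    n = 0
    for g in blocks:
        m = len(g.y)
        v = _block_cov(g, psi1, psi2)
        chol = np.linalg.cholesky(v)
        logdet += 2.0 * np.sum(np.log(np.diagonal(chol)))
        sol = cho_solve((chol, True), g.xy, check_finite=False)
        vix, viy = sol[:, :-1], sol[:, -1]
        xtvx += g.x.T @ vix
        xtvy += g.x.T @ viy
        ytvy += g.y @ viy
        n += m
    return logdet, xtvx, xtvy, ytvy, n


def _block_cov(
    g: "_CountryBlock", psi1: np.ndarray | None, psi2: np.ndarray | None
) -> np.ndarray:
    v = np.diag(g.d)
    if psi1 is not None:
        v += g.zc @ psi1 @ g.zc.T
    if psi2 is not None:
        for sl, zj, _ in g.communities:
            v[sl, sl] += zj @ psi2 @ zj.T
    return v


_LOG2PI = np.log(2.0 * np.pi)


def _neg_loglik(
    params: np.ndarray,
    blocks: list[_CountryBlock],
    random: RandomSpec,
    p: int,
    method: str,
) -> float:
    psi1, psi2 = _unpack_psis(params, random)
    try:
        logdet, xtvx, xtvy, ytvy, n = _profile(blocks, psi1, psi2, p)
        b = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        return 1e12
    rss = ytvy - b @ xtvy
    if method == "ml":
        return 0.5 * (n * _LOG2PI + logdet + rss)
    sign, ld2 = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return 1e12
    return 0.5 * ((n - p) * _LOG2PI + logdet + ld2 + rss)


def _neg_loglik_grad(
    params: np.ndarray,
    blocks: list[_CountryBlock],
    random: RandomSpec,
    p: int,
    method: str,
) -> tuple[float, np.ndarray]:
    """Objective and its analytic gradient in the log-Cholesky parameters.

    With the fixed effects profiled out by GLS, the envelope theorem gives
    d nll / d Psi = 0.5 (Z'V^{-1}Z - Z'V^{-1}rr'V^{-1}Z
                         - [REML] Z'V^{-1}X K X'V^{-1}Z),   K = (X'V^{-1}X)^{-1},
    summed over country blocks, chained through Psi = LL'.
    """
    k1, k2 = random.k_country, random.k_community
    q1 = k1 * (k1 + 1) // 2
    l1 = _chol_expand(params[:q1], k1) if k1 else None
    l2 = _chol_expand(params[q1:], k2) if k2 else None
    psi1 = l1 @ l1.T if k1 else None
    psi2 = l2 @ l2.T if k2 else None

    logdet = 0.0
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    n = 0
    per: list[tuple[_CountryBlock, np.ndarray, np.ndarray, np.ndarray]] = []
    try:
        for g in blocks:
            v = _block_cov(g, psi1, psi2)
            chol = np.linalg.cholesky(v)
            logdet += 2.0 * np.sum(np.log(np.diagonal(chol)))
            sol = cho_solve((chol, True), g.xy, check_finite=False)
            vix, viy = sol[:, :-1], sol[:, -1]
            xtvx += g.x.T @ vix
            xtvy += g.x.T @ viy
            ytvy += g.y @ viy
            n += len(g.y)
            per.append((g, chol, vix, viy))
        k_fixed = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(params)
    b = k_fixed @ xtvy
    rss = ytvy - b @ xtvy
    if method == "ml":
        nll = 0.5 * (n * _LOG2PI + logdet + rss)
    else:
        sign, ld2 = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return 1e12, np.zeros_like(params)
        nll = 0.5 * ((n - p) * _LOG2PI + logdet + ld2 + rss)

    t1 = np.zeros((k1, k1)) if k1 else None
    s1 = np.zeros((k1, k1)) if k1 else None
    g1 = np.zeros((k1, k1)) if k1 else None
    t2 = np.zeros((k2, k2)) if k2 else None
    s2 = np.zeros((k2, k2)) if k2 else None
    g2 = np.zeros((k2, k2)) if k2 else None
    reml = method == "reml"
    for g, chol, vix, viy in per:
        vinv = cho_solve((chol, True), np.eye(len(viy)), check_finite=False)
        vir = viy - vix @ b
        if k1:
            t1 += g.zc.T @ vinv @ g.zc
            sv = g.zc.T @ vir
            s1 += np.outer(sv, sv)
            if reml:
                wv = g.zc.T @ vix
                g1 += wv @ k_fixed @ wv.T
        if k2:
            for sl, zj, _ in g.communities:
                t2 += zj.T @ vinv[sl, sl] @ zj
                sv = zj.T @ vir[sl]
                s2 += np.outer(sv, sv)
                if reml:
                    wv = zj.T @ vix[sl]
                    g2 += wv @ k_fixed @ wv.T

    grad: list[float] = []
    for k, lmat, t, s, gr in ((k1, l1, t1, s1, g1), (k2, l2, t2, s2, g2)):
        if not k:
            continue
        m = 0.5 * (t - s - (gr if reml else 0.0))
        gm = 2.0 * (m @ lmat)
        for i in range(k):
            for j in range(i + 1):
                grad.append(gm[i, j] * (lmat[i, i] if i == j else 1.0))
    return nll, np.asarray(grad)


def _optimize_psis(
    blocks: list[_CountryBlock],
    random: RandomSpec,
    p: int,
    method: str,
    resid_var: float,
) -> tuple[np.ndarray, bool]:
    """Maximize the (restricted) likelihood over the log-Cholesky parameters
    from a small grid of scale-aware starting values."""
    q = random.n_params
    if q == 0:
        return np.zeros(0), True
    s0 = 0.5 * np.log(max(resid_var, 1e-4) / 2.0)
    diag_mask = np.zeros(q, dtype=bool)
    idx = 0
    for k in (random.k_country, random.k_community):
        for i in range(k):
            for j in range(i + 1):
                diag_mask[idx] = i == j
                idx += 1
    best = None
    for shift in (0.0, -2.0, 2.0):
        st = np.where(diag_mask, s0 + shift, 0.0)
        res = optimize.minimize(
            _neg_loglik_grad,
            st,
            args=(blocks, random, p, method),
            method="L-BFGS-B",
            jac=True,
            bounds=[(-12.0, 12.0)] * q,
            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if not np.isfinite(best.fun):
        raise FitError(f"MEMR optimization failed: {best.message}")
    return best.x, bool(best.success)


def fit_memr(
    records: pd.DataFrame,
    fixed_terms: tuple[str, ...] = ("time",),
    interaction: str | None = None,
    random: RandomSpec | None = None,
    method: str = "reml",
    compute_blups: bool = True,
) -> MemrFit:
    """Fit the two-level mixed-effects meta-regression.

    ``records`` must carry one metric only (MMT or MMTP) with columns
    estimate, sd, w, country_id, community_id (plus AT/TAT or label columns
    as the fixed terms require).  ``method`` is "reml" (default, for
    reported fits and random-structure comparisons) or "ml" (for
    fixed-effect likelihood-ratio tests).
    """
    method = method.lower()
    if method not in ("reml", "ml"):
        raise ContractError(f"unknown method: {method}")
    if random is None:
        random = RandomSpec()
    df = _validate_records(records)
    x, names = build_fixed_design(df, fixed_terms, interaction)
    p = x.shape[1]
    if np.linalg.matrix_rank(x) < p:
        raise ContractError("fixed-effect design is rank deficient")
    blocks = _build_blocks(df, x, random)

    q = random.n_params
    resid_var = float(np.var(df["estimate"].to_numpy(dtype=float)))
    params, converged = _optimize_psis(blocks, random, p, method, resid_var)

    psi1, psi2 = _unpack_psis(params, random)
    logdet, xtvx, xtvy, ytvy, n = _profile(blocks, psi1, psi2, p)
    b = np.linalg.solve(xtvx, xtvy)
    cov_b = np.linalg.inv(xtvx)
    loglik = -_neg_loglik(params, blocks, random, p, method)
    k_tot = p + random.n_params
    aic = -2.0 * loglik + 2.0 * k_tot
    bic = -2.0 * loglik + np.log(n) * k_tot

    fit = MemrFit(
        fixed=pd.Series(b, index=names),
        cov_fixed=pd.DataFrame(cov_b, index=names, columns=names),
        psi_country=psi1,
        psi_community=psi2,
        loglik=float(loglik),
        method=method,
        aic=float(aic),
        bic=float(bic),
        n=int(n),
        n_fixed=p,
        n_varparams=q,
        random=random,
        fixed_terms=tuple(fixed_terms),
        interaction=interaction,
        converged=converged,
    )
    if compute_blups:
        fit.blups_country, fit.blups_community = blups(fit, blocks=blocks, b=b)
    return fit


def blups(
    fit: MemrFit,
    records: pd.DataFrame | None = None,
    blocks: list[_CountryBlock] | None = None,
    b: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best linear unbiased predictors of the random effects.

    u_level = Psi_level Z' V^{-1} (y - X b), computed per country block.
    Community-level predictions add fixed + country BLUP + community BLUP.
    """
    if blocks is None:
        df = _validate_records(records)
        x, _ = build_fixed_design(df, fit.fixed_terms, fit.interaction)
        blocks = _build_blocks(df, x, fit.random)
    if b is None:
        b = fit.fixed.values
    psi1, psi2 = fit.psi_country, fit.psi_community
    crows, mrows = [], []
    for g in blocks:
        v = _block_cov(g, psi1, psi2)
        cf = cho_factor(v, lower=True)
        vir = cho_solve(cf, g.y - g.x @ b)
        uc = np.zeros(0)
        if psi1 is not None:
            uc = psi1 @ (g.zc.T @ vir)
            crows.append(
                {"country_id": g.country_id}
                | {t: uc[i] for i, t in enumerate(fit.random.country)}
            )
        for sl, zj, comm in g.communities:
            if psi2 is None:
                continue
            uj = psi2 @ (zj.T @ vir[sl])
            row = {"country_id": g.country_id, "community_id": comm}
            for i, t in enumerate(fit.random.community):
                row[t] = uj[i]
            mrows.append(row)
    country = pd.DataFrame(crows)
    community = pd.DataFrame(mrows)
    return country, community


def lr_test(nested: MemrFit, full: MemrFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of two nested MEMR fits of the same flavor."""
    if nested.method != full.method:
        raise ContractError("LR test requires fits of the same flavor (ML or REML)")
    if nested.method == "reml" and nested.fixed_terms + (nested.interaction,) != (
        full.fixed_terms + (full.interaction,)
    ):
        raise ContractError("REML LR test requires identical fixed-effect parts")
    df = (full.n_fixed + full.n_varparams) - (nested.n_fixed + nested.n_varparams)
    if df < 0:
        raise ContractError("nested model has more parameters than the full model")
    stat = max(2.0 * (full.loglik - nested.loglik), 0.0)
    if df == 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p


def heterogeneity_suite(records: pd.DataFrame) -> pd.DataFrame:
    """The model-comparison ladder probing heterogeneity in the time trend.

    Rows: climate-zone x time and region x time interactions (ML fits, main
    effects in both models so the test isolates the interaction), and the
    country- and community-level random slopes (REML fits; the slope adds
    one variance and one covariance parameter, df = 2).  Per-row failures
    yield NaN statistics instead of aborting.
    """
    rows = []

    def _row(name, fit_reduced, fit_full):
        try:
            red = fit_reduced()
            ful = fit_full()
            stat, df, p = lr_test(red, ful)
            rows.append(
                {
                    "comparison": name,
                    "lr_stat": stat,
                    "df": df,
                    "p": p,
                    "aic_reduced": red.aic,
                    "aic_full": ful.aic,
                    "bic_reduced": red.bic,
                    "bic_full": ful.bic,
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-row error policy
            logger.warning("heterogeneity row %s failed: %s", name, exc)
            rows.append(
                {
                    "comparison": name,
                    "lr_stat": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                    "aic_reduced": np.nan,
                    "aic_full": np.nan,
                    "bic_reduced": np.nan,
                    "bic_full": np.nan,
                }
            )

    for label in ("climate_zone", "region"):
        if label in records.columns and records[label].nunique() > 1:
            # reduced: time + stratum main effects; full adds stratum:time
            def _reduced(lab=label):
                return _fit_with_stratum(records, lab, with_interaction=False)

            def _full(lab=label):
                return _fit_with_stratum(records, lab, with_interaction=True)

            _row(f"{label}_x_time", _reduced, _full)

    full_random = RandomSpec(("intercept", "time"), ("intercept", "time"))
    no_country_slope = RandomSpec(("intercept",), ("intercept", "time"))
    no_community_slope = RandomSpec(("intercept", "time"), ("intercept",))
    _row(
        "country_random_slope",
        lambda: fit_memr(records, ("time",), random=no_country_slope,
                         method="reml", compute_blups=False),
        lambda: fit_memr(records, ("time",), random=full_random,
                         method="reml", compute_blups=False),
    )
    _row(
        "community_random_slope",
        lambda: fit_memr(records, ("time",), random=no_community_slope,
                         method="reml", compute_blups=False),
        lambda: fit_memr(records, ("time",), random=full_random,
                         method="reml", compute_blups=False),
    )
    return pd.DataFrame(rows)


def _fit_with_stratum(
    records: pd.DataFrame, label: str, with_interaction: bool
) -> MemrFit:
    """ML fit with stratum main effects, optionally plus stratum:time."""
    df = records.copy()
    fit = fit_memr(
        df,
        fixed_terms=("time",),
        interaction=label if with_interaction else None,
        method="ml",
        compute_blups=False,
    )
    if with_interaction:
        return fit
    # main effects only: build the interaction design and drop :time columns
    x, names = build_fixed_design(df, ("time",), interaction=label)
    keep = [i for i, nm in enumerate(names) if not nm.endswith(":time")]
    return _fit_fixed_design(df, x[:, keep], [names[i] for i in keep],
                             method="ml")


def _fit_fixed_design(
    records: pd.DataFrame,
    x: np.ndarray,
    names: list[str],
    random: RandomSpec | None = None,
    method: str = "reml",
) -> MemrFit:
    """fit_memr on an explicit fixed design (used for main-effects-only fits)."""
    if random is None:
        random = RandomSpec()
    df = _validate_records(records)
    p = x.shape[1]
    blocks = _build_blocks(df, x, random)
    q = random.n_params
    resid_var = float(np.var(df["estimate"].to_numpy(dtype=float)))
    params, converged = _optimize_psis(blocks, random, p, method, resid_var)
    psi1, psi2 = _unpack_psis(params, random)
    _, xtvx, xtvy, _, n = _profile(blocks, psi1, psi2, p)
    b = np.linalg.solve(xtvx, xtvy)
    loglik = -_neg_loglik(params, blocks, random, p, method)
    k_tot = p + q
    return MemrFit(
        fixed=pd.Series(b, index=names),
        cov_fixed=pd.DataFrame(np.linalg.inv(xtvx), index=names, columns=names),
        psi_country=psi1,
        psi_community=psi2,
        loglik=float(loglik),
        method=method,
        aic=float(-2 * loglik + 2 * k_tot),
        bic=float(-2 * loglik + np.log(n) * k_tot),
        n=int(n),
        n_fixed=p,
        n_varparams=q,
        random=random,
        fixed_terms=("time",),
        interaction=None,
        converged=converged,
    )


def at_adjustment(
    records: pd.DataFrame, stratum: str | None = None
) -> pd.DataFrame:
    """Time slope before and after adjusting for average temperature (AT).

    Fits the time-only model, the model with raw subperiod AT, and the model
    with time-centered AT (AT - TAT) as an extra meta-predictor, overall and
    per stratum level when ``stratum`` names a label column.  Reports the
    time slope, its p-value, and the AT coefficient gamma per fit.
    """
    groups: list[tuple[str, pd.DataFrame]] = [("all", records)]
    if stratum is not None:
        for lev, sub in records.groupby(stratum, sort=True):
            groups.append((str(lev), sub))
    rows = []
    for lev, sub in groups:
        for model, terms in (
            ("time_only", ("time",)),
            ("at", ("time", "AT")),
            ("at_centered", ("time", "AT_centered")),
        ):
            row = {"stratum": lev, "model": model, "n": len(sub)}
            try:
                if "AT" in terms or "AT_centered" in terms:
                    at_col = (
                        sub["AT"]
                        if "AT" in terms
                        else sub["AT"] - sub["TAT"]
                    ).to_numpy(dtype=float)
                    tcol = sub["w"].to_numpy(dtype=float)
                    c = np.corrcoef(at_col, tcol)[0, 1] if len(sub) > 2 else np.nan
                    if np.isfinite(c) and abs(c) > 0.99:
                        x, _ = build_fixed_design(sub, terms)
                        row["condition_number"] = float(np.linalg.cond(x))
                        logger.warning(
                            "AT nearly collinear with time in stratum %s "
                            "(|r|=%.3f, cond=%.1f)", lev, abs(c),
                            row["condition_number"],
                        )
                fit = fit_memr(sub, terms, method="reml", compute_blups=False)
                tab = fit.fixed_table
                row["time_slope"] = tab.loc["time", "coef"]
                row["time_se"] = tab.loc["time", "se"]
                row["time_p"] = tab.loc["time", "p"]
                for nm in ("AT", "AT_centered"):
                    if nm in tab.index:
                        row["gamma"] = tab.loc[nm, "coef"]
                        row["gamma_p"] = tab.loc[nm, "p"]
            except Exception as exc:  # noqa: BLE001 - per-row error policy
                logger.warning("AT adjustment (%s, %s) failed: %s", lev, model, exc)
                row.update(time_slope=np.nan, time_se=np.nan, time_p=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def pooled_trajectory(fit: MemrFit, w_values=None) -> TrendSummary:
    """Pooled value alpha + beta*w per subperiod with Wald 95% CI, plus the
    linear slope (LS) and its p-value."""
    if w_values is None:
        w_values = np.arange(1, 7)
    w_values = np.asarray(w_values, dtype=float)
    names = list(fit.fixed.index)
    ia, ib = names.index("intercept"), names.index("time")
    a, b = fit.fixed.iloc[ia], fit.fixed.iloc[ib]
    cov = fit.cov_fixed.values
    var = (
        cov[ia, ia]
        + w_values**2 * cov[ib, ib]
        + 2.0 * w_values * cov[ia, ib]
    )
    se = np.sqrt(var)
    vals = a + b * w_values
    zcrit = 1.959963984540054
    table = pd.DataFrame(
        {
            "w": w_values,
            "pooled": vals,
            "ci_lo": vals - zcrit * se,
            "ci_hi": vals + zcrit * se,
        }
    )
    slope_se = float(np.sqrt(cov[ib, ib]))
    slope_p = float(2.0 * stats.norm.sf(abs(b) / slope_se))
    return TrendSummary(table=table, slope=float(b), slope_se=slope_se,
                        slope_p=slope_p)


def stratified_fits(
    records: pd.DataFrame,
    stratum: str,
    method: str = "reml",
) -> dict[str, MemrFit | None]:
    """Refit the pooling model separately on each stratum's records."""
    out: dict[str, MemrFit | None] = {}
    for lev, sub in records.groupby(stratum, sort=True):
        try:
            out[str(lev)] = fit_memr(sub, ("time",), method=method,
                                     compute_blups=False)
        except Exception as exc:  # noqa: BLE001
            logger.warning("stratified fit %s=%s failed: %s", stratum, lev, exc)
            out[str(lev)] = None
    return out
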