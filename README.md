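# mmtrend

Two-stage estimation of temporal change in the **minimum mortality
temperature (MMT)** and its percentile (**MMTP**) from multicountry daily
mortality-temperature time series.

The MMT is the daily mean temperature at which the lag-cumulative
temperature-mortality curve attains its minimum — a standard indicator of a
population's optimum temperature and of its susceptibility to heat and cold.
Whether the MMT drifts as the climate warms, and whether any drift is
explained by warming itself or by adaptation, is a question for environmental
epidemiologists working with city- or community-level death registries. This
package implements the complete analysis pipeline for that question, plus a
synthetic-data generator with known ground truth so every stage is testable
without access to restricted mortality registries.

## The model

**Stage 1 — community x subperiod exposure-response.** The study window
(default 1986-2015) is cut into 5-year nonoverlapping subperiods
(w = 1..6). For each community and subperiod, daily all-cause death counts
y_t are modelled by a quasi-Poisson regression

    log lambda_t = alpha_0 + s(x_t; beta) + seasonality + day-of-week,

where seasonality is a natural cubic spline of time with 8 df/year and
s(.) is a distributed lag non-linear model (DLNM): a cross-basis combining
a natural cubic spline of temperature (3 internal knots at the 10th/75th/
90th percentiles, vx = 4) with a natural cubic spline over lags 0..21
(intercept + 3 log-spaced internal knots, vl = 5), giving 20 coefficients.
The coefficients are cumulated over lags,

    theta = (I kron 1'C) beta,    V(theta) = M1 V(beta) M1',

and the MMT is the argmin of sum_k theta_k f_k(x) over a 0.1 degC grid
spanning the 25th-99th percentile window of that subperiod's temperatures
(1st-99th as a sensitivity option). Its standard error is the sample SD of
1000 Monte-Carlo argmins with theta drawn from N(theta_hat, V(theta_hat)).
MMTP is the fraction of observed daily temperatures at or below the MMT.

**Stage 2 — pooling.** The per-(country i, community j, period w) estimates
with known standard errors sd_ijw enter a two-level mixed-effects
meta-regression

    y_ijw = (alpha + a_ij + c_i) + (beta + b_ij + d_i) time_w + eps_ijw,

with community-level random effects (a_ij, b_ij)' ~ N(0, Psi2),
country-level (c_i, d_i)' ~ N(0, Psi1) and eps_ijw ~ N(0, sd_ijw^2) fixed.
REML (or ML) estimation with log-Cholesky-parameterized covariances yields
the pooled linear slope (LS) of the MMT trend, BLUPs per country and
community, stratified fits by climate zone / region / country,
likelihood-ratio tests for random slopes and region/zone x time
interactions, and fits adjusted for the subperiod average temperature AT
(raw, and centered as AT - TAT) to probe whether warming alone explains the
trend.

## Worked example

```python
from mmtrend import (TruthSpec, FirstStageConfig, simulate_dataset,
                     run_first_stage, fit_memr, pooled_trajectory)

# 6 countries x 4 communities, 1986-2015, true MMT rising 0.5 degC/subperiod
spec = TruthSpec(n_countries=6, communities_per_country=4, seed=1,
                 mmt_slope=0.5, country_slope_sd=0.1, community_slope_sd=0.1)
dataset, truth = simulate_dataset(spec)

records = run_first_stage(dataset, FirstStageConfig(seed=2))
mmt = records[records.metric == "MMT"]
fit = fit_memr(mmt, method="reml")
trend = pooled_trajectory(fit)
print(f"LS = {trend.slope:.3f} (se {trend.slope_se:.3f}, p {trend.slope_p:.2g})")
print(trend.table.round(2))
```

prints

```
LS = 0.489 (se 0.149, p 0.001)
     w  pooled  ci_lo  ci_hi
0  1.0   21.50  17.27  25.73
1  2.0   21.99  17.91  26.07
2  3.0   22.48  18.54  26.42
3  4.0   22.97  19.15  26.78
4  5.0   23.46  19.74  27.17
5  6.0   23.94  20.31  27.58
```

The pooled linear slope of 0.49 degC per 5-year subperiod (simulated truth:
0.5) is the headline trend statistic; the table gives the pooled MMT per
subperiod with Wald 95% confidence intervals, which here are wide because
six countries carry substantial between-country heterogeneity.

The same pipeline runs from the shell:

```bash
mmtrend run-all --config config.yaml --out runs/demo
mmtrend report --run-dir runs/demo
```

with subcommands `simulate`, `stage1`, `stage2`, `run-all`, `report` and a
YAML configuration mirroring `mmtrend.config.RunConfig`.

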