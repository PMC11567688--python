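"""Mixed-effects meta-regression: fitting, BLUPs, tests, trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from mmtrend import (
    MemrFit,
    RandomSpec,
    at_adjustment,
    blups,
    fit_memr,
    lr_test,
    pooled_trajectory,
    simulate_memr_records,
    stratified_fits,
)
from mmtrend.second_stage import (
    ContractError,
    _build_blocks,
    _fit_fixed_design,
    _validate_records,
    build_fixed_design,
)


def _toy_records(seed=0, **kw):
    defaults = dict(
        n_countries=3,
        communities_per_country=2,
        psi_country=np.diag([0.2, 0.02]),
        psi_community=np.diag([0.2, 0.02]),
        seed=seed,
    )
    defaults.update(kw)
    return simulate_memr_records(**defaults)


def _manual_fit(records, fixed, psi1, psi2):
    """MemrFit shell with prescribed Psi and fixed effects (for BLUP tests)."""
    names = ["intercept", "time"]
    return MemrFit(
        fixed=pd.Series(fixed, index=names),
        cov_fixed=pd.DataFrame(np.eye(2), index=names, columns=names),
        psi_country=psi1,
        psi_community=psi2,
        loglik=0.0,
        method="reml",
        aic=0.0,
        bic=0.0,
        n=len(records),
        n_fixed=2,
        n_varparams=6,
        random=RandomSpec(),
        fixed_terms=("time",),
        interaction=None,
    )


class TestFitting:
    def test_wls_closed_form_when_no_random_effects(self):
        rec = _toy_records(psi_country=None, psi_community=None, sd_range=(1.0, 1.0))
        fit = fit_memr(rec, random=RandomSpec(None, None), method="ml",
                       compute_blups=False)
        x = np.column_stack([np.ones(len(rec)), rec["w"]])
        b = np.linalg.lstsq(x, rec["estimate"].values, rcond=None)[0]
        np.testing.assert_allclose(fit.fixed.values, b, atol=1e-10)
        # and with unequal known variances: weighted LS closed form
        rec2 = _toy_records(seed=1, psi_country=None, psi_community=None)
        fit2 = fit_memr(rec2, random=RandomSpec(None, None), method="ml",
                        compute_blups=False)
        w = 1.0 / rec2["sd"].values ** 2
        x2 = np.column_stack([np.ones(len(rec2)), rec2["w"]])
        xtwx = (x2 * w[:, None]).T @ x2
        b2 = np.linalg.solve(xtwx, (x2 * w[:, None]).T @ rec2["estimate"].values)
        np.testing.assert_allclose(fit2.fixed.values, b2, atol=1e-10)
        np.testing.assert_allclose(fit2.cov_fixed.values, np.linalg.inv(xtwx),
                                   atol=1e-10)

    def test_two_points_interpolated(self):
        rec = pd.DataFrame(
            {
                "community_id": ["a", "a"],
                "country_id": ["A", "A"],
                "w": [1, 2],
                "estimate": [10.0, 11.0],
                "sd": [0.5, 0.5],
            }
        )
        fit = fit_memr(rec, method="ml", compute_blups=False)
        assert fit.fixed["time"] == pytest.approx(1.0, abs=1e-6)
        # variance components collapse to (near) the zero boundary
        assert np.abs(fit.psi_country).max() < 1e-4
        assert np.abs(fit.psi_community).max() < 1e-4

    def test_simulation_recovery_and_coverage(self):
        """Mean slope estimate near truth; Wald CI coverage near nominal."""
        beta_true = 0.2
        hits, est = 0, []
        n_rep = 40
        for r in range(n_rep):
            rec = simulate_memr_records(
                n_countries=12,
                communities_per_country=4,
                alpha=19.0,
                beta=beta_true,
                psi_country=np.diag([0.25, 0.01]),
                psi_community=np.diag([0.25, 0.01]),
                seed=7000 + r,
            )
            fit = fit_memr(rec, method="reml", compute_blups=False)
            tab = fit.fixed_table
            est.append(tab.loc["time", "coef"])
            hits += tab.loc["time", "ci_lo"] <= beta_true <= tab.loc["time", "ci_hi"]
        assert abs(np.mean(est) - beta_true) < 0.05
        assert hits / n_rep >= 0.85  # binomial tolerance at 40 replicates

    def test_reml_invariant_to_time_centering(self):
        """Affine reparameterization of the fixed design leaves the REML
        likelihood and the variance components unchanged."""
        rec = _toy_records(seed=3, n_countries=5, communities_per_country=3)
        fit = fit_memr(rec, method="reml", compute_blups=False)
        df = _validate_records(rec)
        x, names = build_fixed_design(df, ("time",))
        c = df["w"].mean()
        x_centered = x @ np.array([[1.0, -c], [0.0, 1.0]])
        fit_c = _fit_fixed_design(df, x_centered, names, method="reml")
        assert fit_c.loglik == pytest.approx(fit.loglik, abs=1e-5)
        np.testing.assert_allclose(fit_c.psi_country, fit.psi_country, atol=1e-4)
        np.testing.assert_allclose(fit_c.psi_community, fit.psi_community,
                                   atol=1e-4)
        assert fit_c.fixed["time"] == pytest.approx(fit.fixed["time"], abs=1e-6)

    def test_covariance_scales_with_known_variances(self):
        """Doubling every sd multiplies the fixed-effect covariance by 4
        when there are no random effects."""
        rec = _toy_records(seed=4, psi_country=None, psi_community=None)
        rec2 = rec.copy()
        rec2["sd"] = 2.0 * rec2["sd"]
        f1 = fit_memr(rec, random=RandomSpec(None, None), method="ml",
                      compute_blups=False)
        f2 = fit_memr(rec2, random=RandomSpec(None, None), method="ml",
                      compute_blups=False)
        np.testing.assert_allclose(f2.cov_fixed.values, 4.0 * f1.cov_fixed.values,
                                   rtol=1e-10)
        np.testing.assert_allclose(f2.fixed.values, f1.fixed.values, rtol=1e-10)

    def test_single_level_matches_independent_implementation(self):
        """With the country level removed, the fit agrees with a separately
        coded one-level random-intercept meta-regression."""
        rec = _toy_records(seed=5, n_countries=4, communities_per_country=3,
                           psi_country=None, psi_community=np.diag([0.3, 0.0]))
        rs = RandomSpec(country=None, community=("intercept",))
        fit = fit_memr(rec, random=rs, method="ml", compute_blups=False)

        # independent implementation: marginal ML over tau^2, full matrices
        df = rec.sort_values(["country_id", "community_id", "w"])
        y = df["estimate"].values
        d = df["sd"].values ** 2
        x = np.column_stack([np.ones(len(df)), df["w"].values])
        comm = df["community_id"].values

        def nll(log_tau2):
            tau2 = np.exp(log_tau2)
            v = np.diag(d) + tau2 * (comm[:, None] == comm[None, :])
            vinv = np.linalg.inv(v)
            b = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
            r = y - x @ b
            sign, logdet = np.linalg.slogdet(v)
            return 0.5 * (len(y) * np.log(2 * np.pi) + logdet + r @ vinv @ r)

        res = optimize.minimize_scalar(nll, bounds=(-10, 5), method="bounded",
                                       options={"xatol": 1e-10})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-5)
        tau2 = np.exp(res.x)
        assert fit.psi_community[0, 0] == pytest.approx(tau2, abs=1e-4)

    def test_records_with_nonpositive_sd_dropped(self):
        rec = _toy_records(seed=6)
        rec.loc[rec.index[:3], "sd"] = 0.0
        fit = fit_memr(rec, method="ml", compute_blups=False)
        assert fit.n == len(rec) - 3

    def test_unknown_method_rejected(self):
        with pytest.raises(ContractError):
            fit_memr(_toy_records(), method="mle")


class TestBlups:
    def test_zero_psi_gives_zero_blups(self):
        rec = _toy_records(seed=7)
        fit = _manual_fit(rec, [19.0, 0.2], np.zeros((2, 2)), np.zeros((2, 2)))
        bc, bm = blups(fit, rec)
        assert (bc[["intercept", "time"]].values == 0).all()
        assert (bm[["intercept", "time"]].values == 0).all()

    def test_gls_oracle_on_toy_set(self):
        """BLUPs equal the direct conditional mean G Z' V^{-1} (y - Xb)
        computed with one global covariance matrix."""
        rec = _toy_records(seed=8, n_countries=2, communities_per_country=2,
                           n_periods=3)
        psi1 = np.array([[0.3, 0.05], [0.05, 0.1]])
        psi2 = np.array([[0.2, -0.02], [-0.02, 0.05]])
        fixed = np.array([19.0, 0.2])
        fit = _manual_fit(rec, fixed, psi1, psi2)
        bc, bm = blups(fit, rec)

        df = rec.sort_values(["country_id", "community_id", "w"]).reset_index(
            drop=True
        )
        y = df["estimate"].values
        x = np.column_stack([np.ones(len(df)), df["w"].values])
        z_cols = []
        labels = []
        for cid in sorted(df["country_id"].unique()):
            zi = np.where(
                (df["country_id"] == cid).values[:, None],
                np.column_stack([np.ones(len(df)), df["w"].values]),
                0.0,
            )
            z_cols.append(zi)
            labels.append(("country", cid))
        for mid in sorted(df["community_id"].unique()):
            zj = np.where(
                (df["community_id"] == mid).values[:, None],
                np.column_stack([np.ones(len(df)), df["w"].values]),
                0.0,
            )
            z_cols.append(zj)
            labels.append(("community", mid))
        z = np.hstack(z_cols)
        n_c = df["country_id"].nunique()
        n_m = df["community_id"].nunique()
        g = np.zeros((2 * (n_c + n_m), 2 * (n_c + n_m)))
        for i in range(n_c):
            g[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = psi1
        for j in range(n_m):
            k = 2 * n_c + 2 * j
            g[k : k + 2, k : k + 2] = psi2
        v = z @ g @ z.T + np.diag(df["sd"].values ** 2)
        u = g @ z.T @ np.linalg.solve(v, y - x @ fixed)

        for i, cid in enumerate(sorted(df["country_id"].unique())):
            row = bc[bc.country_id == cid].iloc[0]
            np.testing.assert_allclose(
                [row["intercept"], row["time"]], u[2 * i : 2 * i + 2], atol=1e-8
            )
        for j, mid in enumerate(sorted(df["community_id"].unique())):
            row = bm[bm.community_id == mid].iloc[0]
            k = 2 * n_c + 2 * j
            np.testing.assert_allclose(
                [row["intercept"], row["time"]], u[k : k + 2], atol=1e-8
            )

    def test_noisy_community_shrinks_harder(self):
        """A community whose records carry huge sd is shrunk toward the
        country mean more than an identical but precise community."""
        rows = []
        for mid, sd in (("precise", 0.2), ("noisy", 20.0)):
            for w in range(1, 7):
                rows.append(
                    {
                        "community_id": mid,
                        "country_id": "A",
                        "w": w,
                        "estimate": 22.0,  # both sit 3 above the fixed intercept
                        "sd": sd,
                    }
                )
        rec = pd.DataFrame(rows)
        fit = _manual_fit(rec, [19.0, 0.0], np.zeros((2, 2)), np.diag([1.0, 0.0]))
        _, bm = blups(fit, rec)
        prec = bm[bm.community_id == "precise"]["intercept"].iloc[0]
        noisy = bm[bm.community_id == "noisy"]["intercept"].iloc[0]
        assert abs(noisy) < abs(prec)
        assert prec > 0


class TestLRTest:
    def test_identical_models_give_zero(self):
        rec = _toy_records(seed=9)
        fit = fit_memr(rec, method="ml", compute_blups=False)
        stat, df, p = lr_test(fit, fit)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_random_slope_adds_two_parameters(self):
        rec = _toy_records(seed=10, n_countries=5, communities_per_country=3)
        reduced = fit_memr(
            rec, random=RandomSpec(("intercept", "time"), ("intercept",)),
            method="reml", compute_blups=False,
        )
        full = fit_memr(rec, method="reml", compute_blups=False)
        stat, df, p = lr_test(reduced, full)
        assert df == 2
        assert stat >= 0 and 0 <= p <= 1

    def test_flavor_mismatch_rejected(self):
        rec = _toy_records(seed=11)
        a = fit_memr(rec, method="ml", compute_blups=False)
        b = fit_memr(rec, method="reml", compute_blups=False)
        with pytest.raises(ContractError):
            lr_test(a, b)

    def test_non_nesting_rejected(self):
        rec = _toy_records(seed=12)
        small = fit_memr(rec, random=RandomSpec(("intercept",), ("intercept",)),
                         method="reml", compute_blups=False)
        big = fit_memr(rec, method="reml", compute_blups=False)
        with pytest.raises(ContractError):
            lr_test(big, small)

    def test_aic_bic_definitions(self):
        rec = _toy_records(seed=13)
        fit = fit_memr(rec, method="ml", compute_blups=False)
        k = fit.n_fixed + fit.n_varparams
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
        assert fit.bic == pytest.approx(-2 * fit.loglik + np.log(fit.n) * k)


class TestTrajectory:
    def test_pooled_values_are_affine(self):
        rec = _toy_records(seed=14)
        fit = fit_memr(rec, method="reml", compute_blups=False)
        fit.fixed[:] = [19.5, 0.16]
        tr = pooled_trajectory(fit, np.arange(1, 7))
        assert tr.table["pooled"].iloc[0] == pytest.approx(19.66)
        assert tr.table["pooled"].iloc[-1] == pytest.approx(20.46)
        assert tr.slope == pytest.approx(0.16)

    def test_ci_from_delta_method_oracle(self):
        rec = _toy_records(seed=15)
        fit = fit_memr(rec, method="reml", compute_blups=False)
        tr = pooled_trajectory(fit, np.arange(1, 7))
        cov = fit.cov_fixed.values
        for _, row in tr.table.iterrows():
            c = np.array([1.0, row["w"]])
            se = np.sqrt(c @ cov @ c)
            half = stats.norm.ppf(0.975) * se
            assert row["ci_hi"] - row["pooled"] == pytest.approx(half, rel=1e-9)
        # Wald geometry: widest CI at the extreme w, narrowest near the middle
        widths = (tr.table["ci_hi"] - tr.table["ci_lo"]).values
        assert widths.argmin() in (1, 2, 3, 4)
        assert widths.max() in (widths[0], widths[-1])

    def test_stratified_fits_cover_all_levels(self):
        rec = _toy_records(seed=16, n_countries=4)
        fits = stratified_fits(rec, "region")
        assert set(fits) == set(rec["region"].unique())
        assert all(f is not None for f in fits.values())


class TestATAdjustment:
    def test_time_only_row_matches_plain_fit(self):
        rec = _toy_records(seed=17)
        tab = at_adjustment(rec)
        fit = fit_memr(rec, ("time",), method="reml", compute_blups=False)
        row = tab[(tab.stratum == "all") & (tab.model == "time_only")].iloc[0]
        assert row.time_slope == pytest.approx(fit.fixed["time"], abs=1e-8)

    def test_reports_all_three_models(self):
        rec = _toy_records(seed=18)
        tab = at_adjustment(rec)
        assert set(tab[tab.stratum == "all"].model) == {
            "time_only", "at", "at_centered",
        }
        fitted = tab[tab.stratum == "all"]
        assert np.isfinite(fitted.time_slope).all()
        assert np.isfinite(fitted[fitted.model != "time_only"].gamma).all()


class TestDesignBuilder:
    def test_interaction_columns(self):
        rec = _toy_records(seed=19, n_countries=4,
                           region_labels=["R1", "R1", "R2", "R2"])
        x, names = build_fixed_design(rec, ("time",), interaction="region")
        assert names == ["intercept", "time", "region[R2]", "region[R2]:time"]
        r2 = (rec["region"] == "R2").to_numpy(float)
        np.testing.assert_array_equal(x[:, 2], r2)
        np.testing.assert_array_equal(x[:, 3], r2 * rec["w"].to_numpy(float))

    def test_unknown_term_rejected(self):
        with pytest.raises(ContractError):
            build_fixed_design(_toy_records(), ("time", "humidity"))
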