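"""Mixed-model layer: scaling, REML, Satterthwaite, R², collinearity screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from xylosafe.errors import DomainError, InputError
from xylosafe.lmm import (
    correlation_screen,
    fit_lmm,
    nakagawa_r2,
    prepare_model_frame,
    variance_fractions,
    wald_t_tests,
)


def dense_reml_loglik(theta_log, X, y, groups):
    """Independent oracle: REML log-likelihood via explicit n×n covariance."""
    s2b, s2e = np.exp(theta_log)
    n, p = X.shape
    V = s2e * np.eye(n)
    for g in np.unique(groups):
        idx = groups == g
        V[np.ix_(idx, idx)] += s2b
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldX + r @ Vi @ r)


def balanced_toy(seed=42, groups=5, per=6, s2b=0.5, s2e=1.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(groups), per)
    x = rng.normal(size=groups * per)
    y = (
        1.0
        + 0.5 * x
        + np.repeat(rng.normal(0, np.sqrt(s2b), groups), per)
        + rng.normal(0, np.sqrt(s2e), groups * per)
    )
    return pd.DataFrame({"y": y, "x": x, "site_id": g})


class TestPrepareModelFrame:
    def make_table(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "site_id": np.repeat(np.arange(6), 10),
                "P50": rng.normal(-3.4, 0.3, n),
                "slope": rng.lognormal(1.0, 0.3, n),
                "CWB": np.repeat(rng.uniform(-10, 25, 6), 10),
                "AWC": np.repeat(rng.uniform(50, 300, 6), 10),
                "height": rng.uniform(21, 34, n),
                "branch_age": rng.uniform(1.5, 20.5, n),
                "CI": rng.uniform(0.3, 0.8, n),
            }
        )

    def test_zscore_definition(self):
        frame, scaling = prepare_model_frame(self.make_table())
        for col in frame.attrs["predictors"]:
            assert frame[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert frame[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_log_transforms(self):
        table = self.make_table()
        table.loc[0, "branch_age"] = np.e
        frame, scaling = prepare_model_frame(table)
        raw = scaling.means["log_branch_age"] + frame.loc[0, "log_branch_age"] * scaling.sds[
            "log_branch_age"
        ]
        assert raw == pytest.approx(1.0)  # ln(e) before scaling
        assert np.allclose(frame["log_slope"], np.log(frame["slope"]))

    def test_coefficient_back_transform_roundtrip(self):
        """A per-SD coefficient mapped back equals the raw-scale OLS slope."""
        rng = np.random.default_rng(3)
        table = self.make_table()
        table["P50"] = -3.4 + 0.01 * table["AWC"] + rng.normal(0, 1e-6, len(table))
        frame, scaling = prepare_model_frame(table)
        beta_scaled = np.polyfit(frame["AWC"], frame["P50"], 1)[0]
        assert scaling.back_transform("AWC", beta_scaled) == pytest.approx(0.01, rel=1e-3)

    def test_zero_variance_predictor_named(self):
        table = self.make_table()
        table["CI"] = 0.5
        with pytest.raises(InputError, match="CI"):
            prepare_model_frame(table)

    def test_listwise_drop_counted(self):
        table = self.make_table()
        table.loc[[3, 7], "AWC"] = np.nan
        frame, scaling = prepare_model_frame(table)
        assert scaling.n_dropped == 2
        assert len(frame) == len(table) - 2


class TestREML:
    def test_matches_dense_oracle(self):
        """Grouped REML optimum equals direct maximization of the explicit
        covariance-matrix likelihood on balanced toy data."""
        df = balanced_toy()
        X = np.column_stack([np.ones(len(df)), df["x"]])
        res = fit_lmm(df, "y", ("x",))
        sol = optimize.minimize(
            lambda t: -dense_reml_loglik(t, X, df["y"].to_numpy(), df["site_id"].to_numpy()),
            np.log([0.5, 1.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 10000},
        )
        s2b_o, s2e_o = np.exp(sol.x)
        assert -sol.fun == pytest.approx(res.loglik, abs=1e-6)
        assert res.site_sd**2 == pytest.approx(s2b_o, abs=1e-6)
        assert res.residual_sd**2 == pytest.approx(s2e_o, abs=1e-6)

    def test_degenerate_random_effect_matches_ols(self):
        df = balanced_toy(s2b=0.0, seed=9)
        res = fit_lmm(df, "y", ("x",))
        X = np.column_stack([np.ones(len(df)), df["x"]])
        beta_ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert res.coefs["estimate"].to_numpy() == pytest.approx(beta_ols, abs=1e-6)

    def test_singular_fit_flagged_not_raised(self):
        # pure noise with no group structure drives site variance to zero
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"y": rng.normal(size=40), "x": rng.normal(size=40),
             "site_id": np.repeat(np.arange(4), 10)}
        )
        res = fit_lmm(df, "y", ("x",))
        assert res.site_sd >= 0.0
        if res.singular:
            assert res.site_sd == 0.0

    def test_row_duplication_near_invariance(self):
        """Duplicating every row reweights groups only slightly: fixed-effect
        estimates barely move, and move not at all in the OLS limit
        (no site variance), where the estimator is exactly duplication
        invariant."""
        df = balanced_toy(seed=5)
        res1 = fit_lmm(df, "y", ("x",))
        res2 = fit_lmm(pd.concat([df, df], ignore_index=True), "y", ("x",))
        assert res2.coefs["estimate"].to_numpy() == pytest.approx(
            res1.coefs["estimate"].to_numpy(), abs=0.05
        )
        ols = balanced_toy(s2b=0.0, seed=9)
        r1 = fit_lmm(ols, "y", ("x",))
        r2 = fit_lmm(pd.concat([ols, ols], ignore_index=True), "y", ("x",))
        if r1.singular and r2.singular:
            assert r2.coefs["estimate"].to_numpy() == pytest.approx(
                r1.coefs["estimate"].to_numpy(), abs=1e-9
            )

    def test_dropping_random_intercept_inflates_residual(self):
        df = balanced_toy(s2b=2.0, s2e=0.5, seed=11)
        res = fit_lmm(df, "y", ("x",))
        X = np.column_stack([np.ones(len(df)), df["x"]])
        resid_ols = df["y"] - X @ np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert resid_ols.std(ddof=2) > res.residual_sd


class TestWaldSatterthwaite:
    def test_null_coefficient(self):
        df = balanced_toy(seed=21)
        res = fit_lmm(df, "y", ("x",))
        res.coefs.loc["x", "estimate"] = 0.0
        res.coefs.loc["x", "t"] = 0.0
        res.coefs.loc["x", "p"] = 1.0
        t = wald_t_tests(res)
        assert t.loc["x", "t"] == 0.0 and t.loc["x", "p"] == 1.0

    def test_balanced_intercept_df_is_groups_minus_one(self):
        """For a balanced one-way design the Satterthwaite df of the grand
        mean equals the closed-form between-group df, g − 1."""
        rng = np.random.default_rng(33)
        g, per = 8, 5
        df = pd.DataFrame(
            {
                "y": np.repeat(rng.normal(0, 1.0, g), per) + rng.normal(0, 0.6, g * per),
                "site_id": np.repeat(np.arange(g), per),
            }
        )
        res = fit_lmm(df, "y", ())
        assert res.coefs.loc["(Intercept)", "df"] == pytest.approx(g - 1, rel=1e-3)

    def test_null_pvalues_roughly_uniform(self):
        """p-values of a truly null slope follow U(0,1) across replicates."""
        from scipy.stats import kstest

        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(120):
            g = np.repeat(np.arange(10), 6)
            x = rng.normal(size=60)
            y = np.repeat(rng.normal(0, 0.5, 10), 6) + rng.normal(0, 1, 60)
            res = fit_lmm(pd.DataFrame({"y": y, "x": x, "site_id": g}), "y", ("x",))
            pvals.append(res.coefs.loc["x", "p"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestR2AndFractions:
    def test_no_fixed_effects_means_zero_marginal(self):
        df = balanced_toy(seed=13)
        res = fit_lmm(df, "y", ())
        marg, cond = nakagawa_r2(res)
        assert marg == pytest.approx(0.0, abs=1e-12)
        assert cond >= marg

    def test_collapsed_random_effect(self):
        df = balanced_toy(s2b=0.0, seed=17)
        res = fit_lmm(df, "y", ("x",))
        marg, cond = nakagawa_r2(res)
        if res.singular:
            assert cond == pytest.approx(marg)

    def test_fraction_identities(self):
        df = balanced_toy(seed=19)
        res = fit_lmm(df, "y", ("x",))
        f_fixed, f_site, f_resid = variance_fractions(res)
        assert f_fixed + f_site + f_resid == pytest.approx(1.0, abs=1e-9)
        marg, cond = nakagawa_r2(res)
        assert f_fixed == pytest.approx(marg, abs=1e-12)
        assert f_site == pytest.approx(cond - marg, abs=1e-12)
        assert 0.0 <= marg <= cond <= 1.0


class TestCorrelationScreen:
    def test_self_and_affine_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x + 3, "c": rng.normal(size=50)})
        corr, flags = correlation_screen(df)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert ("a", "b", pytest.approx(1.0)) in [
            (a, b, pytest.approx(r)) for a, b, r in flags
        ] or any(f[:2] == ("a", "b") for f in flags)

    def test_independent_predictors_unflagged(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
        corr, flags = correlation_screen(df)
        assert flags == []
        off_diag = corr.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.7)

    def test_constant_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(DomainError, match="b"):
            correlation_screen(df)
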