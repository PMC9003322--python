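"""Mixed-effects logistic screening: likelihood correctness, Wald
transforms, the bivariate entry rule, and collinearity gatekeeping."""

import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mmdnet import (
    ScreenConfig,
    bivariate_screen,
    collinearity_filter,
    fit_logistic_random_intercept,
)


def test_single_cluster_two_by_two_closed_form():
    """Saturated logistic MLE equals the cross-product odds ratio:
    (40*75)/(60*25) = 2.0."""
    y = np.r_[np.ones(40), np.zeros(60), np.ones(25), np.zeros(75)]
    x = np.r_[np.ones(100), np.zeros(100)]
    fit = fit_logistic_random_intercept(y, x[:, None], np.zeros(200), names=["exposed"])
    assert fit.odds_ratios["exposed"][0] == pytest.approx(2.0, abs=1e-4)
    assert fit.random_intercept_variance == 0.0
    assert fit.converged


def test_zero_cluster_variance_matches_plain_logistic():
    """With no between-cluster heterogeneity in the generator, the mixed
    fit's fixed effects agree with ordinary logistic regression (oracle:
    Newton-Raphson fit from statsmodels) within 1e-3 on the log-odds."""
    rng = np.random.default_rng(0)
    n = 3000
    X = rng.standard_normal((n, 2))
    cluster = rng.integers(0, 7, n)
    eta = -0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic_random_intercept(y, X, cluster, names=["a", "b"])
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    for got, want in zip(
            [fit.coef("intercept"), fit.coef("a"), fit.coef("b")], ref.params):
        assert got == pytest.approx(want, abs=1e-3)
    assert fit.random_intercept_variance < 0.01


def test_matches_lme4_glmer_on_clustered_data(tmp_path):
    """Independent oracle: lme4's glmer (adaptive GH, nAGQ=15) on a
    cohort with a real random intercept."""
    rng = np.random.default_rng(42)
    n = 800
    cluster = rng.integers(0, 7, n)
    u = rng.normal(0, 0.6, 7)
    x = rng.standard_normal(n)
    eta = -0.4 + 0.7 * x + u[cluster]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    csv = tmp_path / "fixture.csv"
    pd.DataFrame(dict(y=y, x=x, cl=cluster)).to_csv(csv, index=False)
    r_code = (
        'suppressMessages(library(lme4));'
        f'd <- read.csv("{csv}");'
        'm <- glmer(y ~ x + (1|cl), data=d, family=binomial, nAGQ=15);'
        'cat(fixef(m), sqrt(unlist(VarCorr(m))), sep="\\n")'
    )
    proc = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                          text=True, timeout=120)
    assert proc.returncode == 0, proc.stderr
    ref_intercept, ref_slope, ref_sd = (float(v) for v in proc.stdout.split())
    fit = fit_logistic_random_intercept(y, x[:, None], cluster, names=["x"])
    assert fit.coef("intercept") == pytest.approx(ref_intercept, abs=5e-3)
    assert fit.coef("x") == pytest.approx(ref_slope, abs=5e-3)
    assert np.sqrt(fit.random_intercept_variance) == pytest.approx(ref_sd, abs=1e-2)


def test_null_covariate_seven_clusters():
    rng = np.random.default_rng(1)
    n = 7000
    x = rng.standard_normal(n)
    cluster = np.repeat(np.arange(7), n // 7)
    y = (rng.random(n) < 0.4).astype(float)
    fit = fit_logistic_random_intercept(y, x[:, None], cluster, names=["x"])
    assert 0.9 < fit.odds_ratios["x"][0] < 1.1
    assert fit.random_intercept_variance < 0.01


def test_wald_interval_transform_consistency():
    rng = np.random.default_rng(2)
    n = 1500
    x = rng.standard_normal(n)
    cluster = rng.integers(0, 4, n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.5 * x)))).astype(float)
    fit = fit_logistic_random_intercept(y, x[:, None], cluster, names=["x"])
    from scipy.stats import norm
    z = norm.ppf(0.975)
    est, se, _ = fit.coefficients["x"]
    or_, lo, hi = fit.odds_ratios["x"]
    assert or_ == pytest.approx(np.exp(est), rel=1e-12)
    assert lo == pytest.approx(np.exp(est - z * se), rel=1e-9)
    assert hi == pytest.approx(np.exp(est + z * se), rel=1e-9)
    assert lo < or_ < hi


def test_missing_values_rejected():
    with pytest.raises(ValueError):
        fit_logistic_random_intercept(
            np.array([0.0, 1.0]), np.array([[1.0], [np.nan]]), np.zeros(2))


def test_planted_sex_effect_recovered_at_scale_20(scale20_table):
    """The generator plants a female-sex log-odds of log(0.72) on MMD; the
    bivariate mixed fit's confidence interval covers it."""
    fit = fit_logistic_random_intercept(
        scale20_table["mmd"], scale20_table[["female"]], scale20_table["site"])
    or_, lo, hi = fit.odds_ratios["female"]
    assert lo < 0.72 < hi
    assert fit.converged
    # countries genuinely differ in prevalence -> positive variance
    assert fit.random_intercept_variance > 0.2


class TestBivariateScreen:
    @pytest.fixture(scope="class")
    def screen_table(self):
        rng = np.random.default_rng(5)
        n = 1200
        site = rng.integers(0, 7, n).astype(str)
        strong = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        eta = -0.2 + 0.9 * strong
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return pd.DataFrame(dict(
            mmd=y, site=site, strong=strong, noise=noise,
            constant=np.ones(n)))

    def test_strong_effect_retained_null_and_constant_excluded(self, screen_table):
        retained, ledger = bivariate_screen(
            screen_table, ["strong", "noise", "constant"])
        assert "strong" in retained
        ledger = ledger.set_index("covariate")
        assert ledger.loc["strong", "p_value"] < 1e-4
        assert ledger.loc["constant", "reason"] == "zero variance"
        assert not ledger.loc["constant", "retained"]

    def test_entry_rule_is_strict(self, screen_table):
        retained, ledger = bivariate_screen(
            screen_table, ["noise"], ScreenConfig(entry_p=0.20))
        p = ledger.set_index("covariate").loc["noise", "p_value"]
        assert ("noise" in retained) == (p < 0.20)
        # a p-value exactly at the cut-off is excluded
        at_cutoff, _ = bivariate_screen(
            screen_table, ["noise"], ScreenConfig(entry_p=max(p, 1e-12)))
        assert "noise" not in at_cutoff


class TestCollinearity:
    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"a": rng.standard_normal(500)})
        table["b"] = table["a"]
        table["c"] = rng.standard_normal(500)
        kept, flagged, vifs = collinearity_filter(table, ["a", "b", "c"])
        assert {(r["a"], r["b"]) for r in flagged.to_dict("records")} == {("a", "b")}
        assert flagged["rho"].iloc[0] == pytest.approx(1.0)
        assert "b" not in kept and "a" in kept and "c" in kept

    def test_independent_columns_not_flagged_and_unit_vif(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.standard_normal((8000, 3)), columns=["a", "b", "c"])
        kept, flagged, vifs = collinearity_filter(table, ["a", "b", "c"])
        assert flagged.empty
        assert kept == ["a", "b", "c"]
        assert np.allclose(vifs.to_numpy(), 1.0, atol=0.02)

    def test_orthogonal_design_exact_unit_vif(self):
        # QR against an explicit intercept column gives mean-zero, mutually
        # orthogonal covariates, so every R^2 is exactly 0 and VIF = 1
        a = np.column_stack([np.ones(64),
                             np.random.default_rng(2).standard_normal((64, 3))])
        q, _ = np.linalg.qr(a)
        table = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
        _, _, vifs = collinearity_filter(table, ["a", "b", "c"])
        assert np.allclose(vifs.to_numpy(), 1.0, atol=1e-8)

    def test_priority_list_breaks_ties(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(400)
        table = pd.DataFrame({"z_log_mpo": x, "shadow": x + 0.01 * rng.standard_normal(400)})
        kept, flagged, _ = collinearity_filter(
            table, ["shadow", "z_log_mpo"],
            ScreenConfig(priority=("z_vitamin_c", "z_log_mpo", "female")))
        assert kept == ["z_log_mpo"]

    def test_constant_covariate_vif_missing(self):
        table = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        _, _, vifs = collinearity_filter(table, ["a", "b"])
        assert np.isnan(vifs["a"])
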