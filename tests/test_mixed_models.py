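import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from whipkin.mixed_models import (
    ModelError,
    fit_error_correlation,
    fit_style_block_model,
    likelihood_ratio_select,
    likelihood_ratio_test,
)
from whipkin.synthetic_scene import CohortParams, simulate_cohort


@pytest.fixture(scope="module")
def gaussian_cohort():
    cp = CohortParams(
        seed=101, beta_style=0.10, beta_block=-0.009, beta_interaction=0.004
    )
    return simulate_cohort(cp)


class TestStyleBlockModel:
    def test_planted_effects_within_ci(self, gaussian_cohort):
        tab, planted = gaussian_cohort
        res = fit_style_block_model(tab, "y")
        for term, key in (("S", "beta_style"), ("B", "beta_block"), ("S:B", "beta_interaction")):
            lo, hi = res.ci(term)
            assert lo <= planted[key] <= hi

    def test_binomial_logit_recovery(self):
        cp = CohortParams(
            seed=7, family="binomial", intercept=-0.5, beta_style=-1.0,
            beta_block=0.15, sd_intercept=0.4, sd_style=0.2, sd_block=0.0,
        )
        tab, planted = simulate_cohort(cp)
        res = fit_style_block_model(tab, "y", family="binomial")
        assert res.family == "binomial-logit"
        lo, hi = res.ci("S")
        assert lo <= planted["beta_style"] <= hi

    def test_style_constant_raises(self, gaussian_cohort):
        tab, _ = gaussian_cohort
        with pytest.raises(ModelError):
            fit_style_block_model(tab[tab["style"] == "discrete"], "y")

    def test_single_participant_raises(self, gaussian_cohort):
        tab, _ = gaussian_cohort
        with pytest.raises(ModelError):
            fit_style_block_model(tab[tab["participant"] == "P01"], "y")

    def test_balanced_design_matches_ols(self):
        """With no participant heterogeneity and a balanced design the LMM
        fixed effects coincide with ordinary least squares."""
        cp = CohortParams(
            seed=3, sd_intercept=0.0, sd_style=0.0, sd_block=0.0,
            n_participants=6, trials_per_block=10,
        )
        tab, _ = simulate_cohort(cp)
        res = fit_style_block_model(tab, "y", re_formula="~1")
        ols = smf.ols("y ~ S + B + S:B", tab).fit()
        for term in ("Intercept", "S", "B", "S:B"):
            assert res.estimate(term) == pytest.approx(ols.params[term], abs=1e-6)


class TestErrorCorrelation:
    def test_rhythmic_only_slope_recovered(self):
        cp = CohortParams(
            seed=11, beta_x=0.0, beta_sx=-0.153, sd_x=0.02,
            x_mean=1.43, x_sd=0.07, intercept=0.3, beta_style=0.05,
            beta_block=0.0, sd_block=0.0, residual_sd=0.08,
        )
        tab, planted = simulate_cohort(cp)
        tab = tab.rename(columns={"y": "error"})
        res = fit_error_correlation(tab, "x")
        lo, hi = res.ci("X")
        assert lo <= 0.0 <= hi  # no slope planted in the discrete style
        lo, hi = res.ci("S:X")
        assert lo <= planted["beta_sx"] <= hi
        # per-style slopes: discrete = bX, rhythmic = bX + bSX
        assert res.estimate("slope_discrete") == pytest.approx(res.estimate("X"))
        assert res.estimate("slope_rhythmic") == pytest.approx(
            res.estimate("X") + res.estimate("S:X")
        )

    def test_uncorrelated_covariate_not_significant(self):
        hits = 0
        for r in range(12):
            cp = CohortParams(
                seed=500 + r, beta_x=0.0, beta_sx=0.0, sd_x=0.0,
                x_mean=0.0, x_sd=1.0, residual_sd=0.1, with_covariate=True,
            )
            tab, _ = simulate_cohort(cp)
            tab = tab.rename(columns={"y": "error"})
            res = fit_error_correlation(tab, "x")
            hits += float(res.fixed.loc["X", "pvalue"]) < 0.05
        assert hits <= 2  # ~alpha of 12 null fits

    def test_single_participant_falls_back_to_fixed_only(self):
        cp = CohortParams(seed=2, n_participants=1, beta_x=0.2, sd_x=0.0, x_sd=1.0)
        tab, _ = simulate_cohort(cp)
        tab = tab.rename(columns={"y": "error"})
        res = fit_error_correlation(tab, "x")
        assert res.method == "OLS"
        assert any(t.get("event") == "single_participant_fixed_only" for t in res.trace)

    def test_degenerate_covariate_rejected(self, gaussian_cohort):
        tab, _ = gaussian_cohort
        tab = tab.rename(columns={"y": "error"}).assign(const_x=1.0)
        with pytest.raises(ModelError):
            fit_error_correlation(tab, "const_x")


class TestLikelihoodRatio:
    def test_identical_models_statistic_zero(self, gaussian_cohort):
        tab, _ = gaussian_cohort
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "y ~ S", tab, groups=tab["participant"]
            ).fit(reml=False, method="bfgs")
        stat, dof, p = likelihood_ratio_test(fit, fit)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert dof == 0 and p == 1.0

    def test_non_nested_comparison_rejected(self, gaussian_cohort):
        tab, _ = gaussian_cohort
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = smf.mixedlm("y ~ S", tab, groups=tab["participant"]).fit(
                reml=False, method="bfgs"
            )
            f2 = smf.mixedlm("y ~ B", tab, groups=tab["participant"]).fit(
                reml=False, method="bfgs"
            )
        with pytest.raises(ModelError):
            likelihood_ratio_test(f1, f2)

    def test_strong_effects_retained(self, gaussian_cohort):
        tab, _ = gaussian_cohort
        retained, trace = likelihood_ratio_select(tab, "y")
        assert "S" in retained and "B" in retained
        assert all("term" in rec or "event" in rec for rec in trace)

    def test_strong_interaction_retained(self):
        cp = CohortParams(seed=21, beta_interaction=0.05)
        tab, _ = simulate_cohort(cp)
        retained, _ = likelihood_ratio_select(tab, "y")
        assert "S:B" in retained

    def test_interaction_skipped_without_main_effects(self):
        cp = CohortParams(
            seed=22, beta_style=0.0, beta_block=0.0, beta_interaction=0.0,
            sd_style=0.0, sd_block=0.0,
        )
        tab, _ = simulate_cohort(cp)
        retained, trace = likelihood_ratio_select(tab, "y")
        tested_terms = {rec.get("term") for rec in trace}
        assert "S" in tested_terms and "B" in tested_terms


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstLme4:
    def test_fixed_effects_match_lme4(self, tmp_path, gaussian_cohort):
        """Independent cross-check of the Gaussian LMM against lme4."""
        tab, _ = gaussian_cohort
        sub = tab[tab["participant"].isin(sorted(tab["participant"].unique())[:8])]
        csv = tmp_path / "cohort.csv"
        sub.to_csv(csv, index=False)
        out = tmp_path / "fe.csv"
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(y ~ S*B + (1 + S | participant), data=d, REML=TRUE)
        write.csv(data.frame(term=names(fixef(m)), est=fixef(m)), "{out}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        r_fe = pd.read_csv(out).set_index("term")["est"]
        res = fit_style_block_model(sub, "y", re_formula="~S")
        assert res.estimate("Intercept") == pytest.approx(r_fe["(Intercept)"], abs=1e-3)
        assert res.estimate("S") == pytest.approx(r_fe["S"], abs=1e-3)
        assert res.estimate("B") == pytest.approx(r_fe["B"], abs=1e-3)
        assert res.estimate("S:B") == pytest.approx(r_fe["S:B"], abs=1e-3)
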