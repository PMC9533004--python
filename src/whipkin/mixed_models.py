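"""Mixed-effects models of task performance.

Two model families are fitted at the trial level:

* the style-by-block model
  ``Y_ij = (b0 + P0i) + (bS + PSi) S_j + (bB + PBi) B_j + bSB S_j B_j + e_ij``
  with style ``S`` coded discrete = 0 / rhythmic = 1 (a positive style
  coefficient means the metric is larger in the rhythmic style), block
  ``B`` numeric 1-5, and participant random intercepts and slopes;
  hit/miss responses use a binomial GLMM with a logit link, all other
  metrics a Gaussian LMM;

* the error-correlation model
  ``E_ij = (b0 + P0i) + (bS + PSi) S_j + (bX + PXi) X_j + bSX S_j X_j + e_ij``
  which tests whether a covariate ``X`` (whip extension, whip azimuth,
  peak hand or tip speed) correlates with error in each style; the
  per-style slopes are ``bX`` (discrete) and ``bX + bSX`` (rhythmic).

Final estimates use restricted maximum likelihood; model selection uses
maximum-likelihood likelihood-ratio tests at alpha = 0.05.  Gaussian
p-values use a t reference with between-participant degrees of freedom
(a coarse small-sample correction); the binomial GLMM is fitted by a
Laplace (posterior-mode) approximation and reports posterior-mode/SD
z-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

__all__ = [
    "MixedModelResult",
    "ModelError",
    "fit_style_block_model",
    "fit_error_correlation",
    "likelihood_ratio_test",
    "likelihood_ratio_select",
]

ALPHA = 0.05


class ModelError(ValueError):
    """The data do not support the requested model."""


@dataclass
class MixedModelResult:
    """Fixed-effect estimates, random-effect variances and fit metadata."""

    fixed: pd.DataFrame  # index: term; columns: estimate, se, z, pvalue
    random_variances: dict[str, float]
    loglike: float
    family: str
    method: str
    converged: bool
    trace: list[dict] = field(default_factory=list)
    df: float | None = None  # between-participant df for t-based inference

    def estimate(self, term: str) -> float:
        return float(self.fixed.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.fixed.loc[term, "se"])

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        q = 0.5 + level / 2.0
        crit = stats.t.ppf(q, self.df) if self.df else stats.norm.ppf(q)
        est, se = self.estimate(term), self.se(term)
        return est - crit * se, est + crit * se


def _prep(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if "S" not in df:
        if "style" not in df:
            raise ModelError("table needs a 'style' or 'S' column")
        levels = set(df["style"].unique())
        if not levels <= {"discrete", "rhythmic"}:
            raise ModelError(f"unknown style levels: {levels}")
        df["S"] = (df["style"] == "rhythmic").astype(float)
    if "B" not in df and "block" in df:
        df["B"] = df["block"].astype(float)
    if "participant" not in df:
        raise ModelError("table needs a 'participant' column")
    return df


def _fixed_frame(names, est, se, df: float | None = None) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.nan)
    if df:
        p = 2 * stats.t.sf(np.abs(z), df)
    else:
        p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"estimate": est, "se": se, "z": z, "pvalue": p}, index=list(names)
    )


def _fit_lmm(
    df: pd.DataFrame,
    formula: str,
    re_formula: str,
    reml: bool,
    trace: list[dict],
) -> "sm.regression.mixed_linear_model.MixedLMResults":
    """Fit a MixedLM, reducing the random structure if the fit is singular."""
    reductions = [re_formula]
    if re_formula not in ("~1", "1"):
        reductions.append("~1")
    last_exc: Exception | None = None
    for rf in reductions:
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(
                        formula, df, groups=df["participant"], re_formula=rf
                    )
                    fit = model.fit(reml=reml, method=method)
                singular = not np.isfinite(fit.llf) or np.any(
                    np.diag(np.atleast_2d(fit.cov_re)) < 0
                )
                if fit.converged and not singular:
                    if rf != re_formula:
                        trace.append(
                            {
                                "event": "random_structure_reduced",
                                "from": re_formula,
                                "to": rf,
                            }
                        )
                    return fit
            except Exception as exc:  # np.linalg.LinAlgError etc.
                last_exc = exc
                continue
    raise ModelError(f"mixed model failed to converge: {last_exc}")


def _lmm_result(fit, family: str, method: str, trace: list[dict]) -> MixedModelResult:
    names = list(fit.model.exog_names)
    # coarse small-sample correction: t-inference on between-participant df
    df = max(float(fit.model.n_groups - 2), 3.0)
    fixed = _fixed_frame(names, fit.fe_params, fit.bse_fe, df=df)
    cov_re = np.atleast_2d(np.asarray(fit.cov_re, dtype=float))
    re_names = list(getattr(fit.model.data, "exog_re_names", None) or [])
    if len(re_names) != cov_re.shape[0]:
        re_names = [f"re{i}" for i in range(cov_re.shape[0])]
    variances = {n: float(cov_re[i, i]) for i, n in enumerate(re_names)}
    variances["residual"] = float(fit.scale)
    return MixedModelResult(
        fixed=fixed,
        random_variances=variances,
        loglike=float(fit.llf),
        family=family,
        method=method,
        converged=bool(fit.converged),
        trace=trace,
        df=df,
    )


def fit_style_block_model(
    table: pd.DataFrame,
    response: str,
    family: str = "gaussian",
    reml: bool = True,
    re_formula: str = "~S+B",
) -> MixedModelResult:
    """Fit the 2 x 5 style-by-block mixed model for one metric.

    ``table`` must carry participant, style (or S), block (or B) and the
    response column.  ``family="binomial"`` fits a logit GLMM (for
    hit/miss); otherwise a Gaussian LMM with participant random intercepts
    and style/block slopes.
    """
    df = _prep(table).dropna(subset=[response])
    if df["participant"].nunique() < 2:
        raise ModelError("need >=2 participants")
    if df["S"].nunique() < 2:
        raise ModelError("both styles must be present")
    trace: list[dict] = []
    formula = f"{response} ~ S + B + S:B"
    if family == "binomial":
        vc = {"participant": "0 + C(participant)", "style_slope": "0 + C(participant):S"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = BinomialBayesMixedGLM.from_formula(formula, vc, df)
            fit = model.fit_map()  # Laplace (posterior-mode) fit
        fixed = _fixed_frame(fit.model.exog_names, fit.fe_mean, fit.fe_sd)
        variances = {
            name: float(np.exp(2 * m))
            for name, m in zip(fit.model.names[len(fit.fe_mean):], fit.vcp_mean)
        }
        return MixedModelResult(
            fixed=fixed,
            random_variances=variances,
            loglike=float("nan"),
            family="binomial-logit",
            method="laplace-map",
            converged=True,
            trace=trace,
        )
    fit = _fit_lmm(df, formula, re_formula, reml, trace)
    return _lmm_result(fit, "gaussian", "REML" if reml else "ML", trace)


def fit_error_correlation(
    table: pd.DataFrame,
    covariate: str,
    response: str = "error",
    reml: bool = True,
) -> MixedModelResult:
    """Fit the error-vs-covariate correlation LMM.

    Adds derived rows ``slope_discrete`` (= bX) and ``slope_rhythmic``
    (= bX + bSX) to the fixed-effects table.  With a single participant the
    random effects drop to an ordinary regression, recorded in the trace.
    """
    df = _prep(table).dropna(subset=[response, covariate]).copy()
    if df[covariate].std(ddof=0) < 1e-12:
        raise ModelError(f"covariate {covariate!r} has zero variance")
    df = df.rename(columns={covariate: "X"})
    trace: list[dict] = []
    formula = f"{response} ~ S + X + S:X"
    if df["participant"].nunique() < 2:
        trace.append({"event": "single_participant_fixed_only"})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols(formula, df).fit()
        fixed = _fixed_frame(fit.model.exog_names, fit.params, fit.bse)
        cov = fit.cov_params().to_numpy()
        result = MixedModelResult(
            fixed=fixed,
            random_variances={"residual": float(fit.mse_resid)},
            loglike=float(fit.llf),
            family="gaussian",
            method="OLS",
            converged=True,
            trace=trace,
        )
        names = list(fit.model.exog_names)
    else:
        fit = _fit_lmm(df, formula, "~S+X", reml, trace)
        result = _lmm_result(fit, "gaussian", "REML" if reml else "ML", trace)
        cov = np.asarray(fit.cov_params())[: len(fit.fe_params), : len(fit.fe_params)]
        names = list(fit.model.exog_names)
    ix, isx = names.index("X"), names.index("S:X")
    bx, bsx = result.fixed["estimate"].iloc[ix], result.fixed["estimate"].iloc[isx]
    se_d = np.sqrt(max(cov[ix, ix], 0.0))
    se_r = np.sqrt(max(cov[ix, ix] + cov[isx, isx] + 2 * cov[ix, isx], 0.0))
    extra = _fixed_frame(["slope_discrete", "slope_rhythmic"], [bx, bx + bsx], [se_d, se_r])
    result.fixed = pd.concat([result.fixed, extra])
    return result


def likelihood_ratio_test(fit_small, fit_big) -> tuple[float, int, float]:
    """Chi-squared LRT between two nested ML fits.

    Returns (statistic, df, p-value); raises :class:`ModelError` when the
    models are not nested (by exogenous term sets) or have unequal data.
    """
    small_terms = set(fit_small.model.exog_names)
    big_terms = set(fit_big.model.exog_names)
    if not small_terms <= big_terms:
        raise ModelError("models are not nested")
    if fit_small.model.endog.shape != fit_big.model.endog.shape:
        raise ModelError("models fitted on different data")
    df_small = len(fit_small.params)
    df_big = len(fit_big.params)
    stat = max(0.0, 2.0 * (fit_big.llf - fit_small.llf))
    dof = max(df_big - df_small, 0)
    if dof == 0:
        return stat, 0, 1.0
    return stat, dof, float(stats.chi2.sf(stat, dof))


def likelihood_ratio_select(
    table: pd.DataFrame,
    response: str,
    terms: tuple[str, ...] = ("S", "B", "S:B"),
    re_formula: str = "~1",
    alpha: float = ALPHA,
) -> tuple[list[str], list[dict]]:
    """Forward selection of fixed-effect terms by ML likelihood-ratio tests.

    Starting from an intercept-plus-random-intercept model, each candidate
    term is added in order and retained when the chi-squared LRT rejects at
    ``alpha``.  Returns (retained terms, selection trace); every comparison
    is recorded with its statistic, degrees of freedom and p-value.
    """
    df = _prep(table).dropna(subset=[response])
    trace: list[dict] = []
    retained: list[str] = []
    current_formula = f"{response} ~ 1"
    current_fit = _fit_lmm(df, current_formula, re_formula, reml=False, trace=trace)
    for term in terms:
        if ":" in term and not all(p in retained for p in term.split(":")):
            # interactions only considered once their main effects are in
            trace.append({"term": term, "skipped": "main effects not retained"})
            continue
        candidate = current_formula + f" + {term}"
        try:
            cand_fit = _fit_lmm(df, candidate, re_formula, reml=False, trace=trace)
        except ModelError as exc:
            trace.append({"term": term, "error": str(exc)})
            continue
        stat, dof, p = likelihood_ratio_test(current_fit, cand_fit)
        keep = p < alpha
        trace.append(
            {"term": term, "lrt_stat": stat, "df": dof, "pvalue": p, "retained": keep}
        )
        if keep:
            retained.append(term)
            current_formula, current_fit = candidate, cand_fit
    return retained, trace
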