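"""Cohort statistics for the odds of high cognitive fatigue.

Implements the clinical-statistics ledger around the behavioural scores:
median dichotomization, distribution-gated two-group comparisons
(Shapiro-Wilk -> t / Welch / Mann-Whitney; chi-square for categorical
variables), unconditional binomial logistic regression with Wald
inference, univariate screening at p <= 0.25, covariate-adjusted models
(age, sex, disease duration, EDSS, anxiety, depression), a spline-based
check of logit linearity, and the power/dropout sample-size arithmetic.

Logistic fits go through statsmodels (IRLS maximum likelihood); odds
ratios are exp(beta) with 95% Wald intervals exp(beta +/- 1.96 SE),
matching the coefficient-(SE) presentation convention of clinical tables.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline

from .errors import EmptyInputError, InvalidInputError, InvalidParameterError
from .intero import InteroScores

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's clinical, behavioural and demographic summary."""

    id: str
    age_years: float
    sex: str
    education_years: float
    edss: float
    disease_duration_years: float
    hads_a: int
    hads_d: int
    ess: int
    mfis_cog: int
    mfis_phys: int
    mfis_soc: int
    mfis_tot: int
    intero_scores: InteroScores | None = None
    metacog_efficiency_visual: float = float("nan")
    metacog_efficiency_memory: float = float("nan")
    dmt_class: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 <= self.edss <= 10.0 or (self.edss * 2) % 1 != 0:
            raise InvalidInputError(f"EDSS must be 0-10 in half steps, got {self.edss}")
        for name, hi in (("hads_a", 21), ("hads_d", 21), ("ess", 24), ("mfis_tot", 84)):
            v = getattr(self, name)
            if not 0 <= v <= hi:
                raise InvalidInputError(f"{name} must lie in [0, {hi}], got {v}")
        if self.mfis_tot != self.mfis_cog + self.mfis_phys + self.mfis_soc:
            raise InvalidInputError("mfis_tot must equal the sum of its sub-scales")


@dataclass(frozen=True)
class ModelFit:
    """A fitted logistic model: Wald summary per term plus diagnostics."""

    terms: tuple
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    n: int
    converged: bool
    deviance: float
    warnings_: tuple = ()

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        return {
            "coef": float(self.coefficients[i]),
            "se": float(self.standard_errors[i]),
            "or": float(self.odds_ratios[i]),
            "ci": (float(self.ci_lower[i]), float(self.ci_upper[i])),
            "p": float(self.p_values[i]),
        }

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coefficients,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p_value": self.p_values,
            }
        )


@dataclass(frozen=True)
class GroupComparison:
    """One between-group test with the gating diagnostics that selected it."""

    variable: str
    test_used: str  # "t" | "welch" | "mann_whitney" | "chi2"
    statistic: float
    p_value: float
    normality_p: float = float("nan")
    variance_ratio_p: float = float("nan")


# ---------------------------------------------------------------------------
# Dichotomization and sample-size arithmetic
# ---------------------------------------------------------------------------


def dichotomize(values, cutoff="median", rule: str = "ge") -> tuple[np.ndarray, float]:
    """Binary labels (1 iff value >= cutoff) and the cutoff used.

    ``cutoff="median"`` uses the sample median of non-missing values with
    midpoint interpolation for even n; missing values stay missing (NaN).
    """
    if rule != "ge":
        raise InvalidParameterError("only the '>= cutoff' rule is supported")
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise EmptyInputError("all values missing")
    cut = float(np.median(v[finite])) if cutoff == "median" else float(cutoff)
    labels = np.where(finite, (v >= cut).astype(float), np.nan)
    return labels, cut


def sample_size_adjust(n_per_group: int, dropout_rate: float) -> int:
    """Inflate a per-group sample size for anticipated dropout: ceil(n / (1 - rate))."""
    if n_per_group < 1:
        raise InvalidParameterError("n_per_group must be >= 1")
    if not 0.0 <= dropout_rate < 1.0:
        raise InvalidParameterError("dropout_rate must lie in [0, 1)")
    return math.ceil(n_per_group / (1.0 - dropout_rate))


def two_sample_t_sample_size(mean_diff: float, sd: float, alpha: float, power: float) -> int:
    """Per-group n for a two-sided two-sample t test (normal approximation).

    n = 2 * ((z_{1-alpha/2} + z_{power}) * sd / mean_diff)^2, rounded up.
    Both alpha and power must be supplied explicitly.
    """
    if mean_diff == 0:
        raise InvalidParameterError("mean_diff must be non-zero")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise InvalidParameterError("alpha and power must lie in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return math.ceil(2.0 * (z * sd / mean_diff) ** 2)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


def _as_design(X) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if "const" not in X.columns and not (X.nunique() == 1).any():
        X = sm.add_constant(X)
    return X


def _check_collinearity(X: pd.DataFrame) -> None:
    M = X.to_numpy()
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify the first column that adds no rank
        bad = []
        for j in range(1, M.shape[1] + 1):
            if np.linalg.matrix_rank(M[:, :j]) < j:
                bad.append(X.columns[j - 1])
        raise InvalidInputError(f"singular design; collinear columns: {bad}")


def fit_logistic(y, X, max_abs_coef: float = 15.0) -> ModelFit:
    """Unconditional binomial logistic regression with Wald inference.

    Fits by IRLS maximum likelihood (statsmodels GLM, binomial family);
    standard errors come from the inverse observed information.  A fit
    whose IRLS did not converge or whose coefficients run away beyond
    ``max_abs_coef`` (the signature of quasi-complete separation) is
    returned with ``converged=False`` and a diagnostic, never silently.
    """
    y = np.asarray(y, dtype=float)
    X = _as_design(X)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    if len(y) == 0:
        raise EmptyInputError("no complete cases")
    if y.min() == y.max():
        raise InvalidInputError("both outcome classes must be present")
    _check_collinearity(X)

    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
    for w in caught:
        if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
            warns.append(str(w.message))

    coefs = np.asarray(res.params)
    ses = np.asarray(res.bse)
    converged = bool(res.converged) and np.isfinite(ses).all() and (np.abs(coefs) < max_abs_coef).all()
    if not converged and not warns:
        warns.append("possible quasi-complete separation: runaway coefficients or infinite SEs")
    if not converged:
        logger.warning("logistic fit flagged non-converged: %s", "; ".join(warns))

    z = coefs / ses
    p = 2.0 * stats.norm.sf(np.abs(z))
    return ModelFit(
        terms=tuple(X.columns),
        coefficients=coefs,
        standard_errors=ses,
        odds_ratios=np.exp(coefs),
        ci_lower=np.exp(coefs - Z_95 * ses),
        ci_upper=np.exp(coefs + Z_95 * ses),
        p_values=p,
        n=len(y),
        converged=converged,
        deviance=float(res.deviance),
        warnings_=tuple(warns),
    )


def univariate_screen(
    y, candidates: pd.DataFrame, alpha_screen: float = 0.25
) -> tuple[list[str], dict[str, ModelFit]]:
    """Single-predictor logistic fits with retention at p <= ``alpha_screen``.

    Returns (retained predictor names, full per-predictor fit table).
    Per-predictor failures are recorded as absent fits, not fatal.
    """
    if candidates.shape[1] == 0:
        raise EmptyInputError("no candidate predictors")
    fits: dict[str, ModelFit] = {}
    retained: list[str] = []
    for name in candidates.columns:
        try:
            fit = fit_logistic(y, candidates[[name]])
        except (InvalidInputError, EmptyInputError) as exc:
            logger.warning("screening fit for %r failed: %s", name, exc)
            continue
        fits[name] = fit
        if fit.term(name)["p"] <= alpha_screen:
            retained.append(name)
    return retained, fits


DEFAULT_COVARIATES = ("age_years", "sex", "disease_duration_years", "edss", "hads_a", "hads_d")


def fit_adjusted_model(
    y, predictor: pd.Series, covariates: pd.DataFrame, epp_warn_threshold: float = 10.0
) -> ModelFit:
    """Full additive model: predictor plus covariates.

    Computes the events-per-predictor ratio (rarer outcome count divided by
    the number of non-intercept model terms) and attaches a caution when it
    falls below ``epp_warn_threshold``, since such models are unstable.
    """
    X = pd.concat([predictor, covariates], axis=1)
    fit = fit_logistic(y, X)
    n_events = min(np.nansum(np.asarray(y)), np.nansum(1 - np.asarray(y, dtype=float)))
    n_terms = len(fit.terms) - (1 if "const" in fit.terms else 0)
    epp = n_events / n_terms
    if epp < epp_warn_threshold:
        msg = f"events per predictor {epp:.1f} < {epp_warn_threshold:g}: adjusted estimates are preliminary"
        logger.warning(msg)
        fit = ModelFit(**{**fit.__dict__, "warnings_": fit.warnings_ + (msg,)})
    return fit


# ---------------------------------------------------------------------------
# Logit linearity check
# ---------------------------------------------------------------------------


def _bspline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline basis with interior knots at quantiles (df columns,
    intercept/linear trend excluded by construction below)."""
    degree = 3
    n_interior = max(df - degree, 0)
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else np.array([])
    lo, hi = x.min(), x.max()
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    basis = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    return basis


def check_logit_linearity(y, x_continuous, df: int = 4, alpha: float = 0.05) -> tuple[str, dict]:
    """Linear-vs-spline likelihood-ratio check of the logit in a continuous predictor.

    Fits logit(P(y=1)) ~ x against a penalty-free cubic B-spline expansion
    of x (default 4 df) and applies an approximate LRT; a significant
    improvement returns the "nonlinear" verdict, advising the caller to
    dichotomize at the median.  Fewer than 10 distinct x values yields an
    automatic "dichotomize" verdict.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_continuous, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if np.unique(x).size < 10:
        return "dichotomize", {"reason": "fewer than 10 distinct values"}
    lin = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
    basis = _bspline_basis(x, df)
    # drop one spline column for identifiability against the intercept
    Xs = sm.add_constant(basis[:, 1:])
    spl = sm.GLM(y, Xs, family=sm.families.Binomial()).fit()
    lr = 2.0 * (spl.llf - lin.llf)
    df_extra = Xs.shape[1] - 2
    p = float(stats.chi2.sf(max(lr, 0.0), df_extra))
    verdict = "nonlinear" if p < alpha else "linear"
    return verdict, {"lr_stat": float(lr), "df": df_extra, "p": p}


# ---------------------------------------------------------------------------
# Two-group comparisons
# ---------------------------------------------------------------------------


def compare_groups(
    records: pd.DataFrame,
    group_label: str,
    variable: str,
    forced_test: str | None = None,
    categorical: bool | None = None,
    alpha_gate: float = 0.05,
) -> GroupComparison:
    """Two-group test with the standard distribution-gated selection.

    Categorical variables get a chi-square test of association.  Continuous
    variables are gated by Shapiro-Wilk per group (non-normal at
    ``alpha_gate`` -> Mann-Whitney U); normal pairs are gated by the F test
    of variance equality into Student's t (equal) or Welch's t (unequal).
    A group with fewer than 3 observations falls back to Mann-Whitney.
    All tests are two-tailed.
    """
    df = records[[group_label, variable]].dropna()
    groups = [g for _, g in df.groupby(group_label)[variable]]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        raise InvalidInputError("exactly two non-empty groups are required")
    a, b = (g.to_numpy() for g in groups)

    if categorical is None:
        categorical = df[variable].dtype == object or df[variable].nunique() <= 2
    if forced_test == "chi2" or (forced_test is None and categorical):
        tab = pd.crosstab(df[group_label], df[variable])
        chi2, p, _, _ = stats.chi2_contingency(tab)
        return GroupComparison(variable, "chi2", float(chi2), float(p))

    if forced_test is not None:
        return _run_continuous_test(forced_test, a, b, variable)

    if min(len(a), len(b)) < 3:
        logger.warning("%s: group too small for Shapiro-Wilk; using Mann-Whitney", variable)
        return _run_continuous_test("mann_whitney", a, b, variable)

    sw_p = min(stats.shapiro(a).pvalue, stats.shapiro(b).pvalue)
    if sw_p < alpha_gate:
        cmp = _run_continuous_test("mann_whitney", a, b, variable)
        return GroupComparison(variable, cmp.test_used, cmp.statistic, cmp.p_value, normality_p=sw_p)

    f = np.var(a, ddof=1) / np.var(b, ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    f_p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    test = "t" if f_p >= alpha_gate else "welch"
    cmp = _run_continuous_test(test, a, b, variable)
    return GroupComparison(variable, test, cmp.statistic, cmp.p_value, normality_p=sw_p, variance_ratio_p=f_p)


def _run_continuous_test(test: str, a: np.ndarray, b: np.ndarray, variable: str) -> GroupComparison:
    if test == "t":
        r = stats.ttest_ind(a, b, equal_var=True)
    elif test == "welch":
        r = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney":
        r = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise InvalidParameterError(f"unknown test {test!r}")
    return GroupComparison(variable, test, float(r.statistic), float(r.pvalue))


# ---------------------------------------------------------------------------
# Table-style reports
# ---------------------------------------------------------------------------


def group_comparison_table(
    cohort: pd.DataFrame, group_label: str, variables: Sequence[str]
) -> pd.DataFrame:
    """Demographics-table style report: one gated test per variable."""
    rows = []
    for v in variables:
        try:
            c = compare_groups(cohort, group_label, v)
        except InvalidInputError as exc:
            logger.warning("comparison for %r skipped: %s", v, exc)
            continue
        rows.append(
            {"variable": c.variable, "test": c.test_used, "statistic": c.statistic,
             "p_value": c.p_value, "normality_p": c.normality_p,
             "variance_ratio_p": c.variance_ratio_p}
        )
    return pd.DataFrame(rows)


def logistic_model_table(
    y,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha_screen: float = 0.25,
) -> pd.DataFrame:
    """Model-table style report: unadjusted and adjusted OR per predictor.

    Each predictor is fitted alone (unadjusted) and, when retained by the
    p <= ``alpha_screen`` screen, with the covariate set (adjusted).
    Complete cases are taken per model, so the effective n may differ
    across predictors.
    """
    retained, fits = univariate_screen(y, predictors, alpha_screen)
    rows = []
    for name in predictors.columns:
        if name not in fits:
            continue
        una = fits[name].term(name)
        row = {
            "predictor": name,
            "n_unadjusted": fits[name].n,
            "coef_unadjusted": una["coef"],
            "se_unadjusted": una["se"],
            "or_unadjusted": una["or"],
            "ci_low_unadjusted": una["ci"][0],
            "ci_high_unadjusted": una["ci"][1],
            "p_unadjusted": una["p"],
            "retained": name in retained,
        }
        adj_fit = fit_adjusted_model(y, predictors[name], covariates)
        adj = adj_fit.term(name)
        row.update(
            n_adjusted=adj_fit.n,
            coef_adjusted=adj["coef"],
            se_adjusted=adj["se"],
            or_adjusted=adj["or"],
            ci_low_adjusted=adj["ci"][0],
            ci_high_adjusted=adj["ci"][1],
            p_adjusted=adj["p"],
            adjusted_converged=adj_fit.converged,
        )
        rows.append(row)
    return pd.DataFrame(rows)
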