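"""Case-control diagnostic layer.

Given a cohort table (one row per subject: group label, HRV features,
clinical covariates) this module provides the statistical toolkit of a
classic biomarker study:

* univariate group comparisons with automatic test dispatch (t-test or
  Mann-Whitney for continuous variables by per-group normality; chi-square
  or Fisher's exact for proportions),
* maximum-likelihood logistic regression with Wald confidence intervals,
  backward stepwise selection, and pre-specified covariate-adjustment
  models,
* empirical ROC curves with the Mann-Whitney AUC identity as a built-in
  cross-check.

Missing feature values are never imputed: each model drops incomplete
rows listwise and reports how many it used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "GroupComparison", "ModelFit", "ROCResult",
    "compare_groups", "logistic_fit", "univariable_screen",
    "stepwise_select", "adjusted_models", "roc_auc",
    "ADJUSTMENT_MODELS", "CollinearityError", "DegenerateComparisonError",
]

POSITIVE_CLASS = "HF"

#: Covariate sets of the five pre-specified adjustment models.  Model 1 is
#: the crude (unadjusted) association of the HRV term with case status.
ADJUSTMENT_MODELS = {
    "model1": [],
    "model2": ["age", "male"],
    "model3": ["age", "male", "beta_blocker", "ccb", "acei_arb"],
    "model4": ["age", "male", "creatinine", "glucose_ac"],
    "model5": ["age", "male", "creatinine", "glucose_ac",
               "cad", "dm", "htn", "dyslipidemia"],
}


class CollinearityError(ValueError):
    """Two model terms are (numerically) identical."""


class DegenerateComparisonError(ValueError):
    """A variable has zero variance in both groups."""


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    method: str            # t | mann-whitney | chi-square | fisher
    statistic: float
    p: float
    summaries: dict        # group -> human-readable summary string
    group_stats: dict      # group -> dict of numeric summaries


def _is_categorical(values: pd.Series) -> bool:
    v = values.dropna()
    if v.dtype == bool or v.dtype == object:
        return True
    return v.nunique() <= 2


def _cont_summary(v: np.ndarray, normal: bool) -> tuple:
    if normal:
        s = f"{np.mean(v):.3g} ± {np.std(v, ddof=1):.3g}"
        d = {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
    else:
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        s = f"{med:.3g} ({q1:.3g}–{q3:.3g})"
        d = {"median": float(med), "q1": float(q1), "q3": float(q3)}
    return s, d


def compare_groups(cohort: pd.DataFrame, variable: str, group_col: str = "group",
                   method: str = "auto", alpha_normality: float = 0.05
                   ) -> GroupComparison:
    """Two-group comparison of one cohort variable.

    In ``auto`` mode, a continuous variable is tested with the independent
    t-test when Shapiro-Wilk accepts normality in both groups and with the
    Mann-Whitney U test otherwise; a categorical variable goes to the
    chi-square test, switching to Fisher's exact test when any expected
    cell count of the 2x2 table falls below 5.  Summaries mirror the
    reporting convention: mean +/- SD for normal data, median (25th-75th)
    otherwise, count (%) for proportions.
    """
    if variable not in cohort.columns:
        raise KeyError(f"variable {variable!r} not in cohort")
    sub = cohort[[group_col, variable]].dropna()
    groups = sorted(sub[group_col].unique(), key=str)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups; have {groups}")
    a = sub.loc[sub[group_col] == groups[0], variable]
    b = sub.loc[sub[group_col] == groups[1], variable]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if sub[variable].nunique() <= 1:
        raise DegenerateComparisonError(
            f"{variable} takes a single value in both groups")

    categorical = method in ("chi-square", "fisher") or (
        method == "auto" and _is_categorical(sub[variable]))

    if categorical:
        tab = pd.crosstab(sub[group_col], sub[variable]).to_numpy()
        if method == "fisher" or (method in ("auto", "chi-square")
                                  and tab.shape == (2, 2)):
            chi2, p_chi, dof, expected = stats.chi2_contingency(tab)
            # Fisher when the chi-square approximation is unsafe: a small
            # expected cell, or an empty observed cell (unbounded OR)
            use_fisher = method == "fisher" or (
                method == "auto"
                and ((expected < 5).any() or (tab == 0).any()))
            if use_fisher and tab.shape == (2, 2):
                odds, p = stats.fisher_exact(tab)
                stat, chosen = float(odds), "fisher"
            else:
                stat, p, chosen = float(chi2), p_chi, "chi-square"
        else:
            chi2, p, _, _ = stats.chi2_contingency(tab)
            stat, chosen = float(chi2), "chi-square"
        summaries, gstats = {}, {}
        for g, v in ((groups[0], a), (groups[1], b)):
            n_pos = int(np.sum(v.astype(float) == np.max(sub[variable].astype(float))))
            summaries[g] = f"{n_pos} ({100 * n_pos / len(v):.0f}%)"
            gstats[g] = {"n": len(v), "n_pos": n_pos}
        return GroupComparison(variable, chosen, stat, float(p), summaries, gstats)

    av, bv = a.to_numpy(float), b.to_numpy(float)
    if np.std(av) == 0 and np.std(bv) == 0:
        raise DegenerateComparisonError(
            f"{variable} has zero variance in both groups")
    if method == "t":
        normal = True
    elif method == "mann-whitney":
        normal = False
    else:
        def _normalish(v):
            return len(v) >= 3 and stats.shapiro(v).pvalue >= alpha_normality
        normal = _normalish(av) and _normalish(bv)
    if normal:
        stat, p = stats.ttest_ind(av, bv)
        chosen = "t"
    else:
        stat, p = stats.mannwhitneyu(av, bv, alternative="two-sided")
        chosen = "mann-whitney"
    summaries, gstats = {}, {}
    for g, v in ((groups[0], av), (groups[1], bv)):
        s, d = _cont_summary(v, normal)
        d["n"] = len(v)
        summaries[g], gstats[g] = s, d
    return GroupComparison(variable, chosen, float(stat), float(p),
                           summaries, gstats)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted logistic model: one row per term (plus intercept).

    ``table`` columns: ``coef, or_, ci_low, ci_high, p, selected``; odds
    ratios and CI bounds are on the OR scale (exp of the coefficient).
    """

    table: pd.DataFrame
    terms: list
    n_obs: int
    n_events: int
    converged: bool
    separation: bool = False
    notes: list = field(default_factory=list)

    def term_row(self, term: str) -> pd.Series:
        return self.table.loc[term]

    @property
    def selected_terms(self) -> list:
        return [t for t in self.terms if bool(self.table.loc[t, "selected"])]


def _outcome_vector(cohort: pd.DataFrame, outcome: str, positive: str) -> pd.Series:
    y = cohort[outcome]
    if y.dtype == object or y.dtype.name == "category" or y.dtype == bool:
        return (y == positive).astype(float)
    return y.astype(float)


def _check_design(X: pd.DataFrame):
    for c in X.columns:
        if np.std(X[c].to_numpy(float)) == 0:
            raise ValueError(f"term {c!r} is constant within the data")
    cols = list(X.columns)
    arr = X.to_numpy(float)
    if len(cols) > 1:
        cc = np.corrcoef(arr, rowvar=False)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if abs(cc[i, j]) > 0.9999:
                    raise CollinearityError(
                        f"terms {cols[i]!r} and {cols[j]!r} are collinear")


def logistic_fit(cohort: pd.DataFrame, outcome: str = "group",
                 terms: list = None, positive: str = POSITIVE_CLASS,
                 maxiter: int = 100) -> ModelFit:
    """Maximum-likelihood logistic regression of case status on ``terms``.

    Rows with any missing value among the terms are dropped listwise.
    Wald 95% CIs; complete separation is detected (perfect predicted
    probabilities or runaway coefficients) and returned as a flagged fit
    with no finite odds ratios rather than as spuriously huge estimates.
    """
    if not terms:
        raise ValueError("at least one model term is required")
    cols = [outcome] + list(terms)
    sub = cohort[cols].dropna()
    y = _outcome_vector(sub, outcome, positive)
    n_events = int(y.sum())
    if n_events < 1 or n_events == len(y):
        raise ValueError("outcome must have both classes present")
    X = sub[list(terms)].astype(float)
    _check_design(X)
    Xc = sm.add_constant(X, has_constant="add")

    separation = False
    notes = []
    res = None
    converged = False
    # Newton first (fast, exact Wald covariance); BFGS as a fallback when
    # the Hessian turns singular, which happens under (quasi-)separation.
    for opt in ("newton", "bfgs"):
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter, method=opt)
            converged = bool(res.mle_retvals.get("converged", True))
            break
        except Exception as exc:
            notes.append(f"{opt} failed: {type(exc).__name__}: {exc}")
            if "PerfectSeparation" in type(exc).__name__:
                separation = True
            res = None
    if res is not None:
        with np.errstate(all="ignore"):
            fitted = res.predict(Xc)
        eps = 1e-10
        if np.all((fitted < eps) | (fitted > 1 - eps)) or \
                np.any(np.abs(res.params.drop("const")) > 30):
            separation = True
            notes.append("complete or quasi-complete separation detected")
        if not converged:
            notes.append(f"did not converge in {maxiter} iterations")

    index = ["const"] + list(terms)
    if res is None or separation:
        table = pd.DataFrame(
            {"coef": np.nan, "or_": np.nan, "ci_low": np.nan,
             "ci_high": np.nan, "p": np.nan, "selected": False}, index=index)
        return ModelFit(table=table, terms=list(terms), n_obs=len(y),
                        n_events=n_events, converged=False,
                        separation=separation, notes=notes)
    with np.errstate(over="ignore"):  # huge CI bounds saturate to inf
        ci = res.conf_int()
        table = pd.DataFrame({
            "coef": res.params,
            "or_": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": res.pvalues,
            "selected": True,
        }).loc[index]
    table.loc["const", "selected"] = False
    return ModelFit(table=table, terms=list(terms), n_obs=len(y),
                    n_events=n_events, converged=converged,
                    separation=False, notes=notes)


def univariable_screen(cohort: pd.DataFrame, terms, outcome: str = "group",
                       positive: str = POSITIVE_CLASS, alpha: float = 0.05
                       ) -> tuple:
    """Fit each term alone; return (per-term ModelFit dict, significant terms).

    Terms whose single-term fit separates or fails keep a NaN p-value and
    are not passed on as candidates.
    """
    fits, significant = {}, []
    for t in terms:
        try:
            fit = logistic_fit(cohort, outcome=outcome, terms=[t],
                               positive=positive)
        except (ValueError, CollinearityError) as exc:
            fits[t] = None
            continue
        fits[t] = fit
        p = fit.table.loc[t, "p"]
        if np.isfinite(p) and p < alpha:
            significant.append(t)
    return fits, significant


def stepwise_select(cohort: pd.DataFrame, candidate_terms, outcome: str = "group",
                    positive: str = POSITIVE_CLASS, p_stay: float = 0.05
                    ) -> ModelFit:
    """Backward stepwise elimination at a stay threshold of ``p_stay``.

    All candidates enter; the term with the largest Wald p >= ``p_stay``
    is dropped and the model refitted until every remaining term is
    significant.  Deterministic: candidates are processed in sorted order
    and p-value ties break lexicographically.  An empty candidate set (or
    eliminating everything) returns an empty-model result, not an error.
    """
    remaining = sorted(candidate_terms)
    notes = []
    fit = None
    while remaining:
        fit = logistic_fit(cohort, outcome=outcome, terms=remaining,
                           positive=positive)
        if fit.separation or not fit.converged:
            # degenerate multivariable fit: drop the term with the widest
            # single-term p among remaining and retry
            uni, _ = univariable_screen(cohort, remaining, outcome=outcome,
                                        positive=positive, alpha=1.1)
            ps = {t: (uni[t].table.loc[t, "p"] if uni[t] is not None else 1.0)
                  for t in remaining}
            worst = max(remaining, key=lambda t: (np.nan_to_num(ps[t], nan=1.0), t))
            notes.append(f"dropped {worst!r}: multivariable fit degenerate")
            remaining.remove(worst)
            fit = None
            continue
        # a NaN p (infinite Wald SE, e.g. near-collinearity after listwise
        # deletion) counts as the least significant term of all
        pvals = fit.table.loc[remaining, "p"].fillna(np.inf)
        worst_p = pvals.max()
        if worst_p < p_stay:
            break
        ties = sorted(pvals.index[pvals == worst_p])
        drop = ties[-1] if len(ties) > 1 else ties[0]
        # deterministic tie-break: largest p, then last lexicographic name
        remaining.remove(drop)
        fit = None
    if not remaining:
        table = pd.DataFrame(columns=["coef", "or_", "ci_low", "ci_high",
                                      "p", "selected"])
        return ModelFit(table=table, terms=[], n_obs=0, n_events=0,
                        converged=True, notes=notes + ["empty model"])
    fit.notes.extend(notes)
    return fit


def adjusted_models(cohort: pd.DataFrame, hrv_term: str, outcome: str = "group",
                    positive: str = POSITIVE_CLASS, models: dict = None) -> dict:
    """Fit the five pre-specified adjustment models for one HRV term.

    Model 1 is unadjusted; models 2-5 add fixed clinical covariate sets
    (see :data:`ADJUSTMENT_MODELS`).  Returns ``{model_name: ModelFit}``;
    the odds ratio of interest is the ``hrv_term`` row of each fit.
    """
    models = models or ADJUSTMENT_MODELS
    if np.std(cohort[hrv_term].dropna().to_numpy(float)) == 0:
        raise ValueError(f"hrv term {hrv_term!r} is constant")
    out = {}
    for name, covs in models.items():
        missing = [c for c in covs if c not in cohort.columns]
        if missing:
            raise KeyError(f"{name}: missing covariate column(s) {missing}")
        out[name] = logistic_fit(cohort, outcome=outcome,
                                 terms=[hrv_term] + list(covs),
                                 positive=positive)
    return out


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float            # raw: P(case value > control value), ties 1/2
    auc_oriented: float   # max(auc, 1 - auc)
    orientation: str      # "higher" or "lower" values predict the positive class
    fpr: np.ndarray
    tpr: np.ndarray
    degenerate: bool = False


def _rank_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Mann-Whitney AUC: U / (n1 n2) with ties counted one half."""
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(cases)].sum()
    u1 = r1 - len(cases) * (len(cases) + 1) / 2.0
    return float(u1 / (len(cases) * len(controls)))


def roc_auc(cohort: pd.DataFrame, variable: str, outcome: str = "group",
            positive: str = POSITIVE_CLASS) -> ROCResult:
    """Empirical ROC of one variable for discriminating cases.

    The raw AUC treats higher values as predicting the positive class
    (cases); the oriented AUC flips direction when the marker is reduced
    in cases, and the orientation used is reported alongside.  The
    trapezoidal area under the empirical curve and the Mann-Whitney
    pair-counting identity agree to machine precision by construction;
    the returned value is the trapezoidal one.
    """
    sub = cohort[[outcome, variable]].dropna()
    y = (sub[outcome] == positive).to_numpy()
    v = sub[variable].to_numpy(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both groups must be nonempty")
    if np.all(v == v[0]):
        return ROCResult(auc=0.5, auc_oriented=0.5, orientation="higher",
                         fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
                         degenerate=True)
    fpr, tpr, _ = roc_curve(y, v, drop_intermediate=False)
    auc_trap = float(np.trapezoid(tpr, fpr))
    auc_rank = _rank_auc(v[y], v[~y])
    if abs(auc_trap - auc_rank) > 1e-9:  # internal consistency guard
        raise AssertionError(
            f"trapezoidal AUC {auc_trap} != rank AUC {auc_rank}")
    if auc_trap >= 0.5:
        return ROCResult(auc=auc_trap, auc_oriented=auc_trap,
                         orientation="higher", fpr=fpr, tpr=tpr)
    fpr2, tpr2, _ = roc_curve(y, -v, drop_intermediate=False)
    return ROCResult(auc=auc_trap, auc_oriented=1.0 - auc_trap,
                     orientation="lower", fpr=fpr2, tpr=tpr2)
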