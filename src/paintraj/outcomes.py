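"""Cluster-outcome associations: bivariate tests, adjusted logistic models, diagnostics.

Bivariate cluster-covariate associations use the chi-square test of
independence for categorical variables, the ANOVA F-test for continuous
ones (Kruskal-Wallis when heavily skewed, |sample skewness| > 2), and a
random-intercept linear mixed model for per-observation acute pain means.
Clinically meaningful pain (NRS >= 3) at 30 days and 1 year is modeled by
covariate-adjusted logistic regression with backward elimination
(likelihood-ratio criterion, stay threshold 0.05); the cluster factor is
forced and never eliminated, with cluster 1 the reference level. Model
diagnostics: Type III likelihood-ratio test of the overall cluster effect,
the Hosmer-Lemeshow calibration test over deciles of fitted risk, and a
patient-bootstrap ROC-AUC assessment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from paintraj.cohort import BaselineRecord, baseline_to_frame, is_clinically_meaningful

logger = logging.getLogger(__name__)

SKEWNESS_RANK_TEST_THRESHOLD = 2.0
CATEGORICAL_VARS = ("sex", "race", "smoking", "cci", "asa", "surgery_category", "anesthesia")
CONTINUOUS_VARS = ("age_years", "baseline_pain", "pain_30d", "pain_1y")
DEFAULT_CANDIDATES = ("age_years", "sex", "race", "smoking", "cci", "asa",
                      "surgery_category", "anesthesia", "baseline_pain")


@dataclass
class BivariateResult:
    variable: str
    test: str            # chi-square | anova-f | kruskal-wallis | lmm-wald
    statistic: float
    p_value: float
    warning: Optional[str] = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")


@dataclass
class LogisticFit:
    """Backward-selected logistic model with a forced cluster factor."""

    outcome: str
    retained_terms: list
    result: object                     # statsmodels results
    odds_ratios: pd.DataFrame          # term, OR, CI bounds, p
    n_used: int
    selection_trace: list
    data: pd.DataFrame
    separation_flag: bool = False

    @property
    def converged(self) -> bool:
        return bool(getattr(self.result, "converged", True)) and not self.separation_flag


def _baseline_frame(baseline, assignment) -> pd.DataFrame:
    if isinstance(baseline, pd.DataFrame):
        df = baseline.copy()
    else:
        df = baseline_to_frame(list(baseline))
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    df["cluster"] = df["patient_id"].map(labels)
    df = df[df["cluster"].notna()].copy()
    df["cluster"] = df["cluster"].astype(int)
    return df


def bivariate_table(baseline, assignment, series=None) -> list[BivariateResult]:
    """Cluster-covariate association tests, one per baseline variable.

    Categorical variables -> chi-square on the cluster contingency table
    (missing rows excluded); continuous -> ANOVA F, or Kruskal-Wallis when
    |skewness| > 2. If ``series`` is given, per-observation acute pain is
    tested with a random-intercept linear mixed model (Wald test of the
    cluster fixed effects). Requires at least two clusters.
    """
    df = _baseline_frame(baseline, assignment)
    clusters = sorted(df["cluster"].unique())
    if len(clusters) < 2:
        raise ValueError("bivariate tests need at least two clusters")

    results = []
    for var in CATEGORICAL_VARS:
        sub = df[[var, "cluster"]].dropna()
        tab = pd.crosstab(sub[var], sub["cluster"])
        stat, p, _, expected = stats.chi2_contingency(tab)
        warning = None
        if np.mean(expected < 1.0) > 0.20:
            warning = "more than 20% of expected cell counts below 1"
        results.append(BivariateResult(var, "chi-square", float(stat), float(p), warning))

    for var in CONTINUOUS_VARS:
        sub = df[[var, "cluster"]].dropna()
        groups = [g[var].to_numpy(dtype=float) for _, g in sub.groupby("cluster")]
        skew = stats.skew(sub[var].to_numpy(dtype=float))
        if abs(skew) > SKEWNESS_RANK_TEST_THRESHOLD:
            stat, p = stats.kruskal(*groups)
            results.append(BivariateResult(var, "kruskal-wallis", float(stat), float(p)))
        else:
            stat, p = stats.f_oneway(*groups)
            results.append(BivariateResult(var, "anova-f", float(stat), float(p)))

    if series is not None:
        results.append(acute_pain_lmm(series, assignment))
    return results


def acute_pain_lmm(series, assignment) -> BivariateResult:
    """Cluster effect on acute pain via a random-intercept linear mixed model."""
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    rows = [(labels[s.patient_id], s.patient_id, o.score)
            for s in series if s.patient_id in labels for o in s.observations]
    long = pd.DataFrame(rows, columns=["cluster", "patient_id", "score"])
    model = smf.mixedlm("score ~ C(cluster)", long, groups=long["patient_id"])
    res = model.fit(reml=True, method="lbfgs")
    terms = [t for t in res.params.index if t.startswith("C(cluster)")]
    constraint = ", ".join(f"{t} = 0" for t in terms)
    wald = res.wald_test(constraint, scalar=True)
    return BivariateResult("acute_pain_mean", "lmm-wald",
                           float(wald.statistic), float(wald.pvalue))


def bivariate_to_frame(results: Sequence[BivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable, "test": r.test, "statistic": r.statistic,
        "p_value": r.p_value, "warning": r.warning} for r in results])


def _fit_logit(df: pd.DataFrame, terms: Sequence[str]):
    formula = "meaningful ~ C(cluster)" + "".join(
        f" + {t}" if t in ("age_years", "baseline_pain") else f" + C({t})" for t in terms)
    model = smf.glm(formula, data=df, family=sm.families.Binomial())
    return model.fit(), formula


def fit_outcome_model(baseline, assignment, outcome: str = "pain_30d",
                      candidates: Optional[Sequence[str]] = None,
                      alpha_stay: float = 0.05) -> LogisticFit:
    """Covariate-adjusted logistic model of clinically meaningful pain.

    Backward elimination: starting from the full candidate set, the
    candidate with the largest likelihood-ratio p-value above ``alpha_stay``
    is removed, repeatedly; the cluster factor is forced. Complete cases on
    the candidate set are used throughout so all nested fits share the same
    rows. Quasi-separation is flagged and confidence intervals marked
    unreliable.
    """
    if outcome not in ("pain_30d", "pain_1y"):
        raise ValueError("outcome must be pain_30d or pain_1y")
    candidates = list(DEFAULT_CANDIDATES if candidates is None else candidates)
    df = _baseline_frame(baseline, assignment)
    df["meaningful"] = df[outcome].map(is_clinically_meaningful)
    df = df.dropna(subset=["meaningful", *candidates]).copy()
    df["meaningful"] = df["meaningful"].astype(int)
    if df["meaningful"].nunique() < 2:
        raise ValueError("outcome is constant; logistic model degenerate")

    terms = list(candidates)
    trace = []
    res, formula = _fit_logit(df, terms)
    while terms:
        drops = []
        for t in terms:
            reduced, _ = _fit_logit(df, [x for x in terms if x != t])
            lr = 2.0 * (res.llf - reduced.llf)
            dfree = res.df_model - reduced.df_model
            p = stats.chi2.sf(max(lr, 0.0), max(dfree, 1))
            drops.append((t, float(p)))
        worst, worst_p = max(drops, key=lambda tp: tp[1])
        if worst_p <= alpha_stay:
            break
        terms = [x for x in terms if x != worst]
        trace.append({"dropped": worst, "lr_p": worst_p,
                      "remaining": list(terms)})
        res, formula = _fit_logit(df, terms)

    separation = bool(np.any(np.abs(res.params) > 15))
    if separation:
        logger.warning("possible separation in %s model; CIs unreliable", outcome)

    ci = res.conf_int()
    table = pd.DataFrame({
        "term": res.params.index,
        "coef": res.params.to_numpy(),
        "odds_ratio": np.exp(res.params.to_numpy()),
        "ci_low": np.exp(ci[0].to_numpy()),
        "ci_high": np.exp(ci[1].to_numpy()),
        "p_value": res.pvalues.to_numpy(),
    })
    return LogisticFit(outcome=outcome, retained_terms=terms, result=res,
                       odds_ratios=table, n_used=int(res.nobs),
                       selection_trace=trace, data=df, separation_flag=separation)


def type3_cluster_test(fit: LogisticFit):
    """Type III likelihood-ratio test of the overall cluster effect.

    Compares the selected model against the same model with the cluster
    factor removed (all other retained terms unchanged).
    """
    full = fit.result
    terms = fit.retained_terms
    if terms:
        formula = "meaningful ~ " + " + ".join(
            t if t in ("age_years", "baseline_pain") else f"C({t})" for t in terms)
    else:
        formula = "meaningful ~ 1"
    reduced = smf.glm(formula, data=fit.data, family=sm.families.Binomial()).fit()
    lr = 2.0 * (full.llf - reduced.llf)
    dfree = int(full.df_model - reduced.df_model)
    p = float(stats.chi2.sf(max(lr, 0.0), dfree))
    return float(lr), dfree, p


def hosmer_lemeshow(fit, g: int = 10):
    """Hosmer-Lemeshow calibration chi-square over groups of fitted risk.

    Groups are deciles of fitted probability (ties assigned to the lower
    group); the statistic has g - 2 degrees of freedom. ``fit`` may be a
    LogisticFit or a (y, p_hat) pair.
    """
    if isinstance(fit, LogisticFit):
        y = fit.data["meaningful"].to_numpy(dtype=float)
        p = np.asarray(fit.result.fittedvalues, dtype=float)
    else:
        y, p = (np.asarray(a, dtype=float) for a in fit)
    if g < 3:
        raise ValueError("Hosmer-Lemeshow needs at least 3 groups (df = g - 2 > 0)")
    order = np.argsort(p, kind="mergesort")
    groups = np.empty(len(p), dtype=int)
    groups[order] = np.minimum((np.arange(len(p)) * g) // len(p), g - 1)
    stat = 0.0
    used = 0
    for gi in range(g):
        mask = groups == gi
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        used += 1
        o1, e1 = float(y[mask].sum()), float(p[mask].sum())
        o0, e0 = n_g - o1, n_g - e1
        if e1 > 0:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 0:
            stat += (o0 - e0) ** 2 / e0
    dfree = used - 2
    return float(stat), int(dfree), float(stats.chi2.sf(stat, dfree))


def roc_resample(fit: LogisticFit, B: int = 200, seed: int = 0):
    """ROC AUC of the fitted probabilities with a patient-level bootstrap.

    Returns (point AUC, bootstrap AUC array, (2.5%, 97.5%) percentile CI).
    """
    from sklearn.metrics import roc_auc_score

    y = fit.data["meaningful"].to_numpy(dtype=int)
    p = np.asarray(fit.result.fittedvalues, dtype=float)
    point = float(roc_auc_score(y, p))
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        if y[idx].min() == y[idx].max():
            continue  # resample without both classes carries no AUC
        aucs.append(roc_auc_score(y[idx], p[idx]))
    aucs = np.asarray(aucs)
    if len(aucs) < 2:
        logger.warning("bootstrap AUC distribution degenerate (B = %d)", B)
        ci = (point, point)
    else:
        ci = (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))
    return point, aucs, ci


def unadjusted_or(a: float, b: float, c: float, d: float):
    """Cross-product odds ratio of a 2x2 table with a log-scale Wald 95% CI.

    Table layout: rows = groups, columns = (event, no event) ->
    OR = (a*d)/(b*c). A zero cell triggers the Haldane 0.5 continuity
    correction (flagged in the third return value).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return float(or_), (float(lo), float(hi)), corrected
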