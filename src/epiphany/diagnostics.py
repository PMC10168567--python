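"""Rule-level predictive performance.

Confusion counts against a boolean outcome, the standard accuracy metrics
(sensitivity, specificity, PPV, NPV, positive/negative likelihood ratios)
with confidence intervals, paired AUC comparison by the DeLong method, and a
multivariable logistic regression over the index's six predictors.

Interval conventions: Wilson score intervals for proportions and the log
method (Simel) for likelihood ratios.  Metrics with a zero denominator are
emitted as undefined with an explanation instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .cohort_io import CohortTable, PatientEpisode


@dataclass(frozen=True)
class TwoByTwo:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    value: float
    lower: float
    upper: float
    note: Optional[str] = None  # set when the metric is undefined

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.value))


@dataclass(frozen=True)
class DiagnosticSummary:
    table: TwoByTwo
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    plr: MetricEstimate
    nlr: MetricEstimate
    ci_mass: float


def confusion(
    cohort: CohortTable,
    positive_rule: Callable[[PatientEpisode], bool],
    outcome: str = "complication_15d",
) -> TwoByTwo:
    """Cross-classify rule positivity against a boolean outcome field."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    tp = fp = fn = tn = 0
    for ep in cohort.episodes():
        truth = getattr(ep, outcome)
        if truth is None:
            raise ValueError(f"outcome {outcome!r} missing for episode {ep.episode_id}")
        pos = bool(positive_rule(ep))
        if pos and truth:
            tp += 1
        elif pos:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    return TwoByTwo(tp, fp, fn, tn)


def _proportion(num: int, den: int, mass: float, name: str) -> MetricEstimate:
    if den == 0:
        return MetricEstimate(np.nan, np.nan, np.nan, f"{name} undefined: zero denominator")
    lo, hi = proportion_confint(num, den, alpha=1 - mass, method="wilson")
    return MetricEstimate(num / den, float(lo), float(hi))


def _likelihood_ratio(
    kind: str, t: TwoByTwo, mass: float
) -> MetricEstimate:
    """LR point estimate with the log-method interval.

    PLR = sens/(1−spec) = (tp/(tp+fn)) / (fp/(fp+tn));
    NLR = (1−sens)/spec = (fn/(tp+fn)) / (tn/(fp+tn)).
    """
    if kind == "plr":
        a, m, b, n = t.tp, t.tp + t.fn, t.fp, t.fp + t.tn
    else:
        a, m, b, n = t.fn, t.tp + t.fn, t.tn, t.fp + t.tn
    if m == 0 or n == 0 or b == 0:
        return MetricEstimate(np.nan, np.nan, np.nan, f"{kind} undefined: zero denominator")
    p1, p2 = a / m, b / n
    value = p1 / p2
    if a == 0:
        # a one-sided interval from 0; the point estimate is exactly 0
        return MetricEstimate(0.0, 0.0, np.nan, f"{kind} is 0: no discordant events")
    z = norm.ppf(1 - (1 - mass) / 2)
    se_log = np.sqrt(1 / a - 1 / m + 1 / b - 1 / n)
    return MetricEstimate(
        value, float(value * np.exp(-z * se_log)), float(value * np.exp(z * se_log))
    )


def diagnostic_metrics(t: TwoByTwo, ci_mass: float = 0.95) -> DiagnosticSummary:
    """Accuracy metrics with Wilson (proportions) / log-method (LR) intervals."""
    if not 0 < ci_mass < 1:
        raise ValueError("ci_mass must be in (0, 1)")
    return DiagnosticSummary(
        table=t,
        sensitivity=_proportion(t.tp, t.tp + t.fn, ci_mass, "sensitivity"),
        specificity=_proportion(t.tn, t.fp + t.tn, ci_mass, "specificity"),
        ppv=_proportion(t.tp, t.tp + t.fp, ci_mass, "ppv"),
        npv=_proportion(t.tn, t.tn + t.fn, ci_mass, "npv"),
        plr=_likelihood_ratio("plr", t, ci_mass),
        nlr=_likelihood_ratio("nlr", t, ci_mass),
        ci_mass=ci_mass,
    )


# --- ROC / DeLong ------------------------------------------------------------

@dataclass(frozen=True)
class RocComparison:
    auc_1: float
    auc_2: float
    var_1: float
    var_2: float
    covariance: float
    z: float
    p_value: float


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, float)
    out[order] = ranks
    return out


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Empirical AUC with the ½-weight convention for tied scores."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    m, n = labels.sum(), (~labels).sum()
    if m == 0 or n == 0:
        raise ValueError("need at least one positive and one negative label")
    r = _midrank(scores)
    return float((r[labels].sum() - m * (m + 1) / 2) / (m * n))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Per-subject structural components V10 (positives) and V01 (negatives)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def auc_delong(
    scores_model1: Sequence[float],
    scores_model2: Sequence[float],
    labels: Sequence[bool],
) -> RocComparison:
    """Two-sided DeLong test for two paired ROC curves.

    Empirical AUCs via the Mann-Whitney statistic; the covariance of the two
    AUCs comes from the per-subject structural components, and the comparison
    is a normal z test on the AUC difference.
    """
    s1 = np.asarray(scores_model1, float)
    s2 = np.asarray(scores_model2, float)
    labels = np.asarray(labels).astype(bool)
    if not (len(s1) == len(s2) == len(labels)):
        raise ValueError("scores and labels must be paired (equal length)")
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise ValueError("need at least one positive and one negative label")

    auc1, v10_1, v01_1 = _delong_components(s1, labels)
    auc2, v10_2, v01_2 = _delong_components(s2, labels)
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        z, p = 0.0, 1.0
    else:
        z = (auc1 - auc2) / np.sqrt(var_diff)
        p = 2 * norm.sf(abs(z))
    return RocComparison(
        auc_1=float(auc1),
        auc_2=float(auc2),
        var_1=float(cov[0, 0]),
        var_2=float(cov[1, 1]),
        covariance=float(cov[0, 1]),
        z=float(z),
        p_value=float(p),
    )


# --- logistic regression -----------------------------------------------------

@dataclass
class LogisticFit:
    table: pd.DataFrame  # variable, or, ci_low, ci_high, coef, se, p
    converged: bool
    separation: list  # variables flagged for (quasi-)complete separation
    deviance: float


def logistic_fit(
    design: pd.DataFrame, outcome: Sequence[bool], ci_mass: float = 0.95
) -> LogisticFit:
    """Multivariable logistic regression with Wald odds-ratio intervals.

    Fit by Newton scoring (iteratively reweighted least squares) with
    convergence tolerance 1e-8 and at most 50 iterations.  Complete or
    quasi-complete separation is detected from runaway coefficients/standard
    errors and reported explicitly instead of blowing up silently.
    """
    y = np.asarray(outcome).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    X = design.astype(float)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant column(s) in design: {constant}")
    Xc = sm.add_constant(X, prepend=True)
    model = sm.Logit(y, Xc)
    try:
        res = model.fit(method="newton", maxiter=50, tol=1e-8, disp=False)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:
        res = model.fit(method="bfgs", maxiter=200, disp=False)
        converged = False

    z = norm.ppf(1 - (1 - ci_mass) / 2)
    coefs = res.params
    ses = res.bse
    separation = [
        v
        for v in X.columns
        if abs(coefs[v]) > 15 or not np.isfinite(ses[v]) or ses[v] > 100
    ]
    rows = []
    for v in X.columns:
        b, se = coefs[v], ses[v]
        rows.append(
            {
                "variable": v,
                "or": np.exp(b),
                "ci_low": np.exp(b - z * se),
                "ci_high": np.exp(b + z * se),
                "coef": b,
                "se": se,
                "p": res.pvalues[v],
                "separation": v in separation,
            }
        )
    return LogisticFit(
        table=pd.DataFrame(rows),
        converged=converged,
        separation=separation,
        deviance=float(-2 * res.llf),
    )


EPIPHANY_LOGISTIC_VARIABLES = [
    "hestia_any",
    "symptomatic",
    "recist_progressing",
    "primary_resected",
    "spo2",
    "ecog_ps",
]


def epiphany_design(cohort: CohortTable) -> pd.DataFrame:
    """Design matrix of the index's six predictors for the logistic model."""
    from .risk_models import assess_hestia

    rows = []
    for ep in cohort.episodes():
        rows.append(
            {
                "hestia_any": float(assess_hestia(ep).any_met),
                "symptomatic": float(ep.symptomatic),
                "recist_progressing": float(ep.recist_group == "progressing"),
                "primary_resected": float(ep.primary_resected),
                "spo2": float(ep.spo2),
                "ecog_ps": float(ep.ecog_ps),
            }
        )
    return pd.DataFrame(rows, columns=EPIPHANY_LOGISTIC_VARIABLES)
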