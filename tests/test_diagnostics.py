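import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from epiphany._util import pct
from epiphany.cohort_io import cohort_from_episodes
from epiphany.diagnostics import (
    TwoByTwo,
    auc_delong,
    auc_mann_whitney,
    confusion,
    diagnostic_metrics,
    logistic_fit,
)

# the dichotomized index (high vs other) cross-classified against 15-day
# complications, recombined from the published per-stratum counts
INDEX_TABLE = TwoByTwo(tp=90, fp=349, fn=17, tn=444)
# the adapted Hestia rule against the same outcome
HESTIA_TABLE = TwoByTwo(tp=99, fp=451, fn=8, tn=342)


def test_confusion_counts(default_cohort):
    from epiphany.risk_models import classify_epiphany

    t = confusion(default_cohort, lambda ep: classify_epiphany(ep) == "high")
    cats = default_cohort.frame["_stratum"]
    assert t.tp + t.fp == (cats == "high").sum()
    assert t.fn + t.tn == cats.isin(["low", "intermediate"]).sum()
    assert t.total == len(default_cohort)


def test_confusion_rule_always_false(episode_factory):
    cohort = cohort_from_episodes(
        [episode_factory(episode_id=f"e{i}", complication_15d=i == 0) for i in range(4)]
    )
    t = confusion(cohort, lambda ep: False)
    assert (t.tp, t.fp) == (0, 0)
    assert (t.fn, t.tn) == (1, 3)


def test_metrics_on_published_count_recombination():
    m = diagnostic_metrics(INDEX_TABLE)
    assert pct(m.sensitivity.value) == 84.1
    assert pct(m.npv.value) == 96.3
    h = diagnostic_metrics(HESTIA_TABLE)
    assert pct(h.npv.value) == 97.7
    assert h.nlr.value == pytest.approx(0.17, abs=0.005)


def test_metrics_perfect_rule():
    m = diagnostic_metrics(TwoByTwo(tp=10, fp=0, fn=0, tn=20))
    assert m.sensitivity.value == m.specificity.value == 1.0
    assert m.ppv.value == m.npv.value == 1.0
    assert m.nlr.value == 0.0


def test_metric_identities_and_interval_ranges():
    for t in (INDEX_TABLE, HESTIA_TABLE, TwoByTwo(3, 5, 2, 30)):
        m = diagnostic_metrics(t)
        sens, spec = m.sensitivity.value, m.specificity.value
        assert m.plr.value == pytest.approx(sens / (1 - spec), abs=1e-12)
        assert m.nlr.value == pytest.approx((1 - sens) / spec, abs=1e-12)
        for est in (m.sensitivity, m.specificity, m.ppv, m.npv):
            assert 0.0 <= est.lower <= est.value <= est.upper <= 1.0
        for est in (m.plr, m.nlr):
            assert est.lower <= est.value <= est.upper


def test_zero_denominator_flagged_not_raised():
    m = diagnostic_metrics(TwoByTwo(tp=0, fp=0, fn=2, tn=8))
    assert not m.ppv.defined
    assert "denominator" in m.ppv.note


# --- AUC / DeLong -----------------------------------------------------------

def test_delong_identical_scores():
    rng = np.random.default_rng(0)
    s = rng.normal(size=100)
    labels = rng.random(100) < 0.4
    r = auc_delong(s, s, labels)
    assert r.auc_1 == r.auc_2
    assert r.z == 0.0 and r.p_value == 1.0


def test_auc_perfect_scores():
    labels = np.array([0, 0, 1, 1, 0, 1], bool)
    assert auc_mann_whitney(labels.astype(float), labels) == 1.0


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(1)
    s = rng.normal(size=300)
    labels = rng.random(300) < 0.3
    a1 = auc_mann_whitney(s, labels)
    a2 = auc_mann_whitney(np.exp(2 * s) + 7, labels)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_delong_agrees_with_paired_bootstrap():
    """Independent oracle: paired bootstrap of the AUC difference."""
    rng = np.random.default_rng(42)
    n = 200
    labels = rng.random(n) < 0.35
    signal = labels.astype(float)
    s1 = signal + rng.normal(0, 1.1, n)
    s2 = signal + rng.normal(0, 1.6, n)
    r = auc_delong(s1, s2, labels)

    boots = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        if 0 < labels[idx].sum() < n:
            boots.append(
                auc_mann_whitney(s1[idx], labels[idx])
                - auc_mann_whitney(s2[idx], labels[idx])
            )
    se = np.std(boots, ddof=1)
    z = (r.auc_1 - r.auc_2) / se
    p_boot = 2 * norm.sf(abs(z))
    assert abs(r.p_value - p_boot) < 0.02


def test_delong_degenerate_labels_rejected():
    with pytest.raises(ValueError):
        auc_delong([1, 2, 3], [1, 2, 3], [True, True, True])


# --- logistic regression -----------------------------------------------------

def test_logistic_single_binary_covariate_matches_cross_product():
    """With one binary covariate the MLE odds ratio is the 2x2 cross-product
    ratio ad/bc (closed-form oracle)."""
    x = np.array([1] * 40 + [0] * 60)
    y = np.array([1] * 12 + [0] * 28 + [1] * 9 + [0] * 51)
    fit = logistic_fit(pd.DataFrame({"x": x}), y)
    a, b = 12, 28
    c, d = 9, 51
    assert fit.table.loc[0, "or"] == pytest.approx((a * d) / (b * c), abs=1e-6)
    assert fit.converged


def test_logistic_null_coverage():
    """When the outcome is independent of all covariates, nominal 95% Wald
    intervals cover OR = 1 at about the nominal rate."""
    rng = np.random.default_rng(7)
    n, reps = 5_000, 200
    covered = 0
    total = 0
    for _ in range(reps):
        X = pd.DataFrame(
            {
                "b1": rng.random(n) < 0.4,
                "b2": rng.random(n) < 0.2,
                "c1": rng.normal(size=n),
            }
        ).astype(float)
        y = rng.random(n) < 0.2
        fit = logistic_fit(X, y)
        for _, row in fit.table.iterrows():
            total += 1
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
    rate = covered / total
    assert 0.91 <= rate <= 0.99


def test_logistic_constant_column_rejected():
    X = pd.DataFrame({"x": [1.0] * 20, "y2": np.arange(20.0)})
    y = np.array([0, 1] * 10)
    with pytest.raises(ValueError, match="constant"):
        logistic_fit(X, y)


def test_logistic_separation_flagged():
    x = np.array([0] * 20 + [1] * 20, float)
    y = x.astype(int)  # complete separation
    fit = logistic_fit(pd.DataFrame({"x": x}), y)
    assert fit.separation == ["x"]
    assert fit.table.loc[0, "separation"]
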