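import numpy as np
import pytest

from epiphany.risk_models import (
    RISK_ORDER,
    DecisionTreeSpec,
    ModelSpecError,
    UnevaluableError,
    assess_hestia,
    audit_hestia_monotonicity,
    available_score_specs,
    classify_epiphany,
    default_tree,
    enumerate_lattice,
    predicted_vs_observed,
    score_points,
    tree_features,
)
from epiphany.cohort_io import cohort_from_episodes


# --- adapted Hestia ---------------------------------------------------------

@pytest.mark.parametrize(
    "overrides, expected",
    [
        ({"sbp": 95.0}, {"sbp_lt_100"}),
        ({"sbp": 100.0}, set()),  # strict inequality at the printed boundary
        ({"spo2": 90.0}, set()),
        ({"spo2": 89.9}, {"spo2_lt_90"}),
        ({"rr": 30.0}, {"rr_ge_30"}),  # weak inequality as printed
        ({"hr": 110.0}, {"hr_ge_110"}),
        ({"platelets": 49_999.0}, {"platelets_lt_50000"}),
        ({"platelets": 50_000.0}, set()),
        ({"pe_symptoms": frozenset({"sudden_or_progressive_dyspnea"}),
          "presentation": "suspected"}, {"dyspnea"}),
        ({"clinically_relevant_bleeding": True}, {"clinically_relevant_bleeding"}),
        ({"sbp": 92.0, "hr": 115.0}, {"sbp_lt_100", "hr_ge_110"}),
        ({}, set()),
    ],
)
def test_hestia_criteria_thresholds(episode_factory, overrides, expected):
    a = assess_hestia(episode_factory(**overrides))
    assert a.criteria_met == frozenset(expected)
    assert a.any_met == bool(expected)


def test_hestia_ignores_unread_fields(episode_factory):
    a = assess_hestia(episode_factory())
    b = assess_hestia(episode_factory(age=40, tumor_type="breast", recist="pd",
                                      ecog_ps=4, outpatient=False))
    assert a == b


def test_hestia_missing_vital_errors_by_name(episode_factory):
    import dataclasses

    ep = dataclasses.replace(episode_factory(), rr=None)
    with pytest.raises(UnevaluableError, match="rr_ge_30"):
        assess_hestia(ep, strict=True)
    assert "rr_ge_30" not in assess_hestia(ep, strict=False).criteria_met


# --- decision tree ----------------------------------------------------------

def test_tree_exhaustive_and_deterministic():
    """Every point of the discretized feature lattice reaches exactly one leaf."""
    tree = default_tree()
    for combo in enumerate_lattice():
        cat1 = tree.classify_features(combo)
        cat2 = tree.classify_features(dict(combo))
        assert cat1 == cat2
        assert cat1 in RISK_ORDER


def test_hestia_positive_never_low():
    tree = default_tree()
    for combo in enumerate_lattice():
        if combo["hestia_any"]:
            assert tree.classify_features(combo) != "low"


def test_hestia_flip_monotone():
    """Turning the Hestia flag on never lowers the risk category."""
    assert audit_hestia_monotonicity(default_tree()) == []


def test_identical_split_variables_identical_category(episode_factory):
    a = episode_factory(age=45, tumor_type="breast")
    b = episode_factory(age=80, tumor_type="lung", outpatient=False)
    assert classify_epiphany(a) == classify_epiphany(b)


def test_invalid_tree_rejected_before_classification():
    tree = default_tree()
    broken = DecisionTreeSpec(
        name="broken",
        root=tree.root,
        nodes={**tree.nodes, "dangling": {"test": {"feature": "spo2", "op": "ge", "value": 90},
                                          "if_true": "nowhere", "if_false": "nowhere"}},
        leaves=tree.leaves,
    )
    with pytest.raises(ModelSpecError):
        broken.validate()


def test_tree_features_derivation(episode_factory):
    ep = episode_factory(recist="pd", spo2=91.0, ecog_ps=3, presentation="suspected",
                         pe_symptoms=frozenset({"chest_pain"}))
    f = tree_features(ep)
    assert f["recist_group"] == "progressing"
    assert f["presentation"] == "suspected"
    assert not f["hestia_any"]


# --- point scores -----------------------------------------------------------

def test_spesi_never_low_in_cancer_cohort(default_cohort):
    """The active-cancer item awards a point to everyone, so nobody scores 0."""
    spesi = available_score_specs()["spesi"]
    for ep in list(default_cohort.episodes())[:200]:
        score, cls = score_points(ep, spesi)
        assert score >= 1
        assert cls == "high"


def test_empty_item_list_scores_zero(episode_factory):
    from epiphany.risk_models import PointScoreSpec

    spec = PointScoreSpec(name="null", enabled=True, items=[],
                          classes=[{"name": "only", "min": 0, "max": 0,
                                    "predicted_30d_mortality": 0.1}])
    assert score_points(episode_factory(), spec) == (0.0, "only")


def test_pesi_points_match_manual_addition(episode_factory):
    """Summed points reproduce the shipped class boundaries on hand-built episodes."""
    pesi = available_score_specs()["pesi"]
    ep = episode_factory(
        age=70, sex="male", hr=115.0, sbp=95.0, rr=32.0, spo2=88.0,
    )
    ep.extras.update(
        heart_failure=False, chronic_lung_disease=True, temperature=36.5,
        altered_mental_status=False,
    )
    # 70 (age) + 10 (male) + 30 (cancer) + 10 (lung disease) + 20 (HR)
    # + 30 (SBP) + 20 (RR) + 20 (SpO2) = 210
    score, cls = score_points(ep, pesi)
    assert score == 210
    assert cls == "class_v"
    mild = episode_factory(age=30, sex="female")
    mild.extras.update(heart_failure=False, chronic_lung_disease=False,
                       temperature=37.0, altered_mental_status=False)
    assert score_points(mild, pesi) == (60.0, "class_i")


def test_pesi_unevaluable_without_comorbidity_columns(episode_factory):
    pesi = available_score_specs()["pesi"]
    with pytest.raises(UnevaluableError, match="heart_failure"):
        score_points(episode_factory(), pesi)


def test_disabled_stub_raises(episode_factory):
    riete = available_score_specs()["riete"]
    with pytest.raises(UnevaluableError, match="stub"):
        score_points(episode_factory(), riete)


# --- predicted vs observed --------------------------------------------------

def _two_class_spec(p_low, p_high):
    from epiphany.risk_models import PointScoreSpec

    return PointScoreSpec(
        name="toy", enabled=True,
        items=[{"name": "old", "feature": "age", "op": "gt", "value": 70, "points": 1}],
        classes=[{"name": "young", "min": 0, "max": 0, "predicted_30d_mortality": p_low},
                 {"name": "old", "min": 1, "max": 1, "predicted_30d_mortality": p_high}],
    )


def test_predicted_vs_observed_exact_small_case(episode_factory):
    eps = []
    # 10 young (1 death), 10 old (2 deaths); predicted 0.1 / 0.2
    for i in range(10):
        eps.append(episode_factory(episode_id=f"y{i}", age=60, death_30d=i < 1,
                                   os_time=0.5 if i < 1 else 12.0, os_event=i < 1))
    for i in range(10):
        eps.append(episode_factory(episode_id=f"o{i}", age=80, death_30d=i < 2,
                                   os_time=0.5 if i < 2 else 12.0, os_event=i < 2))
    table = predicted_vs_observed(cohort_from_episodes(eps), _two_class_spec(0.1, 0.2))
    young = table[table["class"] == "young"].iloc[0]
    old = table[table["class"] == "old"].iloc[0]
    assert young["expected_deaths"] == pytest.approx(1.0)
    assert old["expected_deaths"] == pytest.approx(2.0)
    assert young["ratio"] == pytest.approx(1.0)
    assert old["ratio"] == pytest.approx(1.0)
    pooled = table[table["class"] == "all"].iloc[0]
    assert pooled["observed_deaths"] == 3


def test_predicted_vs_observed_zero_prediction_flagged(episode_factory):
    eps = [episode_factory(episode_id=f"e{i}", age=60, death_30d=False)
           for i in range(5)]
    table = predicted_vs_observed(cohort_from_episodes(eps), _two_class_spec(0.0, 0.0))
    row = table[table["class"] == "young"].iloc[0]
    assert row["observed_deaths"] == 0
    assert not row["ratio_defined"]
    empty = table[table["class"] == "old"].iloc[0]
    assert empty["n"] == 0 and not empty["ratio_defined"]


def test_predicted_vs_observed_pooled_ratio_converges():
    """Law of large numbers: with the true mortality as the prediction, the
    pooled observed/expected ratio approaches 1."""
    from epiphany.risk_models import PointScoreSpec
    from epiphany.synthetic_cohort import CohortConfig, generate_cohort

    cohort = generate_cohort(CohortConfig(n_total=50_000), seed=11)
    true_pooled = 65 / 900  # configured mixture mortality
    spec = PointScoreSpec(
        name="truth", enabled=True, items=[],
        classes=[{"name": "everyone", "min": 0, "max": 0,
                  "predicted_30d_mortality": true_pooled}],
    )
    table = predicted_vs_observed(cohort, spec)
    pooled = table[table["class"] == "all"].iloc[0]
    assert pooled["ratio"] == pytest.approx(1.0, abs=0.05)
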