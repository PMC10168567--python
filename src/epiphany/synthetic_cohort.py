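"""Synthetic cohort generator.

Emulates the statistical structure the validation analyses assume, so every
pipeline stage is testable without patient-level data: three risk strata with
configurable sizes and 15-day complication probabilities, per-stratum 30-day
mortality and overall-survival medians, and 6-month bleeding/rethrombosis
cumulative incidences with death as a competing event.  Free covariates (age,
sex, tumor type, vitals within their allowed ranges) are drawn independently
from the published baseline marginals; no correlation structure between them
is claimed.

Generation is stratum-first: each subject is assigned a risk stratum, then a
leaf of the decision tree belonging to that stratum, and feature values are
sampled to satisfy the leaf's predicate path.  Classifying a generated
episode therefore returns its sampled stratum by construction (round-trip
guarantee, asserted at generation time).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._util import DEFAULT_SEED
from .cohort_io import DAYS_30_IN_MONTHS, CohortTable, COLUMNS
from .risk_models import DecisionTreeSpec, default_tree

STRATA = ("low", "intermediate", "high")

#: baseline marginals for free covariates (published cohort description)
TUMOR_MARGINALS = {
    "lung": 0.263, "colorectal": 0.187, "breast": 0.081, "pancreatic": 0.071,
    "bladder": 0.052, "stomach": 0.050, "ovarian": 0.044, "cns": 0.034,
    "endometrial": 0.028, "other": 0.190,
}
RECIST_MARGINALS = {
    "ne": 0.400, "uk": 0.064, "pd": 0.227, "sd": 0.160, "pr": 0.104,
    "cr": 0.022, "ned": 0.023,
}
PRESENTATION_MARGINALS = {
    "suspected": 0.354, "unsuspected_symptomatic": 0.160,
    "unsuspected_asymptomatic": 0.486,
}
RECIST_GROUPS = {"progressing": ("pd", "ne", "uk"), "controlled": ("cr", "pr", "sd", "ned")}
ECOG_MARGINALS = np.array([0.151, 0.496, 0.254, 0.091, 0.008])

#: conditional prevalence of each adapted Hestia criterion given >=1 met
CRITERION_PREVALENCE = {
    "dyspnea": 0.45, "sbp_lt_100": 0.15, "spo2_lt_90": 0.25, "rr_ge_30": 0.15,
    "hr_ge_110": 0.25, "other_admission_criterion": 0.15,
    "clinically_relevant_bleeding": 0.10, "high_bleeding_risk": 0.20,
    "platelets_lt_50000": 0.07,
}


@dataclass
class CohortConfig:
    """Study-level generating parameters.

    Defaults reproduce the validation cohort's structure: stratum sizes
    232/229/439 of 900, per-stratum 15-day complication probabilities and
    30-day mortality from the published counts, overall-survival medians
    16.5/14.4/4.4 months, and 6-month bleeding/rethrombosis cumulative
    incidences 6.2%/12.7% and 2.9%/7.0% (low-or-moderate vs high) with death
    as the competing event.  Times are months; administrative censoring
    applies to every time-to-event field.
    """

    n_total: int = 900
    stratum_probs: Tuple[float, float, float] = (232 / 900, 229 / 900, 439 / 900)
    complication_probs: Tuple[float, float, float] = (5 / 232, 12 / 229, 90 / 439)
    mortality_30d: Tuple[float, float, float] = (1 / 232, 7 / 229, 57 / 439)
    os_median_months: Tuple[float, float, float] = (16.5, 14.4, 4.4)
    bleed_cif_6mo: Dict[str, float] = field(
        default_factory=lambda: {"low_moderate": 0.062, "high": 0.127}
    )
    rethrombosis_cif_6mo: Dict[str, float] = field(
        default_factory=lambda: {"low_moderate": 0.029, "high": 0.070}
    )
    outpatient_fraction: Dict[str, float] = field(
        default_factory=lambda: {"low": 273 / 461, "intermediate": 273 / 461,
                                 "high": 78 / 439}
    )
    prior_anticoagulation_frac: float = 110 / 900
    complication_day_median: int = 4
    complication_day_max: int = 15
    censor_months: float = 36.0
    cif_horizon_months: float = 6.0
    leaf_weights: Optional[Dict[str, float]] = None  # leaf_id -> weight
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if abs(sum(self.stratum_probs) - 1.0) > 1e-9:
            raise ValueError("stratum probabilities must sum to 1")
        probs = (
            list(self.stratum_probs) + list(self.complication_probs)
            + list(self.mortality_30d) + list(self.bleed_cif_6mo.values())
            + list(self.rethrombosis_cif_6mo.values())
            + list(self.outpatient_fraction.values())
            + [self.prior_anticoagulation_frac]
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")


class ConfigTreeMismatch(ValueError):
    """A configured stratum has no reachable leaf under the supplied tree."""


def calibrate_competing_hazards(
    target_cif_6mo: float, death_rate: float, horizon: float = 6.0
) -> float:
    """Cause-specific event hazard matching a cumulative-incidence target.

    Under constant hazards (event λ_e, competing death λ_d) the cumulative
    incidence of the event is
    CIF_e(t) = λ_e/(λ_e + λ_d) · (1 − exp(−(λ_e + λ_d) t)).
    Solves CIF_e(horizon) = target for λ_e by monotone root finding
    (tolerance 1e-10).  Raises for targets at or above the attainable
    asymptote.
    """
    if death_rate < 0 or not 0 <= target_cif_6mo:
        raise ValueError("rates and targets must be nonnegative")
    if target_cif_6mo == 0.0:
        return 0.0
    if target_cif_6mo >= 1.0:
        raise ValueError(
            f"target {target_cif_6mo} unattainable: the cumulative incidence "
            f"approaches 1 only as the event hazard diverges"
        )
    if death_rate == 0.0:
        return -np.log(1.0 - target_cif_6mo) / horizon

    def cif(lam_e):
        tot = lam_e + death_rate
        return lam_e / tot * (1.0 - np.exp(-tot * horizon))

    hi = 1.0
    while cif(hi) < target_cif_6mo:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(f"target {target_cif_6mo} unattainable at horizon {horizon}")
    return float(brentq(lambda l: cif(l) - target_cif_6mo, 0.0, hi, xtol=1e-10))


def _truncated_geometric_q(median: int, kmax: int) -> float:
    """Success parameter of the day-of-complication distribution.

    pmf ∝ q^k on 0..kmax with q = 1 − p, calibrated so the smallest m with
    CDF(m) >= 0.5 is ``median``.
    """

    def cdf_at_median(q):
        return (1 - q ** (median + 1)) / (1 - q ** (kmax + 1)) - 0.5

    return float(brentq(cdf_at_median, 1e-9, 1 - 1e-9, xtol=1e-12))


def _trunc_normal(rng, m, sd, lo, hi, size):
    """Rejection-free truncated normal via inverse CDF."""
    from scipy.stats import norm

    a, b = norm.cdf((lo - m) / sd), norm.cdf((hi - m) / sd)
    u = rng.uniform(a, b, size)
    return m + sd * norm.ppf(u)


def _choice(rng, options, weights, size):
    w = np.asarray(weights, float)
    return rng.choice(np.asarray(options, object), size=size, p=w / w.sum())


def _path_constraints(path):
    """Fold a leaf's predicate path into per-feature constraints."""
    cons = {
        "hestia_any": None,
        "presentation": set(PRESENTATION_MARGINALS),
        "recist_group": set(RECIST_GROUPS),
        "primary_resected": None,
        "spo2": [0.0, 100.0],
        "ecog_ps": [0, 4],
    }
    for feature, op, value, taken in path:
        if feature in ("hestia_any", "primary_resected"):
            want = value if op == "eq" else not value
            cons[feature] = want if taken else (not want)
        elif feature in ("presentation",):
            allowed = {value} if taken else set(PRESENTATION_MARGINALS) - {value}
            cons["presentation"] &= allowed
        elif feature == "recist_group":
            allowed = {value} if taken else set(RECIST_GROUPS) - {value}
            cons["recist_group"] &= allowed
        elif feature in ("spo2", "ecog_ps"):
            lo, hi = cons[feature]
            eps = 0.1 if feature == "spo2" else 1
            if op == "ge":
                lo, hi = (max(lo, value), hi) if taken else (lo, min(hi, value - eps))
            elif op == "le":
                lo, hi = (lo, min(hi, value)) if taken else (max(lo, value + eps), hi)
            elif op == "lt":
                lo, hi = (lo, min(hi, value - eps)) if taken else (max(lo, value), hi)
            elif op == "gt":
                lo, hi = (max(lo, value + eps), hi) if taken else (lo, min(hi, value))
            if lo > hi:
                raise ConfigTreeMismatch(f"unsatisfiable {feature} range on path")
            cons[feature] = [lo, hi]
    if not cons["presentation"] or not cons["recist_group"]:
        raise ConfigTreeMismatch("unsatisfiable categorical constraint on path")
    return cons


def _sample_block(rng, m: int, cons: dict, config: CohortConfig, stratum: str) -> dict:
    """Feature columns for ``m`` episodes constrained to one leaf path."""
    cols: dict = {}

    pres_opts = sorted(cons["presentation"])
    cols["presentation"] = _choice(
        rng, pres_opts, [PRESENTATION_MARGINALS[p] for p in pres_opts], m
    )
    symptomatic = cols["presentation"] != "unsuspected_asymptomatic"

    recist_opts = [v for g in sorted(cons["recist_group"]) for v in RECIST_GROUPS[g]]
    cols["recist"] = _choice(
        rng, recist_opts, [RECIST_MARGINALS[v] for v in recist_opts], m
    )

    if cons["primary_resected"] is None:
        cols["primary_resected"] = rng.random(m) < 0.335
    else:
        cols["primary_resected"] = np.full(m, cons["primary_resected"])

    elo, ehi = cons["ecog_ps"]
    ecog_opts = np.arange(elo, ehi + 1)
    cols["ecog_ps"] = _choice(rng, list(ecog_opts), ECOG_MARGINALS[elo : ehi + 1], m).astype(int)

    # --- adapted Hestia criteria and vitals ---------------------------------
    hestia_on = bool(cons["hestia_any"])
    slo, shi = cons["spo2"]
    spo2_criterion_possible = hestia_on and slo < 90
    crit: Dict[str, np.ndarray] = {}
    if hestia_on:
        for name, prev in CRITERION_PREVALENCE.items():
            allowed = np.full(m, True)
            if name == "dyspnea":
                allowed = symptomatic
            if name == "spo2_lt_90" and not spo2_criterion_possible:
                allowed = np.full(m, False)
            crit[name] = (rng.random(m) < prev) & allowed
        met = np.stack(list(crit.values()))
        none_met = ~met.any(axis=0)
        if none_met.any():
            # force one allowed criterion uniformly at random
            names = list(CRITERION_PREVALENCE)
            for i in np.flatnonzero(none_met):
                allowed = [
                    nm for nm in names
                    if not (nm == "dyspnea" and not symptomatic[i])
                    and not (nm == "spo2_lt_90" and not spo2_criterion_possible)
                ]
                crit[rng.choice(allowed)][i] = True
    else:
        for name in CRITERION_PREVALENCE:
            crit[name] = np.zeros(m, bool)

    cols["sbp"] = np.where(
        crit["sbp_lt_100"],
        np.round(_trunc_normal(rng, 88, 8, 60, 99, m)),
        np.round(_trunc_normal(rng, 128, 14, 100, 190, m)),
    )
    spo2_lo_ok = max(slo, 90.0)
    spo2_normal = _trunc_normal(rng, 96, 1.8, spo2_lo_ok, shi, m)
    if spo2_criterion_possible:
        spo2_low = _trunc_normal(rng, 86, 3, max(slo, 70.0), min(shi, 89.9), m)
        cols["spo2"] = np.round(np.where(crit["spo2_lt_90"], spo2_low, spo2_normal), 1)
    else:
        cols["spo2"] = np.round(spo2_normal, 1)
    cols["rr"] = np.where(
        crit["rr_ge_30"],
        np.round(_trunc_normal(rng, 33, 3, 30, 50, m)),
        np.round(_trunc_normal(rng, 17, 3.5, 8, 29, m)),
    )
    cols["hr"] = np.where(
        crit["hr_ge_110"],
        np.round(_trunc_normal(rng, 118, 8, 110, 170, m)),
        np.round(_trunc_normal(rng, 84, 13, 45, 109, m)),
    )
    cols["platelets"] = np.where(
        crit["platelets_lt_50000"],
        np.round(rng.uniform(10_000, 49_999, m)),
        np.round(np.clip(np.exp(rng.normal(np.log(230_000), 0.35, m)), 50_000, 900_000)),
    )
    cols["clinically_relevant_bleeding"] = crit["clinically_relevant_bleeding"]
    cols["high_bleeding_risk"] = crit["high_bleeding_risk"]
    cols["other_admission_criterion"] = crit["other_admission_criterion"]

    # symptoms: dyspnea only via its criterion; symptomatic episodes report
    # at least one of the three
    chest = symptomatic & (rng.random(m) < 0.70)
    sync = symptomatic & (rng.random(m) < 0.15)
    dysp = crit["dyspnea"]
    none_sym = symptomatic & ~(chest | sync | dysp)
    chest = chest | none_sym
    symlist = []
    for i in range(m):
        toks = []
        if dysp[i]:
            toks.append("sudden_or_progressive_dyspnea")
        if chest[i]:
            toks.append("chest_pain")
        if sync[i]:
            toks.append("syncope")
        symlist.append(";".join(sorted(toks)))
    cols["pe_symptoms"] = np.array(symlist, object)

    # --- free demographics --------------------------------------------------
    cols["age"] = np.round(_trunc_normal(rng, 66, 11.5, 21, 94, m)).astype(int)
    cols["sex"] = _choice(rng, ["male", "female"], [0.574, 0.426], m)
    cols["tumor_type"] = _choice(
        rng, list(TUMOR_MARGINALS), list(TUMOR_MARGINALS.values()), m
    )
    cols["stage_iv"] = rng.random(m) < 0.783
    cols["prior_anticoagulation"] = rng.random(m) < config.prior_anticoagulation_frac
    cols["outpatient"] = rng.random(m) < config.outpatient_fraction[stratum]
    return cols


def _sample_outcomes(rng, m: int, stratum_idx: int, config: CohortConfig) -> dict:
    cols: dict = {}
    s = stratum_idx
    theta = config.complication_probs[s]
    p30 = config.mortality_30d[s]
    med = config.os_median_months[s]
    cens = config.censor_months

    comp = rng.random(m) < theta
    q = _truncated_geometric_q(config.complication_day_median, config.complication_day_max)
    pmf = q ** np.arange(config.complication_day_max + 1)
    days = _choice(rng, list(range(config.complication_day_max + 1)), pmf, m).astype(float)
    cols["complication_15d"] = comp
    cols["complication_day"] = np.where(comp, days, np.nan)

    # two-piece OS: death within 30 days with probability p30, otherwise an
    # exponential tail with the rate solved so the survival median equals the
    # configured stratum median
    t30 = DAYS_30_IN_MONTHS
    death30 = rng.random(m) < p30
    early = rng.uniform(0.02, t30, m)
    rate = np.log(2.0 * (1.0 - p30)) / (med - t30)
    late = t30 + rng.exponential(1.0 / rate, m)
    t_death = np.where(death30, early, late)
    cols["death_30d"] = death30
    cols["os_event"] = t_death <= cens
    cols["os_time"] = np.minimum(t_death, cens)

    lam_d = np.log(2.0) / med
    for prefix, targets, cause_name, death_name in (
        ("bleed", config.bleed_cif_6mo, "bleeding", "death_without_bleeding"),
        ("rethrombosis", config.rethrombosis_cif_6mo, "rethrombosis",
         "death_without_rethrombosis"),
    ):
        group = "high" if STRATA[s] == "high" else "low_moderate"
        lam_e = calibrate_competing_hazards(
            targets[group], lam_d, config.cif_horizon_months
        )
        tot = lam_e + lam_d
        t_tot = rng.exponential(1.0 / tot, m) if tot > 0 else np.full(m, np.inf)
        is_event = rng.random(m) < (lam_e / tot if tot > 0 else 0.0)
        observed = t_tot <= cens
        status = np.where(
            observed, np.where(is_event, cause_name, death_name), "censored"
        )
        cols[f"{prefix}_time"] = np.minimum(t_tot, cens)
        cols[f"{prefix}_status"] = status
    return cols


def generate_cohort(
    config: Optional[CohortConfig] = None,
    tree: Optional[DecisionTreeSpec] = None,
    seed: Optional[int] = None,
) -> CohortTable:
    """Generate a cohort table under the configured study conditions.

    Deterministic: the same seed and config yield a byte-identical CSV via
    :func:`epiphany.cohort_io.write_cohort`.
    """
    config = config or CohortConfig()
    config.validate()
    tree = tree or default_tree()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    paths = tree.leaf_paths()
    leaves_by_stratum: Dict[str, list] = {s: [] for s in STRATA}
    for leaf, cat in tree.leaves.items():
        leaves_by_stratum[cat].append(leaf)
    for s in STRATA:
        if config.stratum_probs[STRATA.index(s)] > 0 and not leaves_by_stratum[s]:
            raise ConfigTreeMismatch(f"stratum {s!r} has no reachable leaf in the tree")

    strat_counts = rng.multinomial(config.n_total, config.stratum_probs)
    frames = []
    for s_idx, stratum in enumerate(STRATA):
        n_s = int(strat_counts[s_idx])
        if n_s == 0:
            continue
        leaves = sorted(leaves_by_stratum[stratum])
        if config.leaf_weights:
            w = np.array([config.leaf_weights.get(l, 1.0) for l in leaves], float)
        else:
            w = np.ones(len(leaves))
        leaf_counts = rng.multinomial(n_s, w / w.sum())
        for leaf, m in zip(leaves, leaf_counts):
            if m == 0:
                continue
            cons = _path_constraints(paths[leaf])
            cols = _sample_block(rng, int(m), cons, config, stratum)
            cols.update(_sample_outcomes(rng, int(m), s_idx, config))
            block = pd.DataFrame(cols)
            block["_stratum"] = stratum
            block["_leaf"] = leaf
            frames.append(block)

    frame = pd.concat(frames, ignore_index=True)
    perm = rng.permutation(len(frame))
    frame = frame.iloc[perm].reset_index(drop=True)
    frame.insert(0, "episode_id", [f"ep{i + 1:06d}" for i in range(len(frame))])
    frame = frame[COLUMNS + ["_stratum", "_leaf"]]

    _assert_round_trip(frame, tree)
    return CohortTable(frame, source=f"synthetic(seed={config.seed if seed is None else seed})")


def _assert_round_trip(frame: pd.DataFrame, tree: DecisionTreeSpec) -> None:
    """Verify classify(episode) == sampled stratum for every generated row."""
    feats = _vector_features(frame)
    for i, f in enumerate(feats):
        got = tree.classify_features(f)
        want = frame["_stratum"].iat[i]
        if got != want:
            raise AssertionError(
                f"round-trip failure at row {i}: sampled {want!r}, classified {got!r}"
            )


def _vector_features(frame: pd.DataFrame) -> list:
    """Tree features for every row, computed from the raw columns."""
    from .cohort_io import RECIST_PROGRESSING

    hestia = (
        (frame["sbp"] < 100)
        | (frame["spo2"] < 90)
        | (frame["rr"] >= 30)
        | (frame["hr"] >= 110)
        | frame["pe_symptoms"].str.contains("sudden_or_progressive_dyspnea")
        | frame["other_admission_criterion"].astype(bool)
        | frame["clinically_relevant_bleeding"].astype(bool)
        | frame["high_bleeding_risk"].astype(bool)
        | (frame["platelets"] < 50_000)
    ).to_numpy()
    recist_group = np.where(
        frame["recist"].isin(sorted(RECIST_PROGRESSING)), "progressing", "controlled"
    )
    out = []
    for i in range(len(frame)):
        out.append(
            {
                "hestia_any": bool(hestia[i]),
                "presentation": frame["presentation"].iat[i],
                "recist_group": recist_group[i],
                "primary_resected": bool(frame["primary_resected"].iat[i]),
                "spo2": float(frame["spo2"].iat[i]),
                "ecog_ps": int(frame["ecog_ps"].iat[i]),
            }
        )
    return out
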