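"""Risk classifiers: adapted Hestia criteria, the EPIPHANY decision tree, and
point-based comparator scores.

All three classifiers are *data*, not code: the adapted Hestia checklist, the
decision tree, and each point score ship as YAML files under ``models/`` so
that the transcription from the source publications stays reviewable and
replaceable.  This module only interprets those specifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort_io import (
    PE_SYMPTOMS,
    PRESENTATIONS,
    CohortTable,
    PatientEpisode,
)

MODELS_DIR = Path(__file__).parent / "models"
RISK_ORDER = {"low": 0, "intermediate": 1, "high": 2}

_MISSING = object()


class ModelSpecError(ValueError):
    """A model configuration file is structurally invalid or ambiguous."""


class UnevaluableError(ValueError):
    """An episode lacks the data a criterion or score item needs."""


def _load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _episode_value(episode: PatientEpisode, feature: str):
    if hasattr(episode, feature):
        return getattr(episode, feature)
    return episode.extras.get(feature, _MISSING)


def _apply_op(op: str, value, target) -> bool:
    if op == "eq":
        return value == target
    if op == "lt":
        return value < target
    if op == "le":
        return value <= target
    if op == "gt":
        return value > target
    if op == "ge":
        return value >= target
    if op == "in":
        return value in target
    if op == "contains":
        return target in value
    raise ModelSpecError(f"unknown predicate op {op!r}")


# --- adapted Hestia criteria -------------------------------------------------

@dataclass(frozen=True)
class HestiaAssessment:
    criteria_met: frozenset
    any_met: bool

    def __post_init__(self):
        assert self.any_met == bool(self.criteria_met)


@dataclass
class HestiaSpec:
    name: str
    criteria: list  # of dicts {name, feature, op, value}

    @classmethod
    def load(cls, path=None) -> "HestiaSpec":
        raw = _load_yaml(path or MODELS_DIR / "hestia_adapted.yaml")
        return cls(name=raw["name"], criteria=raw["criteria"])


_DEFAULT_HESTIA: Optional[HestiaSpec] = None


def default_hestia_spec() -> HestiaSpec:
    global _DEFAULT_HESTIA
    if _DEFAULT_HESTIA is None:
        _DEFAULT_HESTIA = HestiaSpec.load()
    return _DEFAULT_HESTIA


def assess_hestia(
    episode: PatientEpisode, spec: Optional[HestiaSpec] = None, strict: bool = True
) -> HestiaAssessment:
    """Exact subset of the nine adapted criteria met by an episode.

    Inequalities are strict/weak exactly as the checklist prints them, so
    boundary vitals (SBP exactly 100, SpO2 exactly 90) trigger nothing.
    """
    spec = spec or default_hestia_spec()
    met = set()
    for crit in spec.criteria:
        value = _episode_value(episode, crit["feature"])
        if value is _MISSING or value is None:
            if strict:
                raise UnevaluableError(
                    f"criterion {crit['name']!r} cannot be evaluated: "
                    f"missing {crit['feature']!r}"
                )
            continue
        if _apply_op(crit["op"], value, crit["value"]):
            met.add(crit["name"])
    return HestiaAssessment(frozenset(met), bool(met))


# --- EPIPHANY decision tree --------------------------------------------------

#: discretized lattice used to prove exhaustiveness/determinism by enumeration.
#: SpO2 / ECOG-PS probes bracket every cutpoint a shipped or user tree may use.
FEATURE_LATTICE = {
    "hestia_any": [False, True],
    "presentation": sorted(PRESENTATIONS),
    "recist_group": ["controlled", "progressing"],
    "primary_resected": [False, True],
    "spo2": [80.0, 88.0, 89.9, 90.0, 92.9, 93.0, 95.0, 100.0],
    "ecog_ps": [0, 1, 2, 3, 4],
}


def tree_features(episode: PatientEpisode, hestia: Optional[HestiaAssessment] = None) -> dict:
    """The split variables of the index, derived from one episode."""
    hestia = hestia or assess_hestia(episode)
    return {
        "hestia_any": hestia.any_met,
        "presentation": episode.presentation,
        "recist_group": episode.recist_group,
        "primary_resected": episode.primary_resected,
        "spo2": episode.spo2,
        "ecog_ps": episode.ecog_ps,
    }


@dataclass
class DecisionTreeSpec:
    name: str
    root: str
    nodes: dict  # node_id -> {test: {feature, op, value}, if_true, if_false}
    leaves: dict  # leaf_id -> category

    @classmethod
    def load(cls, path=None) -> "DecisionTreeSpec":
        raw = _load_yaml(path or MODELS_DIR / "epiphany_tree.yaml")
        tree = cls(
            name=raw.get("name", "tree"),
            root=raw["root"],
            nodes=raw["nodes"],
            leaves=raw["leaves"],
        )
        tree.validate()
        return tree

    # -- structural validation ------------------------------------------------

    def validate(self) -> None:
        if self.root not in self.nodes and self.root not in self.leaves:
            raise ModelSpecError(f"root {self.root!r} is neither a node nor a leaf")
        for leaf, cat in self.leaves.items():
            if cat not in RISK_ORDER:
                raise ModelSpecError(f"leaf {leaf!r} has unknown category {cat!r}")
        for nid, node in self.nodes.items():
            if nid in self.leaves:
                raise ModelSpecError(f"{nid!r} is both a node and a leaf")
            test = node.get("test")
            if not test or not {"feature", "op"} <= set(test):
                raise ModelSpecError(f"node {nid!r} has no well-formed test")
            if test["feature"] not in FEATURE_LATTICE:
                raise ModelSpecError(
                    f"node {nid!r} tests unknown feature {test['feature']!r}"
                )
            for branch in ("if_true", "if_false"):
                target = node.get(branch)
                if target is None:
                    raise ModelSpecError(f"node {nid!r} missing branch {branch!r}")
                if target not in self.nodes and target not in self.leaves:
                    raise ModelSpecError(
                        f"node {nid!r} branch {branch!r} targets unknown id {target!r}"
                    )
        self._check_single_rooted_acyclic()
        # exhaustiveness + determinism over the discretized feature lattice
        for combo in enumerate_lattice():
            self.classify_features(combo)

    def _check_single_rooted_acyclic(self) -> None:
        seen: set = set()
        stack: set = set()

        def visit(nid: str):
            if nid in self.leaves:
                return
            if nid in stack:
                raise ModelSpecError(f"cycle through node {nid!r}")
            if nid in seen:
                return
            stack.add(nid)
            for branch in ("if_true", "if_false"):
                visit(self.nodes[nid][branch])
            stack.discard(nid)
            seen.add(nid)

        visit(self.root)
        unreachable = set(self.nodes) - seen
        if unreachable:
            raise ModelSpecError(f"unreachable nodes: {sorted(unreachable)}")

    # -- classification -------------------------------------------------------

    def classify_features(self, features: dict, return_leaf: bool = False):
        nid = self.root
        for _ in range(len(self.nodes) + 1):
            if nid in self.leaves:
                cat = self.leaves[nid]
                return (cat, nid) if return_leaf else cat
            node = self.nodes[nid]
            test = node["test"]
            value = features.get(test["feature"], _MISSING)
            if value is _MISSING or value is None:
                raise UnevaluableError(
                    f"tree node {nid!r} needs feature {test['feature']!r}"
                )
            nid = node["if_true"] if _apply_op(test["op"], value, test.get("value")) else node["if_false"]
        raise ModelSpecError("classification did not reach a leaf")

    def leaf_paths(self) -> dict:
        """leaf_id -> list of (feature, op, value, branch_taken) constraints."""
        paths: dict = {}

        def walk(nid, path):
            if nid in self.leaves:
                paths[nid] = list(path)
                return
            t = self.nodes[nid]["test"]
            walk(self.nodes[nid]["if_true"], path + [(t["feature"], t["op"], t.get("value"), True)])
            walk(self.nodes[nid]["if_false"], path + [(t["feature"], t["op"], t.get("value"), False)])

        walk(self.root, [])
        return paths


def enumerate_lattice() -> Iterable[dict]:
    """Every combination of the discretized split variables.

    The symptomatic/asymptomatic distinction is derived from presentation, so
    the lattice stays internally consistent.
    """
    from itertools import product

    keys = list(FEATURE_LATTICE)
    for values in product(*(FEATURE_LATTICE[k] for k in keys)):
        yield dict(zip(keys, values))


_DEFAULT_TREE: Optional[DecisionTreeSpec] = None


def default_tree() -> DecisionTreeSpec:
    global _DEFAULT_TREE
    if _DEFAULT_TREE is None:
        _DEFAULT_TREE = DecisionTreeSpec.load()
    return _DEFAULT_TREE


def classify_epiphany(
    episode: PatientEpisode,
    tree: Optional[DecisionTreeSpec] = None,
    hestia_spec: Optional[HestiaSpec] = None,
) -> str:
    """Risk category ('low' | 'intermediate' | 'high') for one episode."""
    tree = tree or default_tree()
    return tree.classify_features(tree_features(episode, assess_hestia(episode, hestia_spec)))


def audit_hestia_monotonicity(tree: Optional[DecisionTreeSpec] = None) -> list:
    """Check that turning the Hestia flag on never lowers the risk category.

    Returns the list of violating lattice points (empty for a sound tree);
    violations are reported, never silently accepted.
    """
    tree = tree or default_tree()
    violations = []
    for combo in enumerate_lattice():
        if combo["hestia_any"]:
            continue
        before = tree.classify_features(combo)
        flipped = dict(combo, hestia_any=True)
        after = tree.classify_features(flipped)
        if RISK_ORDER[after] < RISK_ORDER[before]:
            violations.append((combo, before, after))
    return violations


# --- point-based comparator scores ------------------------------------------

@dataclass
class PointScoreSpec:
    """Declarative sum score: items award points, thresholds map to classes."""

    name: str
    enabled: bool
    items: list
    classes: list  # [{name, min?, max?, predicted_30d_mortality}]

    @classmethod
    def load(cls, path) -> "PointScoreSpec":
        raw = _load_yaml(path)
        spec = cls(
            name=raw["name"],
            enabled=bool(raw.get("enabled", False)),
            items=raw.get("items") or [],
            classes=raw.get("classes") or [],
        )
        for c in spec.classes:
            p = c.get("predicted_30d_mortality")
            if p is not None and not 0 <= p <= 1:
                raise ModelSpecError(f"{spec.name}: class {c['name']!r} probability {p}")
        return spec

    def class_for(self, score: float) -> str:
        for c in self.classes:
            lo = c.get("min", -np.inf)
            hi = c.get("max", np.inf)
            if lo <= score <= hi:
                return c["name"]
        raise ModelSpecError(f"{self.name}: score {score} matches no class range")


def available_score_specs() -> dict:
    """All shipped point-score configurations, keyed by name."""
    return {
        p.stem: PointScoreSpec.load(p)
        for p in sorted(MODELS_DIR.glob("*.yaml"))
        if p.stem not in {"cohort_schema", "epiphany_tree", "hestia_adapted"}
    }


def score_points(episode: PatientEpisode, spec: PointScoreSpec):
    """(total score, risk class) for one episode under a point-score spec."""
    if not spec.enabled:
        raise UnevaluableError(f"model {spec.name!r} is a stub (enabled: false)")
    total = 0.0
    for item in spec.items:
        op = item["op"]
        if op == "always":
            total += item.get("points", 0)
            continue
        value = _episode_value(episode, item["feature"])
        if value is _MISSING or value is None:
            policy = item.get("missing", "error")
            if policy == "assume_false":
                continue
            raise UnevaluableError(
                f"{spec.name}: item {item['name']!r} cannot be evaluated "
                f"(missing {item['feature']!r})"
            )
        if op == "points_from_value":
            total += float(value)
        elif _apply_op(op, value, item.get("value")):
            total += item.get("points", 0)
    return total, spec.class_for(total)


def predicted_vs_observed(cohort: CohortTable, spec: PointScoreSpec) -> pd.DataFrame:
    """Observed vs model-predicted 30-day deaths per risk class.

    Expected deaths per class are n * predicted probability; the observed
    count gets an exact (Clopper-Pearson) binomial interval.  Classes with no
    members, or zero expected deaths, are emitted with the ratio flagged
    undefined rather than dropped.
    """
    from scipy.stats import beta as beta_dist

    pred = {c["name"]: c.get("predicted_30d_mortality") for c in spec.classes}
    rows = []
    assignments = []
    deaths = []
    for ep in cohort.episodes():
        _, cls = score_points(ep, spec)
        assignments.append(cls)
        deaths.append(bool(ep.death_30d))
    assignments = np.asarray(assignments)
    deaths = np.asarray(deaths)

    def one_row(name, mask, p):
        n = int(mask.sum())
        obs = int(deaths[mask].sum())
        exp = (n * p) if p is not None else np.nan
        ratio = obs / exp if exp and exp > 0 else np.nan
        lo = beta_dist.ppf(0.025, obs, n - obs + 1) if n and obs > 0 else (0.0 if n else np.nan)
        hi = beta_dist.ppf(0.975, obs + 1, n - obs) if n and obs < n else (1.0 if n else np.nan)
        return {
            "class": name,
            "n": n,
            "observed_deaths": obs,
            "expected_deaths": exp,
            "ratio": ratio,
            "ratio_defined": bool(np.isfinite(ratio)),
            "obs_rate_ci_low": lo,
            "obs_rate_ci_high": hi,
        }

    for c in spec.classes:
        rows.append(one_row(c["name"], assignments == c["name"], pred[c["name"]]))
    pooled_expected = sum(
        r["expected_deaths"] for r in rows if np.isfinite(r["expected_deaths"])
    )
    pooled = one_row("all", np.ones(len(assignments), bool), None)
    pooled["expected_deaths"] = pooled_expected
    pooled["ratio"] = (
        pooled["observed_deaths"] / pooled_expected if pooled_expected > 0 else np.nan
    )
    pooled["ratio_defined"] = bool(np.isfinite(pooled["ratio"]))
    rows.append(pooled)
    return pd.DataFrame(rows)
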