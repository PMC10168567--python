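"""End-to-end validation pipeline.

Runs the full rule-validation analysis on a cohort table and emits the report
bundle as CSV tables plus a structured run log: per-stratum event estimation
(raw proportion, Jeffreys posterior mean/mode, HDI and equal-tailed
intervals), pairwise posterior exceedance probabilities, comparator-model
accuracy metrics with pairwise DeLong tests, Kaplan-Meier curves and medians
by stratum, Aalen-Johansen bleeding/rethrombosis incidences with Gray's
tests (high vs low-or-moderate), the logistic odds-ratio table, a per-leaf
decision-tree reconstruction, and the two prespecified subgroup re-runs
(excluding prior anticoagulation; outpatients only).

Any stage failure aborts the run with the stage name and removes partial
outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._util import DEFAULT_SEED, pct
from .bayes_binomial import central_interval, hdi, jeffreys_posterior, prob_greater
from .cohort_io import CohortTable, read_cohort
from .diagnostics import (
    TwoByTwo,
    auc_delong,
    auc_mann_whitney,
    diagnostic_metrics,
    epiphany_design,
    logistic_fit,
)
from .risk_models import (
    DecisionTreeSpec,
    PointScoreSpec,
    UnevaluableError,
    assess_hestia,
    available_score_specs,
    classify_epiphany,
    default_tree,
    score_points,
    tree_features,
)
from .synthetic_cohort import STRATA
from .time_to_event import aalen_johansen, gray_test, km_fit


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def _classify_all(cohort: CohortTable, tree: DecisionTreeSpec):
    cats, hestia_any = [], []
    for ep in cohort.episodes():
        h = assess_hestia(ep)
        cats.append(tree.classify_features(tree_features(ep, h)))
        hestia_any.append(h.any_met)
    return np.asarray(cats, object), np.asarray(hestia_any, bool)


def _stratum_rows(mask_by_label, outcome: np.ndarray, endpoint: str):
    rows = []
    for label, mask in mask_by_label:
        n = int(mask.sum())
        k = int(outcome[mask].sum()) if n else 0
        post = jeffreys_posterior(k, n)
        defined = n > 0
        h = hdi(post) if defined else None
        c = central_interval(post) if defined else None
        rows.append(
            {
                "endpoint": endpoint,
                "category": label,
                "events": k,
                "n": n,
                "raw_pct": pct(post.raw) if defined else np.nan,
                "posterior_mean_pct": pct(post.mean) if defined else np.nan,
                "posterior_mode_pct": pct(post.mode) if defined and post.mode is not None else np.nan,
                "hdi_low_pct": pct(h.lower) if defined else np.nan,
                "hdi_high_pct": pct(h.upper) if defined else np.nan,
                "central_low_pct": pct(c.lower) if defined else np.nan,
                "central_high_pct": pct(c.upper) if defined else np.nan,
                "undefined": not defined,
            }
        )
    return pd.DataFrame(rows)


def stratum_table(cohort: CohortTable, cats: np.ndarray, hestia_any: np.ndarray) -> pd.DataFrame:
    frame = cohort.frame
    comp = frame["complication_15d"].astype(bool).to_numpy()
    death = frame["death_30d"].astype(bool).to_numpy()
    groups = [(f"epiphany_{s}", cats == s) for s in STRATA]
    groups += [("hestia_negative", ~hestia_any), ("hestia_positive", hestia_any)]
    out = [
        _stratum_rows(groups, comp, "complications_15d"),
        _stratum_rows(groups, death, "death_30d"),
    ]
    return pd.concat(out, ignore_index=True)


def exceedance_table(cohort: CohortTable, cats: np.ndarray, hestia_any: np.ndarray) -> pd.DataFrame:
    comp = cohort.frame["complication_15d"].astype(bool).to_numpy()

    def post(mask):
        return jeffreys_posterior(int(comp[mask].sum()), int(mask.sum()))

    pairs = [
        ("epiphany_intermediate", "epiphany_low", cats == "intermediate", cats == "low"),
        ("epiphany_high", "epiphany_intermediate", cats == "high", cats == "intermediate"),
        ("epiphany_high", "epiphany_low", cats == "high", cats == "low"),
        ("hestia_positive", "hestia_negative", hestia_any, ~hestia_any),
    ]
    rows = []
    for a, b, ma, mb in pairs:
        if ma.sum() == 0 or mb.sum() == 0:
            rows.append({"greater": a, "lesser": b, "prob_pct": np.nan, "undefined": True})
            continue
        p = prob_greater(post(ma), post(mb))
        rows.append({"greater": a, "lesser": b, "prob_pct": pct(p), "undefined": False})
    return pd.DataFrame(rows)


def compare_models(
    cohort: CohortTable,
    models: Optional[dict] = None,
    outcome: str = "complications_15d",
    tree: Optional[DecisionTreeSpec] = None,
) -> pd.DataFrame:
    """Accuracy metrics per configured model, plus pairwise DeLong tests.

    Models are (name -> scorer) where a scorer maps an episode to a numeric
    risk score and a positivity flag.  The shipped set contains the
    dichotomized index (high vs other), the adapted Hestia rule, and every
    enabled point score; unevaluable models are skipped with a named warning.
    """
    tree = tree or default_tree()
    outcome_field = "complication_15d" if outcome == "complications_15d" else "death_30d"
    if models is None:
        models = standard_models(tree)

    labels = cohort.frame[outcome_field].astype(bool).to_numpy()
    rows = []
    scores: dict = {}
    for name, scorer in models.items():
        try:
            sc, pos = [], []
            for ep in cohort.episodes():
                s, p = scorer(ep)
                sc.append(s)
                pos.append(p)
        except UnevaluableError as exc:
            warnings.warn(f"model {name!r} skipped: {exc}")
            continue
        sc = np.asarray(sc, float)
        pos = np.asarray(pos, bool)
        t = TwoByTwo(
            tp=int((pos & labels).sum()),
            fp=int((pos & ~labels).sum()),
            fn=int((~pos & labels).sum()),
            tn=int((~pos & ~labels).sum()),
        )
        m = diagnostic_metrics(t)
        auc = auc_mann_whitney(sc, labels) if 0 < labels.sum() < len(labels) else np.nan
        scores[name] = sc
        rows.append(
            {
                "model": name,
                "outcome": outcome,
                "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
                "sensitivity_pct": pct(m.sensitivity.value),
                "specificity_pct": pct(m.specificity.value),
                "ppv_pct": pct(m.ppv.value),
                "npv_pct": pct(m.npv.value),
                "npv_ci_low_pct": pct(m.npv.lower),
                "npv_ci_high_pct": pct(m.npv.upper),
                "plr": m.plr.value,
                "nlr": m.nlr.value,
                "auc": auc,
            }
        )
    if not rows:
        raise ValueError("no evaluable model")
    return pd.DataFrame(rows), _pairwise_delong(scores, labels)


def _pairwise_delong(scores: dict, labels: np.ndarray) -> pd.DataFrame:
    names = list(scores)
    rows = []
    if 0 < labels.sum() < len(labels):
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = auc_delong(scores[names[i]], scores[names[j]], labels)
                rows.append(
                    {
                        "model_1": names[i], "model_2": names[j],
                        "auc_1": r.auc_1, "auc_2": r.auc_2,
                        "z": r.z, "p_value": r.p_value,
                    }
                )
    return pd.DataFrame(rows, columns=["model_1", "model_2", "auc_1", "auc_2", "z", "p_value"])


def standard_models(tree: DecisionTreeSpec, extra_scores: Sequence[str] = ()) -> dict:
    """The default comparator set for :func:`compare_models`."""
    cat_score = {"low": 1.0, "intermediate": 2.0, "high": 3.0}

    def epiphany_scorer(ep):
        cat = classify_epiphany(ep, tree)
        return cat_score[cat], cat == "high"

    def hestia_scorer(ep):
        a = assess_hestia(ep)
        return float(len(a.criteria_met) > 0), a.any_met

    models = {"epiphany_dichotomized": epiphany_scorer, "hestia_adapted": hestia_scorer}
    specs = available_score_specs()
    for name, spec in specs.items():
        if not spec.enabled:
            continue

        def point_scorer(ep, _spec=spec):
            score, cls = score_points(ep, _spec)
            positive = cls != _spec.classes[0]["name"]
            return score, positive

        models[name] = point_scorer
    return models


def tree_reconstruction(cohort: CohortTable, tree: DecisionTreeSpec) -> pd.DataFrame:
    """Per-leaf episode counts and complication rates (the reconstructed tree)."""
    rows = {leaf: {"leaf": leaf, "category": cat, "n": 0, "complications": 0}
            for leaf, cat in tree.leaves.items()}
    for ep in cohort.episodes():
        _, leaf = tree.classify_features(
            tree_features(ep, assess_hestia(ep)), return_leaf=True
        )
        rows[leaf]["n"] += 1
        rows[leaf]["complications"] += int(bool(ep.complication_15d))
    out = pd.DataFrame(list(rows.values()))
    out["complication_rate_pct"] = [
        pct(c / n) if n else np.nan for c, n in zip(out["complications"], out["n"])
    ]
    return out


def km_by_stratum(cohort: CohortTable, cats: np.ndarray):
    frame = cohort.frame
    ok = frame["os_time"].notna() & frame["os_event"].notna()
    curves, med_rows = [], []
    for s in STRATA:
        mask = (cats == s) & ok.to_numpy()
        if mask.sum() == 0:
            med_rows.append({"category": s, "n": 0, "median_months": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan})
            continue
        sc = km_fit(
            frame.loc[mask, "os_time"].astype(float),
            frame.loc[mask, "os_event"].astype(bool),
        )
        curves.append(
            pd.DataFrame(
                {
                    "group": s,
                    "time": sc.times,
                    "estimate": sc.survival,
                    "variance": sc.variance,
                    "n_at_risk": sc.at_risk,
                }
            )
        )
        med_rows.append(
            {"category": s, "n": sc.n, "median_months": sc.median,
             "ci_low": sc.median_ci[0], "ci_high": sc.median_ci[1]}
        )
    curve_df = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
    return curve_df, pd.DataFrame(med_rows)


_STATUS_CODES = {
    "bleed": {"censored": 0, "bleeding": 1, "death_without_bleeding": 2},
    "rethrombosis": {"censored": 0, "rethrombosis": 1, "death_without_rethrombosis": 2},
}


def competing_risks_analysis(cohort: CohortTable, cats: np.ndarray, horizon: float = 6.0):
    """AJ incidence curves for bleeding/rethrombosis, high vs low-or-moderate,
    with Gray's test for each event."""
    frame = cohort.frame
    rows, curves = [], []
    for prefix in ("bleed", "rethrombosis"):
        codes = _STATUS_CODES[prefix]
        ok = frame[f"{prefix}_time"].notna() & frame[f"{prefix}_status"].notna()
        groups = {}
        for gname, mask in (
            ("low_moderate", np.isin(cats, ["low", "intermediate"])),
            ("high", cats == "high"),
        ):
            mm = mask & ok.to_numpy()
            t = frame.loc[mm, f"{prefix}_time"].astype(float).to_numpy()
            s = frame.loc[mm, f"{prefix}_status"].map(codes).to_numpy()
            groups[gname] = (t, s)
            if len(t):
                ci = aalen_johansen(t, s)
                curves.append(
                    pd.DataFrame(
                        {
                            "event": prefix,
                            "group": gname,
                            "time": ci.times,
                            "estimate": ci.cif[1],
                            "variance": ci.variance[1],
                        }
                    )
                )
        if all(len(t) for t, _ in groups.values()):
            g = gray_test([groups["low_moderate"], groups["high"]], cause=1)
            at6 = {
                name: aalen_johansen(*groups[name]).at(horizon, 1) for name in groups
            }
            rows.append(
                {
                    "event": prefix,
                    "cif_low_moderate_pct": pct(at6["low_moderate"]),
                    "cif_high_pct": pct(at6["high"]),
                    "horizon_months": horizon,
                    "gray_statistic": g.statistic,
                    "gray_p": g.p_value,
                }
            )
    curve_df = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
    return curve_df, pd.DataFrame(rows)


def outpatient_table(cohort: CohortTable, cats: np.ndarray) -> pd.DataFrame:
    frame = cohort.frame
    out_mask = frame["outpatient"].astype(bool).to_numpy()
    comp = frame["complication_15d"].astype(bool).to_numpy()
    groups = [
        ("epiphany_low_intermediate", out_mask & np.isin(cats, ["low", "intermediate"])),
        ("epiphany_high", out_mask & (cats == "high")),
    ]
    table = _stratum_rows(groups, comp, "complications_15d_outpatient")
    lo, hi = groups[0][1], groups[1][1]
    if lo.sum() and hi.sum():
        p = prob_greater(
            jeffreys_posterior(int(comp[hi].sum()), int(hi.sum())),
            jeffreys_posterior(int(comp[lo].sum()), int(lo.sum())),
        )
        table.attrs["prob_high_gt_low_intermediate_pct"] = pct(p)
    return table


def run_validation(
    cohort: CohortTable | str | Path,
    output_dir: str | Path,
    tree: Optional[DecisionTreeSpec] = None,
    seed: int = DEFAULT_SEED,
    exclude_prior_anticoag: bool = False,
    outpatient_only: bool = False,
    config_hash: Optional[str] = None,
) -> dict:
    """Run every stage and write the report bundle under ``output_dir``.

    Returns a dict of the in-memory tables.  On any stage failure the partial
    bundle is removed and :class:`PipelineError` names the stage.
    """
    tree = tree or default_tree()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    created = False
    results: dict = {}
    stage = "load"
    try:
        if not isinstance(cohort, CohortTable):
            cohort = read_cohort(cohort, strict=True)
        if exclude_prior_anticoag:
            cohort = cohort.subset(~cohort.frame["prior_anticoagulation"].astype(bool))
        if outpatient_only:
            cohort = cohort.subset(cohort.frame["outpatient"].astype(bool))
        if len(cohort) == 0:
            raise ValueError("no episodes after subgroup filters")

        stage = "classification"
        cats, hestia_any = _classify_all(cohort, tree)

        stage = "stratum_table"
        results["stratum_table"] = stratum_table(cohort, cats, hestia_any)
        stage = "exceedance"
        results["exceedance"] = exceedance_table(cohort, cats, hestia_any)
        stage = "model_comparison"
        comp_tables = {}
        for oc in ("complications_15d", "death_30d"):
            metrics, delong = compare_models(cohort, outcome=oc, tree=tree)
            comp_tables[oc] = (metrics, delong)
        results["model_comparison"] = comp_tables
        stage = "km"
        results["km_curves"], results["km_medians"] = km_by_stratum(cohort, cats)
        stage = "competing_risks"
        results["cif_curves"], results["gray_tests"] = competing_risks_analysis(cohort, cats)
        stage = "logistic"
        try:
            fit = logistic_fit(
                epiphany_design(cohort),
                cohort.frame["complication_15d"].astype(bool).to_numpy(),
            )
            results["logistic"] = fit.table
        except ValueError as exc:
            # degenerate designs (single-class outcome, constant predictor in a
            # one-stratum cohort) are reported, not fatal
            results["logistic"] = pd.DataFrame(
                [{"variable": None, "or": np.nan, "note": str(exc)}]
            )
        stage = "tree_reconstruction"
        results["tree_leaves"] = tree_reconstruction(cohort, tree)
        stage = "outpatient_subgroup"
        results["outpatient"] = outpatient_table(cohort, cats)
        stage = "sensitivity_prior_anticoag"
        if not exclude_prior_anticoag:
            sens = cohort.subset(~cohort.frame["prior_anticoagulation"].astype(bool))
            if len(sens):
                s_cats, s_h = _classify_all(sens, tree)
                results["sensitivity_excl_anticoag"] = stratum_table(sens, s_cats, s_h)

        stage = "write"
        created = True
        results["stratum_table"].to_csv(out / "stratum_table.csv", index=False)
        results["exceedance"].to_csv(out / "exceedance.csv", index=False)
        for oc, (metrics, delong) in comp_tables.items():
            metrics.to_csv(out / f"model_comparison_{oc}.csv", index=False)
            delong.to_csv(out / f"delong_{oc}.csv", index=False)
        results["km_curves"].to_csv(out / "km_curves.csv", index=False)
        results["km_medians"].to_csv(out / "km_medians.csv", index=False)
        results["cif_curves"].to_csv(out / "cif_curves.csv", index=False)
        results["gray_tests"].to_csv(out / "gray_tests.csv", index=False)
        results["logistic"].to_csv(out / "logistic_or.csv", index=False)
        results["tree_leaves"].to_csv(out / "tree_leaves.csv", index=False)
        results["outpatient"].to_csv(out / "outpatient.csv", index=False)
        if "sensitivity_excl_anticoag" in results:
            results["sensitivity_excl_anticoag"].to_csv(
                out / "sensitivity_excl_anticoag.csv", index=False
            )
        log = {
            "package_version": __version__,
            "seed": seed,
            "n_episodes": len(cohort),
            "tree": tree.name,
            "source": cohort.source,
            "config_hash": config_hash,
            "filters": {
                "exclude_prior_anticoag": exclude_prior_anticoag,
                "outpatient_only": outpatient_only,
            },
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        return results
    except Exception as exc:  # noqa: BLE001 - abort semantics need the stage name
        if created:
            for f in out.glob("*"):
                if f.is_file():
                    f.unlink()
        raise PipelineError(stage, exc) from exc


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
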