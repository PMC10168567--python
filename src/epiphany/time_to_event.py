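"""Overall survival and competing-risks analyses.

Kaplan-Meier curves with Greenwood variance and median survival (interval by
inverting the log(-log) confidence band, the Brookmeyer-Crowley construction),
the log-rank test, the Aalen-Johansen cumulative-incidence estimator for an
event with death as a competing risk, and Gray's test comparing two
cumulative-incidence functions.

Kaplan-Meier, log-rank and Aalen-Johansen are delegated to lifelines behind
this module's interface; Gray's test is implemented here (no installed Python
package provides it).  Ties between events and censorings at the same time
follow the standard convention: events first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy.stats import chi2


@dataclass
class SurvivalCurve:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) at those times
    variance: np.ndarray  # Greenwood variance of S(t)
    at_risk: np.ndarray
    median: float  # NaN when the curve never reaches 0.5
    median_ci: tuple
    n: int

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_fit(times: Sequence[float], event_flags: Sequence[bool]) -> SurvivalCurve:
    """Product-limit estimate of the survival function.

    The median is the first time S(t) <= 0.5; with everything censored the
    median is undefined and returned as NaN (flagged, not raised).
    """
    t = np.asarray(times, float)
    e = np.asarray(event_flags).astype(bool)
    if np.any(t < 0):
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    # keep rows with at least one event (the survival steps)
    steps = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    s_at = surv.loc[steps.index].to_numpy()
    # Greenwood: Var[S(t)] = S(t)^2 * cumsum(d / (n (n - d)))
    d = steps["observed"].to_numpy(float)
    n_at = steps["at_risk"].to_numpy(float)
    greenwood = s_at**2 * np.cumsum(
        np.divide(d, n_at * (n_at - d), out=np.full_like(d, np.inf), where=n_at > d)
    )
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo = float(ci.iloc[0, 0])
    hi = float(ci.iloc[0, 1])
    return SurvivalCurve(
        times=steps.index.to_numpy(float),
        survival=s_at,
        variance=greenwood,
        at_risk=n_at,
        median=median if np.isfinite(median) else float("nan"),
        median_ci=(lo, hi),
        n=len(t),
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int


def logrank_test(groups: Sequence[tuple]) -> LogrankResult:
    """K-sample log-rank test; ``groups`` is a list of (times, event_flags)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, float)
        times.append(t)
        events.append(np.asarray(e).astype(int))
        labels.append(np.full(len(t), i))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return LogrankResult(float(res.test_statistic), float(res.p_value), len(groups) - 1)


# --- Aalen-Johansen ---------------------------------------------------------

@dataclass
class CumulativeIncidence:
    times: np.ndarray
    cif: Dict[int, np.ndarray]  # cause -> F_cause(t) on ``times``
    variance: Dict[int, np.ndarray]
    n: int

    def at(self, t: float, cause: int) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cif[cause][idx])


def aalen_johansen(
    times: Sequence[float], status: Sequence[int], causes: Sequence[int] = (1, 2)
) -> CumulativeIncidence:
    """Cause-specific cumulative incidence (0 = censored, 1, 2 = causes).

    With a single cause present the estimate reduces exactly to 1 - KM.
    """
    t = np.asarray(times, float)
    s = np.asarray(status).astype(int)
    valid = set(causes) | {0}
    bad = set(np.unique(s)) - valid
    if bad:
        raise ValueError(f"unknown status code(s) {sorted(bad)}; expected {sorted(valid)}")
    grid = np.unique(t)
    cif: Dict[int, np.ndarray] = {}
    var: Dict[int, np.ndarray] = {}
    for cause in causes:
        if not np.any(s == cause):
            cif[cause] = np.zeros_like(grid)
            var[cause] = np.zeros_like(grid)
            continue
        ajf = AalenJohansenFitter(calculate_variance=True, seed=0)
        ajf.fit(t, s, event_of_interest=cause)
        col = ajf.cumulative_density_.columns[0]
        est = ajf.cumulative_density_[col]
        idx = np.searchsorted(est.index.to_numpy(float), grid, side="right") - 1
        vals = est.to_numpy()
        cif[cause] = np.where(idx >= 0, vals[np.clip(idx, 0, None)], 0.0)
        v = ajf.variance_.to_numpy().ravel()
        var[cause] = np.where(idx >= 0, v[np.clip(idx, 0, None)], 0.0)
    return CumulativeIncidence(times=grid, cif=cif, variance=var, n=len(t))


# --- Gray's test -------------------------------------------------------------

def _left_limit_steps(step_times, step_values, at, start):
    """Evaluate a right-continuous step function's left limit at ``at``."""
    idx = np.searchsorted(step_times, at, side="left") - 1
    out = np.where(idx >= 0, step_values[np.clip(idx, 0, None)], start)
    return out


def _km_cif_left(t, s, cause, at):
    """(S(at-), F_cause(at-)) for one group, all-cause KM and AJ CIF."""
    order = np.argsort(t, kind="stable")
    t, s = t[order], s[order]
    ev_times = np.unique(t[s > 0])
    n = len(t)
    S = 1.0
    F = 0.0
    sv = np.empty(len(ev_times))
    fv = np.empty(len(ev_times))
    for i, u in enumerate(ev_times):
        y = n - np.searchsorted(t, u, side="left")
        d_all = np.sum((t == u) & (s > 0))
        d_c = np.sum((t == u) & (s == cause))
        F += S * d_c / y
        S *= 1 - d_all / y
        sv[i] = S
        fv[i] = F
    return (
        _left_limit_steps(ev_times, sv, at, 1.0),
        _left_limit_steps(ev_times, fv, at, 0.0),
    )


@dataclass(frozen=True)
class GrayTestResult:
    statistic: float
    p_value: float
    df: int
    score: float
    variance: float


def gray_test(groups: Sequence[tuple], cause: int = 1) -> GrayTestResult:
    """Two-sample test for equality of cumulative-incidence functions.

    The score compares the subdistribution-hazard increments between the two
    groups using Gray's modified risk sets
    R_k(t) = Y_k(t) (1 - F_k(t-)) / S_k(t-), which keep subjects who failed
    from the competing cause in the risk set with their estimated
    representation; the unit weight corresponds to rho = 0.  The variance is
    the hypergeometric (log-rank-type) form on those modified risk sets, and
    the statistic is referred to chi-square with 1 df.
    """
    if len(groups) != 2:
        raise ValueError("Gray's test is implemented for exactly two groups")
    ts, ss = [], []
    for t, s in groups:
        t = np.asarray(t, float)
        s = np.asarray(s).astype(int)
        if len(t) == 0:
            raise ValueError("a group has no observations")
        ts.append(t)
        ss.append(s)
    all_t = np.concatenate(ts)
    all_s = np.concatenate(ss)
    etimes = np.unique(all_t[all_s == cause])
    if len(etimes) == 0:
        return GrayTestResult(0.0, 1.0, 1, 0.0, 0.0)

    R = []
    d_cause = []
    for t, s in zip(ts, ss):
        srt = np.sort(t)
        y = len(t) - np.searchsorted(srt, etimes, side="left")
        s_minus, f_minus = _km_cif_left(t, s, cause, etimes)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(s_minus > 0, y * (1 - f_minus) / s_minus, 0.0)
        R.append(r)
        ct = np.sort(t[s == cause])
        d = np.searchsorted(ct, etimes, side="right") - np.searchsorted(
            ct, etimes, side="left"
        )
        d_cause.append(d.astype(float))

    r1, r2 = R
    d1, d2 = d_cause
    rtot = r1 + r2
    dtot = d1 + d2
    ok = rtot > 0
    a = np.divide(r1, rtot, out=np.zeros_like(r1), where=ok)
    score = float(np.sum(d1[ok] - a[ok] * dtot[ok]))
    corr = np.where(rtot > 1, (rtot - dtot) / np.maximum(rtot - 1, 1e-300), 1.0)
    variance = float(np.sum((a * (1 - a) * dtot * corr)[ok]))
    if variance <= 0:
        return GrayTestResult(0.0, 1.0, 1, score, variance)
    stat = score**2 / variance
    return GrayTestResult(stat, float(chi2.sf(stat, 1)), 1, score, variance)
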