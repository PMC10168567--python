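import numpy as np
import pytest
from scipy.stats import chi2

from epiphany.time_to_event import (
    aalen_johansen,
    gray_test,
    km_fit,
    logrank_test,
)


# --- Kaplan-Meier -----------------------------------------------------------

def test_km_no_censoring_empirical_steps():
    sc = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
    assert np.allclose(sc.survival, [0.75, 0.5, 0.25, 0.0])
    assert sc.median == 2.0


def test_km_hand_computed_with_censoring():
    """Six subjects, one censored at t=3: product-limit values by hand."""
    sc = km_fit([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 1, 1])
    assert np.allclose(sc.times, [1, 2, 4, 5, 6])
    assert np.allclose(sc.survival, [5 / 6, 4 / 6, 4 / 9, 2 / 9, 0.0])
    assert sc.median == 4.0
    # Greenwood at t=2 (no censoring yet) equals the binomial variance
    s = 4 / 6
    assert sc.variance[1] == pytest.approx(s * s * (1 / 30 + 1 / 20))


def test_km_all_censored_median_flagged():
    sc = km_fit([1, 2, 3], [0, 0, 0])
    assert np.isnan(sc.median)


def test_km_exponential_median_recovery():
    rng = np.random.default_rng(3)
    median = 8.0
    t = rng.exponential(median / np.log(2), 20_000)
    cens = rng.uniform(0, 40, 20_000)
    sc = km_fit(np.minimum(t, cens), t <= cens)
    assert sc.median == pytest.approx(median, rel=0.02)


def test_km_invariant_to_row_order():
    rng = np.random.default_rng(5)
    t = rng.exponential(5, 300)
    e = rng.random(300) < 0.7
    sc1 = km_fit(t, e)
    perm = rng.permutation(300)
    sc2 = km_fit(t[perm], e[perm])
    assert np.allclose(sc1.survival, sc2.survival)
    assert np.allclose(sc1.times, sc2.times)


def _km_survival_at(t, e, probe):
    """Independent product-limit evaluator for the bootstrap oracle."""
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    s = 1.0
    i = 0
    n = len(t)
    while i < n and t[i] <= probe:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += e[j]
            j += 1
        if d:
            s *= 1 - d / (n - i)
        i = j
    return s


def test_km_greenwood_close_to_bootstrap():
    rng = np.random.default_rng(11)
    n = 500
    t = rng.exponential(5, n)
    cens = rng.uniform(0, 15, n)
    ft, ev = np.minimum(t, cens), (t <= cens).astype(int)
    sc = km_fit(ft, ev)
    t_probe = sc.times[np.searchsorted(sc.times, 4.0)]
    assert _km_survival_at(ft, ev, t_probe) == pytest.approx(sc.at(t_probe), abs=1e-12)
    boots = []
    for _ in range(2000):
        idx = rng.integers(0, n, n)
        boots.append(_km_survival_at(ft[idx], ev[idx], t_probe))
    var_boot = np.var(boots, ddof=1)
    var_gw = sc.variance[np.searchsorted(sc.times, t_probe)]
    assert var_gw == pytest.approx(var_boot, rel=0.15)


# --- log-rank ----------------------------------------------------------------

def test_logrank_identical_groups():
    t = np.arange(1, 21, dtype=float)
    e = np.ones(20, int)
    r = logrank_test([(t, e), (t, e)])
    assert r.statistic == pytest.approx(0.0, abs=1e-9)


def test_logrank_power_under_proportional_hazards():
    rng = np.random.default_rng(13)
    rejections = 0
    for _ in range(100):
        t1 = rng.exponential(10, 1000)
        t2 = rng.exponential(5, 1000)  # hazard ratio 2
        r = logrank_test([(t1, np.ones(1000)), (t2, np.ones(1000))])
        rejections += r.p_value < 0.05
    assert rejections > 99 * 0.99 or rejections == 100


def _fast_logrank_stat(t, e, g):
    """Two-sample log-rank chi-square, for the permutation loop."""
    etimes = np.unique(t[e > 0])
    srt_all = np.sort(t)
    srt_1 = np.sort(t[g])
    y_all = len(t) - np.searchsorted(srt_all, etimes, side="left")
    y_1 = g.sum() - np.searchsorted(srt_1, etimes, side="left")
    ct_all = np.sort(t[e > 0])
    ct_1 = np.sort(t[g & (e > 0)])
    d_all = np.searchsorted(ct_all, etimes, "right") - np.searchsorted(ct_all, etimes, "left")
    d_1 = np.searchsorted(ct_1, etimes, "right") - np.searchsorted(ct_1, etimes, "left")
    exp = y_1 * d_all / y_all
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(
            y_all > 1,
            d_all * (y_1 / y_all) * (1 - y_1 / y_all) * (y_all - d_all) / (y_all - 1),
            0.0,
        )
    u = np.sum(d_1 - exp)
    vv = np.sum(v)
    return u * u / vv if vv > 0 else 0.0


def test_logrank_against_permutation_oracle():
    rng = np.random.default_rng(17)
    n = 60
    t = rng.exponential(np.where(np.arange(n) < n // 2, 6.0, 4.0))
    e = rng.random(n) < 0.9
    g = np.arange(n) < n // 2
    obs = logrank_test([(t[g], e[g]), (t[~g], e[~g])])
    # the fast permutation statistic must reproduce the package statistic
    assert _fast_logrank_stat(t, e, g) == pytest.approx(obs.statistic, rel=1e-9)
    cnt = 0
    B = 5000
    for _ in range(B):
        gp = rng.permutation(g)
        cnt += _fast_logrank_stat(t, e, gp) >= obs.statistic
    p_perm = (cnt + 1) / (B + 1)
    assert abs(obs.p_value - p_perm) < 0.02


# --- Aalen-Johansen ----------------------------------------------------------

def test_aj_reduces_to_one_minus_km_without_competing_events():
    rng = np.random.default_rng(19)
    t = rng.exponential(5, 400)
    cens = rng.uniform(0, 12, 400)
    ft = np.minimum(t, cens)
    st = np.where(t <= cens, 1, 0)
    ci = aalen_johansen(ft, st)
    sc = km_fit(ft, st == 1)
    for probe in (1.0, 3.0, 6.0):
        assert ci.at(probe, 1) == pytest.approx(1 - sc.at(probe), abs=1e-9)
    assert np.all(ci.cif[2] == 0.0)


def test_aj_constant_hazards_closed_form():
    """CIF_1(t) = lam1/(lam1+lam2) * (1 - exp(-(lam1+lam2) t))."""
    rng = np.random.default_rng(23)
    lam1, lam2, n = 0.10, 0.05, 50_000
    t = rng.exponential(1 / (lam1 + lam2), n)
    cause = np.where(rng.random(n) < lam1 / (lam1 + lam2), 1, 2)
    ci = aalen_johansen(t, cause)
    expect = lam1 / (lam1 + lam2) * (1 - np.exp(-(lam1 + lam2) * 6.0))
    assert ci.at(6.0, 1) == pytest.approx(expect, abs=0.005)


def test_aj_all_competing_cause():
    t = np.array([1.0, 2.0, 3.0])
    ci = aalen_johansen(t, np.array([2, 2, 2]))
    assert np.all(ci.cif[1] == 0.0)


def test_aj_monotone_and_bounded(default_cohort):
    f = default_cohort.frame
    codes = {"censored": 0, "bleeding": 1, "death_without_bleeding": 2}
    ci = aalen_johansen(
        f["bleed_time"].astype(float), f["bleed_status"].map(codes)
    )
    for cause in (1, 2):
        assert np.all(np.diff(ci.cif[cause]) >= -1e-12)
    assert np.all(ci.cif[1] + ci.cif[2] <= 1 + 1e-9)


def test_aj_unknown_status_code_rejected():
    with pytest.raises(ValueError, match="status"):
        aalen_johansen([1.0, 2.0], [1, 7])


def test_aj_invariant_to_row_order():
    rng = np.random.default_rng(29)
    t = rng.exponential(4, 200)
    s = rng.integers(0, 3, 200)
    a = aalen_johansen(t, s)
    perm = rng.permutation(200)
    b = aalen_johansen(t[perm], s[perm])
    assert np.allclose(a.cif[1], b.cif[1])


# --- Gray's test -------------------------------------------------------------

def _competing_sample(rng, n, hr=1.0):
    g = np.repeat([0, 1], n // 2)
    te = rng.exponential(1 / (0.08 * np.where(g == 1, hr, 1.0)))
    td = rng.exponential(1 / 0.06, n)
    t = np.minimum(te, td)
    c = np.where(te <= td, 1, 2)
    cens = rng.exponential(1 / 0.04, n)
    ft = np.minimum(t, cens)
    st = np.where(t <= cens, c, 0)
    return ft, st, g


def test_gray_identical_groups():
    t = np.arange(1.0, 31.0)
    s = np.tile([1, 2, 0], 10)
    r = gray_test([(t, s), (t, s)])
    assert r.p_value > 0.99


def test_gray_reference_implementation_value():
    """Frozen cross-check: the same fixture evaluated with the R `cmprsk`
    reference implementation gives stat 6.6141, p 0.010117 for cause 1 and
    stat 2.3855, p 0.12247 for cause 2."""
    rng = np.random.default_rng(20171014)
    ft, st, g = _competing_sample(rng, 120, hr=2.0)
    r1 = gray_test([(ft[g == 0], st[g == 0]), (ft[g == 1], st[g == 1])], cause=1)
    r2 = gray_test([(ft[g == 0], st[g == 0]), (ft[g == 1], st[g == 1])], cause=2)
    assert r1.statistic == pytest.approx(6.6141, rel=0.05)
    assert r1.p_value == pytest.approx(0.010117, abs=0.002)
    assert r2.p_value == pytest.approx(0.12247, abs=0.01)


def test_gray_null_calibration():
    """Type-I error at the nominal 5% level under equal subdistribution
    hazards (500 replicates, n=200)."""
    rng = np.random.default_rng(31)
    rejections = 0
    reps = 500
    for _ in range(reps):
        ft, st, g = _competing_sample(rng, 200, hr=1.0)
        r = gray_test([(ft[g == 0], st[g == 0]), (ft[g == 1], st[g == 1])])
        rejections += r.p_value < 0.05
    assert 0.02 <= rejections / reps <= 0.08


def test_gray_empty_group_rejected():
    with pytest.raises(ValueError, match="no observations"):
        gray_test([(np.array([]), np.array([])), (np.array([1.0]), np.array([1]))])
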