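"""Bayesian estimation of per-stratum event probabilities.

The event probability θ of each risk stratum (15-day serious complications,
30-day mortality) is estimated with the Bayesian alternative to the binomial
test: a Jeffreys Beta(½, ½) prior updated with k events in n episodes gives a
Beta(k + ½, n − k + ½) posterior.  The module provides both interval
conventions in circulation for such posteriors — the highest-density interval
(narrowest region with the nominal mass) and the equal-tailed quantile
interval — because the two differ visibly for skewed posteriors at small k.
Pairwise comparisons between strata are posterior exceedance probabilities
P(θ_A > θ_B) for independent posteriors, and the sample-size helper inverts a
posterior-precision (assurance) criterion by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, optimize
from scipy.stats import beta as beta_dist

from ._util import DEFAULT_SEED


@dataclass(frozen=True)
class BetaPosterior:
    """Jeffreys-updated binomial posterior Beta(k + ½, n − k + ½)."""

    k: int
    n: int

    def __post_init__(self):
        if self.n < 0 or self.k < 0 or self.k > self.n:
            raise ValueError(f"invalid counts k={self.k}, n={self.n}")

    @property
    def a(self) -> float:
        return self.k + 0.5

    @property
    def b(self) -> float:
        return self.n - self.k + 0.5

    @property
    def raw(self) -> float:
        """The raw proportion k/n (the point estimate the report tables print)."""
        if self.n == 0:
            return float("nan")
        return self.k / self.n

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def mode(self) -> Optional[float]:
        """Interior mode, or the boundary (0 or 1) when a ≤ 1 or b ≤ 1."""
        if self.a > 1 and self.b > 1:
            return (self.a - 1) / (self.a + self.b - 2)
        if self.a <= 1 and self.b <= 1:
            return None  # U-shaped prior: both boundaries are modes
        return 0.0 if self.a <= 1 else 1.0

    def dist(self):
        return beta_dist(self.a, self.b)


@dataclass(frozen=True)
class CredibleInterval:
    lower: float
    upper: float
    mass: float
    kind: str  # 'hdi' | 'central'

    def __post_init__(self):
        assert 0.0 <= self.lower < self.upper <= 1.0

    @property
    def width(self) -> float:
        return self.upper - self.lower


def jeffreys_posterior(k: int, n: int) -> BetaPosterior:
    """Posterior for k events in n trials under the Jeffreys prior."""
    return BetaPosterior(int(k), int(n))


def hdi(post: BetaPosterior, mass: float = 0.95) -> CredibleInterval:
    """Narrowest interval containing ``mass`` posterior probability.

    Found by minimizing upper − lower over the lower-tail probability
    p ∈ [0, 1 − mass] with bounded scalar optimization (tolerance 1e-10 in p).
    For boundary-mode posteriors (a ≤ 1 or b ≤ 1) the interval is one-sided
    from the corresponding boundary.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    d = post.dist()
    if post.a <= 1 and post.b > 1:
        return CredibleInterval(0.0, float(d.ppf(mass)), mass, "hdi")
    if post.b <= 1 and post.a > 1:
        return CredibleInterval(float(d.ppf(1 - mass)), 1.0, mass, "hdi")

    def width(p):
        return d.ppf(p + mass) - d.ppf(p)

    res = optimize.minimize_scalar(
        width, bounds=(0.0, 1.0 - mass), method="bounded", options={"xatol": 1e-10}
    )
    lo = float(d.ppf(res.x))
    hi = float(d.ppf(res.x + mass))
    return CredibleInterval(lo, hi, mass, "hdi")


def central_interval(post: BetaPosterior, mass: float = 0.95) -> CredibleInterval:
    """Equal-tailed quantile interval with ``mass`` posterior probability."""
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    tail = (1 - mass) / 2
    d = post.dist()
    return CredibleInterval(float(d.ppf(tail)), float(d.ppf(1 - tail)), mass, "central")


def prob_greater(
    post_a: BetaPosterior,
    post_b: BetaPosterior,
    method: str = "quadrature",
    seed: int = DEFAULT_SEED,
    n_draws: int = 1_000_000,
) -> float:
    """P(θ_A > θ_B) for independent posteriors.

    Quadrature evaluates ∫ f_A(x) F_B(x) dx to absolute tolerance 1e-9; the
    Monte-Carlo path draws from both posteriors and must agree with the
    quadrature within sampling error.
    """
    if method == "quadrature":
        da, db = post_a.dist(), post_b.dist()
        value, _ = integrate.quad(
            lambda x: da.pdf(x) * db.cdf(x), 0.0, 1.0, epsabs=1e-9, limit=500
        )
        return float(min(max(value, 0.0), 1.0))
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        xa = rng.beta(post_a.a, post_a.b, n_draws)
        xb = rng.beta(post_b.a, post_b.b, n_draws)
        return float(np.mean(xa > xb))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class AssuranceResult:
    """Smallest stratum size meeting a posterior-precision criterion.

    Reported under both circulating readings of an "interval width < w"
    precision rule: ``full_width`` takes w as the entire interval width,
    ``half_width`` takes w as the half-width (entire width < 2w).  ``total``
    scales a stratum size up by the assumed stratum fraction.
    """

    theta: float
    width: float
    mass: float
    assurance: float
    stratum_fraction: float
    n_stratum_full_width: Optional[int]
    n_stratum_half_width: Optional[int]
    total_full_width: Optional[int]
    total_half_width: Optional[int]
    attainment_curve: dict  # n -> attainment prob under the full-width reading


def _attainment(n: int, theta: float, width: float, mass: float, rng, n_reps: int) -> float:
    """P(HDI width < width) when k ~ Binomial(n, theta), by simulation.

    The HDI width depends on k only, so widths are computed once per distinct
    simulated k.
    """
    ks = rng.binomial(n, theta, n_reps)
    uniq, counts = np.unique(ks, return_counts=True)
    ok = 0
    for k, c in zip(uniq, counts):
        w = hdi(jeffreys_posterior(int(k), n), mass).width
        if w < width:
            ok += c
    return ok / n_reps


def assurance_sample_size(
    theta: float,
    width: float,
    mass: float = 0.95,
    assurance: float = 0.90,
    stratum_fraction: float = 1 / 3,
    seed: int = DEFAULT_SEED,
    n_reps: int = 10_000,
    n_max: int = 20_000,
) -> AssuranceResult:
    """Invert the precision rule by seeded Monte-Carlo over candidate sizes.

    Returns the smallest stratum n whose attainment probability reaches
    ``assurance`` for each width reading, or None when ``n_max`` is not
    enough; the attainment curve over probed sizes is returned for diagnosis.
    """
    for p, name in [(theta, "theta"), (mass, "mass"), (assurance, "assurance"),
                    (stratum_fraction, "stratum_fraction")]:
        if not 0 < p < 1:
            raise ValueError(f"{name} must be in (0, 1)")
    if width <= 0:
        raise ValueError("width must be positive")

    curve: dict = {}

    def solve(target_width):
        if target_width >= 1.0:
            return 1
        rng = np.random.default_rng(seed)
        lo, hi = 1, None
        n = 4
        while n <= n_max:
            att = _attainment(n, theta, target_width, mass, rng, n_reps)
            if target_width == width:
                curve[n] = att
            if att >= assurance:
                hi = n
                break
            lo = n
            n *= 2
        if hi is None:
            return None
        while hi - lo > 1:
            mid = (lo + hi) // 2
            att = _attainment(mid, theta, target_width, mass, rng, n_reps)
            if target_width == width:
                curve[mid] = att
            if att >= assurance:
                hi = mid
            else:
                lo = mid
        return hi

    n_full = solve(width)
    n_half = solve(2 * width)
    ceil_div = lambda n: int(np.ceil(n / stratum_fraction)) if n else None
    return AssuranceResult(
        theta=theta,
        width=width,
        mass=mass,
        assurance=assurance,
        stratum_fraction=stratum_fraction,
        n_stratum_full_width=n_full,
        n_stratum_half_width=n_half,
        total_full_width=ceil_div(n_full),
        total_half_width=ceil_div(n_half),
        attainment_curve=curve,
    )
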