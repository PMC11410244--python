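"""Closed-form results and experimental-design calculators.

Covers the diffusion-approximation fixation probability of a mutant in a
well-mixed serial-passage population, the head-to-head estimate of the
competitive advantage, Wilson score intervals for fixation proportions,
t-based intervals for mean fixation/extinction times, and the minimal
number of experimental replicates for two arms to show a *significant*
difference in the stringent sense of non-overlapping confidence
intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "ConfidenceInterval",
    "fixation_probability_wm",
    "competitive_advantage",
    "effective_advantage",
    "wilson_interval",
    "mean_time_interval",
    "min_replicates_proportions",
    "min_replicates_means",
]

#: Cap on the replicate-number searches.
MAX_REPLICATE_SEARCH = 10**6

#: Extra replicate numbers over which disjointness must persist before a
#: minimal n is accepted (guards rare non-monotonic edge cases).
STABILITY_WINDOW = 20


@dataclass(frozen=True)
class ConfidenceInterval:
    """Two-sided confidence interval ``[lower, upper]`` at ``level``."""

    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")

    def overlaps(self, other: "ConfidenceInterval") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def fixation_probability_wm(n_mut: float, B: float, st: float) -> float:
    """Fixation probability of n mutants in a well-mixed serial-passage deme.

    Diffusion approximation (valid for B >> 1 and |st| << 1, and a good
    guide well beyond)::

        rho = (1 - e^{-2 n st}) / (1 - e^{-2 B st})

    with the continuous extension ``n / B`` at st = 0.  The effective
    advantage st plays the role of the selection coefficient of the
    classical Wright-Fisher result.
    """
    if not 0 <= n_mut <= B:
        raise ValueError(f"initial mutant count {n_mut} must lie in [0, B = {B}]")
    if st == 0.0:
        return n_mut / B
    num = -math.expm1(-2.0 * n_mut * st)
    den = -math.expm1(-2.0 * B * st)
    return num / den


def competitive_advantage(W0: float, W1: float, M0: float, M1: float) -> float:
    """Fitness ratio 1 + s from a head-to-head growth competition.

    With wild-types growing ``W0 -> W1`` and mutants ``M0 -> M1`` over
    the same interval, the ratio of exponential growth rates is
    ``log(M1/M0) / log(W1/W0) = 1 + s``.
    """
    if min(W0, W1, M0, M1) <= 0:
        raise ValueError("all abundances must be positive")
    if W1 <= W0 or M1 <= M0:
        raise ValueError("both types must grow (W1 > W0 and M1 > M0)")
    return math.log(M1 / M0) / math.log(W1 / W0)


def effective_advantage(s: float, t: float) -> float:
    """Effective fitness advantage st from relative advantage s and growth time t."""
    if t <= 0:
        raise ValueError("growth time t must be positive")
    return s * t


def wilson_interval(p_hat: float, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Wilson score interval for a binomial proportion.

    ``(p + z^2/2n +/- z sqrt(p(1-p)/n + z^2/4n^2)) / (1 + z^2/n)`` with z
    the two-sided standard-normal quantile.  Better average coverage than
    the Wald interval, especially for proportions near 0 or 1.
    """
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    z = stats.norm.ppf(0.5 + level / 2.0)
    z2n = z * z / n
    center = p_hat + z2n / 2.0
    radius = z * math.sqrt(p_hat * (1.0 - p_hat) / n + z2n / (4.0 * n))
    denom = 1.0 + z2n
    lower = min(max((center - radius) / denom, 0.0), 1.0)
    upper = min(max((center + radius) / denom, 0.0), 1.0)
    return ConfidenceInterval(lower, upper, level)


def mean_time_interval(tau_hat: float, sigma_hat: float, n: int, level: float = 0.95) -> ConfidenceInterval:
    """t-based interval ``tau_hat +/- t_(n-1) sigma_hat / sqrt(n)`` for a mean time.

    ``sigma_hat`` is the sample standard deviation of the per-replicate
    times; ``t_(n-1)`` the two-sided Student quantile with n - 1 degrees
    of freedom.
    """
    if n < 2:
        raise ValueError("n must be at least 2 for a t interval")
    if sigma_hat < 0:
        raise ValueError("sigma_hat must be non-negative")
    tq = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    half = tq * sigma_hat / math.sqrt(n)
    return ConfidenceInterval(tau_hat - half, tau_hat + half, level)


def _min_n_disjoint(interval_at, n_start: int) -> int:
    """Smallest n >= n_start with stably disjoint intervals.

    ``interval_at(n)`` returns the two arms' intervals at replicate
    number n; disjointness must hold for n .. n + STABILITY_WINDOW.
    """
    n = n_start
    while n <= MAX_REPLICATE_SEARCH:
        if all(
            not interval_at(k)[0].overlaps(interval_at(k)[1])
            for k in range(n, n + STABILITY_WINDOW + 1)
        ):
            return n
        n += 1
    raise RuntimeError(
        f"no replicate number up to {MAX_REPLICATE_SEARCH} gives disjoint intervals"
    )


def min_replicates_proportions(p1: float, p2: float, level: float = 0.95) -> int:
    """Minimal replicates for disjoint Wilson intervals around p1 and p2.

    The smallest n such that the two arms' Wilson intervals (same n in
    both) are disjoint, and remain so for the next 20 values of n.
    """
    if p1 == p2:
        raise ValueError("p1 and p2 must differ; equal proportions never separate")
    return _min_n_disjoint(
        lambda n: (wilson_interval(p1, n, level), wilson_interval(p2, n, level)), 1
    )


def min_replicates_means(
    tau1: float, sigma1: float, tau2: float, sigma2: float, level: float = 0.95
) -> int:
    """Minimal replicates for disjoint t-based mean-time intervals.

    Uses the same replicate number in both arms; requires the two means
    to differ.
    """
    if tau1 == tau2:
        raise ValueError("tau1 and tau2 must differ; equal means never separate")
    return _min_n_disjoint(
        lambda n: (
            mean_time_interval(tau1, sigma1, n, level),
            mean_time_interval(tau2, sigma2, n, level),
        ),
        2,
    )
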