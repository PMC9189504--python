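"""Closed-form probability helpers and genetic-distance unit conversions.

These back the sanity arguments of the scan (how likely are k simultaneous
false positives, how likely is a tail count of artifact windows) and the
conversion between physical distance and population-scaled recombination
distance rho = 4*Ne*r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats as _stats

__all__ = [
    "RhoScaling",
    "binomial_tail_at_least",
    "independent_product",
    "physical_to_rho",
]


@dataclass(frozen=True)
class RhoScaling:
    """Mapping between physical distance and rho units.

    One rho unit is defined as ``cm_per_rho`` centimorgans; physical distance
    converts through the local sex-averaged map density ``cm_per_mb``.  The
    defaults (1 cM/Mb, 0.01 cM per rho) make one rho unit correspond to 10 kb.
    """

    cm_per_mb: float = 1.0
    cm_per_rho: float = 0.01
    bp_per_rho: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0 or self.cm_per_rho <= 0:
            raise ValueError("scaling constants must be positive")
        object.__setattr__(
            self, "bp_per_rho", self.cm_per_rho / self.cm_per_mb * 1e6
        )


def binomial_tail_at_least(n: int, p: float, k: int) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p).

    Uses the regularized incomplete beta function (via scipy's survival
    function), which is numerically stable for tail probabilities far below
    machine-epsilon-times-n, the regime these artifact arguments live in.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    n = int(n)
    k = int(k)
    if n < 0 or not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(_stats.binom.sf(k - 1, n, p))


def independent_product(rate: float, k: int) -> float:
    """Probability that k independent events each of probability ``rate``
    all occur: rate ** k."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    k = int(k)
    if k < 0:
        raise ValueError(f"k must be a non-negative integer, got {k}")
    return float(rate) ** k


def physical_to_rho(distance_bp: float, scaling: RhoScaling | None = None) -> float:
    """Convert a physical distance in bp to rho units under ``scaling``."""
    if distance_bp < 0:
        raise ValueError(f"distance must be non-negative, got {distance_bp}")
    if scaling is None:
        scaling = RhoScaling()
    return float(distance_bp) / scaling.bp_per_rho
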