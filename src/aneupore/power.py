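"""Poisson error/power design for chromosome-level copy-number detection.

At ultra-low coverage the number of uniquely assigned (UA) reads landing on a
chromosome (or any genomic span) is well approximated by a Poisson count with
mean ``lam`` proportional to the span's mappable share of the genome.  Whether
a relative copy-number change of factor ``f`` (1.5 for a full trisomy against
a diploid baseline, 1.3 for a 30% change) is detectable from that count is
then a question about Poisson tails:

* type-I error -- a normal region's count exceeding the decision boundary
  placed at ``f * lam``: ``P(X > ceil(f * lam))`` with ``X ~ Poisson(lam)``;
* type-II error -- a truly changed region's count falling back below the
  normal expectation: ``P(X' < lam)`` with ``X' ~ Poisson(f * lam)``.

Both boundary conventions (strict upper tail beyond ``ceil(f*lam)``; strictly
below ``lam``) are part of this module's contract and are echoed in the JSON
metadata the CLI emits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

#: Effective genome span (bp) used for read-depth planning when none is given:
#: a uniquely-alignable human genome proxy of 3,100 Mb.
DEFAULT_GENOME_SPAN = 3_100_000_000

TYPE1_CONVENTION = "P(X > ceil(effect_factor*lam)) with X ~ Poisson(lam)"
TYPE2_CONVENTION = "P(X' <= ceil(lam)-1) with X' ~ Poisson(effect_factor*lam)"


def poisson_sf(k: int, lam: float) -> float:
    """Upper-tail probability ``P(X > k)`` for ``X ~ Poisson(lam)``.

    ``k = -1`` returns 1 (the full mass).  Uses the regularized
    incomplete-gamma evaluation from scipy, which complements the lower tail
    to better than 1e-12 for all ``lam`` used here.
    """
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if k < -1:
        raise ValueError(f"k must be >= -1, got {k}")
    if k == -1:
        return 1.0
    return float(stats.poisson.sf(k, lam))


def type1_error(lam: float, effect_factor: float = 1.5) -> float:
    """Probability of falsely detecting a copy-number *gain* of ``effect_factor``.

    A normal region with Poisson mean ``lam`` is falsely flagged when its
    count lands strictly beyond the boundary ``t = ceil(effect_factor * lam)``.
    """
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if effect_factor <= 1:
        raise ValueError(
            f"effect_factor must exceed 1 for a gain, got {effect_factor}"
        )
    boundary = math.ceil(effect_factor * lam)
    return poisson_sf(boundary, lam)


def type2_error(lam: float, effect_factor: float) -> float:
    """Probability of *missing* a true copy-number gain of ``effect_factor``.

    The changed region's count ``X' ~ Poisson(effect_factor * lam)`` is missed
    when it falls strictly below the normal expectation ``lam``, i.e.
    ``P(X' <= ceil(lam) - 1)``.
    """
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if effect_factor <= 1:
        raise ValueError(
            f"effect_factor must exceed 1 for a gain, got {effect_factor}"
        )
    boundary = math.ceil(lam) - 1
    if boundary < 0:
        return 0.0
    return float(stats.poisson.cdf(boundary, effect_factor * lam))


def expected_region_reads(
    n_reads: int, region_span: float, genome_span: float = DEFAULT_GENOME_SPAN
) -> float:
    """Expected UA reads on a region: ``n_reads * region_span / genome_span``."""
    if region_span <= 0 or genome_span <= 0:
        raise ValueError("spans must be positive")
    if region_span > genome_span:
        raise ValueError(
            f"region_span {region_span} exceeds genome_span {genome_span}"
        )
    return n_reads * region_span / genome_span


def min_reads_for_region(
    region_span: float,
    genome_span: float = DEFAULT_GENOME_SPAN,
    effect_factor: float = 1.5,
    alpha_max: float = 0.001,
    beta_max: float = 0.05,
    n_cap: int = 100_000_000,
) -> int:
    """Smallest total read count meeting both error bounds for a region.

    Searches for the least ``n`` such that, at ``lam = expected_region_reads``,
    ``type1_error <= alpha_max`` and ``type2_error <= beta_max``.  Both errors
    decrease in ``lam`` so the feasible set is (up to the integer boundary
    jitter of the Poisson tails) an upper ray; an exponential bracket followed
    by bisection plus a final downward scan handles the jitter exactly.
    """
    if not (0 < alpha_max < 1 and 0 < beta_max < 1):
        raise ValueError("error bounds must be in (0, 1)")

    def ok(n: int) -> bool:
        lam = expected_region_reads(n, region_span, genome_span)
        if lam <= 0:
            return False
        return (
            type1_error(lam, effect_factor) <= alpha_max
            and type2_error(lam, effect_factor) <= beta_max
        )

    hi = 1
    while not ok(hi):
        hi *= 2
        if hi > n_cap:
            lam = expected_region_reads(n_cap, region_span, genome_span)
            a = type1_error(lam, effect_factor)
            b = type2_error(lam, effect_factor)
            binding = "alpha" if a > alpha_max else "beta"
            raise ValueError(
                f"no n <= {n_cap} satisfies the bounds "
                f"(binding constraint: {binding}; at n={n_cap} "
                f"alpha={a:.3g}, beta={b:.3g})"
            )
    lo = hi // 2
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    # Poisson boundaries are integer-valued in lam, so feasibility is not
    # perfectly monotone in n; walk down through any feasible pocket.
    while hi > 1 and ok(hi - 1):
        hi -= 1
    return hi


@dataclass
class PoissonDesign:
    """A λ / effect-size design point with its type-I/II errors."""

    lam: float
    effect_factor: float = 1.5
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        self.alpha = type1_error(self.lam, self.effect_factor)
        self.beta = type2_error(self.lam, self.effect_factor)

    def to_dict(self) -> dict:
        return {
            "lam": self.lam,
            "effect_factor": self.effect_factor,
            "type1_boundary": math.ceil(self.effect_factor * self.lam),
            "alpha": self.alpha,
            "beta": self.beta,
            "type1_convention": TYPE1_CONVENTION,
            "type2_convention": TYPE2_CONVENTION,
        }
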