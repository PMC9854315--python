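"""Exact inferential primitives: Wilson score intervals and Fisher tests.

Proportions of flagged participants are summarised with 95% Wilson score
intervals (well-behaved for binomial data at small n and extreme
proportions, with no continuity correction) and compared between pools by
two-sided Fisher exact tests (the sum-of-at-most-as-probable-tables
convention), which suit unequal and small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import DomainError


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (display convention for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for k successes out of n, on the 0-100 scale.

    Returns unrounded (lo, hi) percentages; use :func:`round_half_up` for
    display at one decimal.
    """
    if n < 1:
        raise DomainError("wilson_ci requires n >= 1")
    if not 0 <= k <= n:
        raise DomainError("wilson_ci requires 0 <= k <= n")
    if not 0.0 < conf < 1.0:
        raise DomainError("conf must lie in (0, 1)")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    pct = 100.0 * k / n
    # the score interval contains p-hat by construction; clamp float noise
    return (min(max(float(lo) * 100.0, 0.0), pct),
            max(min(float(hi) * 100.0, 100.0), pct))


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    p is the sum of hypergeometric probabilities, at fixed margins, of all
    tables at most as probable as the observed one.  Requires non-negative
    integer counts and strictly positive row and column margins.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise DomainError("fisher_exact requires non-negative integer counts")
    a, b, c, d = (int(x) for x in counts)
    if min(a + b, c + d, a + c, b + d) == 0:
        raise DomainError("fisher_exact requires positive margins")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class ProportionSummary:
    """A proportion with its Wilson interval, on the 0-100 scale.

    ``pct``, ``wilson_lo`` and ``wilson_hi`` are unrounded; ``formatted``
    applies the one-decimal half-up display convention.
    """

    k: int
    n: int
    pct: float
    wilson_lo: float
    wilson_hi: float
    conf: float = 0.95

    @classmethod
    def from_counts(cls, k: int, n: int, conf: float = 0.95) -> "ProportionSummary":
        lo, hi = wilson_ci(k, n, conf)
        return cls(k=k, n=n, pct=100.0 * k / n, wilson_lo=lo, wilson_hi=hi,
                   conf=conf)

    def formatted(self) -> str:
        return (f"{round_half_up(self.pct):.1f}% "
                f"[{round_half_up(self.wilson_lo):.1f}, "
                f"{round_half_up(self.wilson_hi):.1f}]")
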