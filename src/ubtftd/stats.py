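"""Exact 2x2 contingency statistics and multiple-testing correction.

The two-sided Fisher exact test uses the probability-mass rule: the p-value
is the total hypergeometric probability of all tables sharing the observed
margins whose probability does not exceed that of the observed table.  For
table totals <= 200 all arithmetic is exact integer arithmetic (binomial
coefficients), so printed 3-decimal p-values are stable; larger tables fall
back to log-space factorials.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache

import numpy as np

from .errors import ConfigError

__all__ = [
    "ContingencyTable",
    "fisher_exact_two_sided",
    "benjamini_hochberg",
    "odds_ratio",
]

_EXACT_TOTAL_LIMIT = 200
#: relative slack when comparing table probabilities in the two-sided rule
#: (only relevant on the log-space fallback path; exact path uses integers)
_REL_EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows are groups, columns are outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigError("contingency counts must be non-negative")
        if self.total < 1:
            raise ConfigError("contingency table must contain at least one count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True if any margin is zero (p = 1 by convention)."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@lru_cache(maxsize=200_000)
def _comb(n: int, k: int) -> int:
    return math.comb(n, k)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value under the probability-mass rule."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.degenerate:
        return 1.0
    r1, c1, n = a + b, a + c, table.total
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    if n <= _EXACT_TOTAL_LIMIT:
        weights = [_comb(r1, k) * _comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
        obs = weights[a - lo]
        numer = sum(w for w in weights if w <= obs)
        return numer / _comb(n, c1)
    # log-space fallback for large tables
    lg = math.lgamma
    def logw(k: int) -> float:
        return (
            lg(r1 + 1) - lg(k + 1) - lg(r1 - k + 1)
            + lg(n - r1 + 1) - lg(c1 - k + 1) - lg(n - r1 - (c1 - k) + 1)
        )
    logws = np.array([logw(k) for k in range(lo, hi + 1)])
    log_obs = logws[a - lo]
    mask = logws <= log_obs + _REL_EPS
    log_total = lg(n + 1) - lg(c1 + 1) - lg(n - c1 + 1)
    p = float(np.exp(logws[mask] - log_total).sum())
    return min(p, 1.0)


def odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio ad/bc (inf when bc = 0)."""
    if table.b * table.c == 0:
        return math.inf
    return (table.a * table.d) / (table.b * table.c)


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()
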