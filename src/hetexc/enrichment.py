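"""Two-group comparisons: Fisher's exact test and fold enrichment.

Group comparisons throughout the screen (region groups, allele-balance
fail rates, population distribution of candidates, inheritance-pattern
enrichment) reduce to a 2x2 contingency table; effect size is reported as
Fold Enrichment — the ratio of the two row proportions — alongside the
two-sided Fisher exact P value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import InvalidInputError

__all__ = ["ContingencyTable2x2", "EnrichmentResult", "fisher_two_sided", "fold_enrichment"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts; rows are groups, columns are outcome / not-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidInputError("contingency cells must be non-negative")
        if self.a + self.b == 0 and self.c + self.d == 0:
            raise InvalidInputError("at least one row total must be positive")

    @property
    def degenerate(self) -> bool:
        """True if a row or column margin is zero (P = 1 by convention)."""
        return 0 in (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class EnrichmentResult:
    fold_enrichment: float
    p_value: float
    proportions: tuple[float, float]
    degenerate: bool = False


def fisher_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact P: the sum of hypergeometric probabilities of
    all tables (same margins) no more probable than the observed one."""
    if table.degenerate:
        return 1.0
    return float(
        stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")[1]
    )


def fold_enrichment(table: ContingencyTable2x2) -> EnrichmentResult:
    """Ratio of row proportions a/(a+b) over c/(c+d), with its Fisher P."""
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise InvalidInputError("fold enrichment requires both row totals > 0")
    p1 = table.a / (table.a + table.b)
    p2 = table.c / (table.c + table.d)
    if p2 == 0:
        fe = math.inf if p1 > 0 else math.nan
    else:
        fe = p1 / p2
    return EnrichmentResult(
        fold_enrichment=fe,
        p_value=fisher_two_sided(table),
        proportions=(p1, p2),
        degenerate=table.degenerate,
    )
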