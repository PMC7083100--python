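"""Allele-balance (AB) histograms and the genotype-error filters built on them.

Allele balance is the fraction of sequencing reads supporting the minor
allele in a heterozygous call; a true heterozygote is expected near 0.5.
Population databases summarise AB per variant as carrier counts in 20 bins
of width 0.05 spanning [0, 1].  Two quality signals derive from the
histogram:

* **VCNAB** — the percentage of Variant Carriers with Normal (0.40–0.55)
  Allele Balance.  Low VCNAB marks variants whose heterozygous calls are
  likely genotyping artefacts.
* **High-AB reclassification** — heterozygous calls with AB above 0.8 are
  plausibly misclassified homozygotes; moving them from het to hom-alt and
  re-running the exact HWE test removes heterozygote-excess signals caused
  by such miscalls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError
from .hwe import GenotypeCounts

__all__ = [
    "ABHistogram",
    "ReclassificationOutcome",
    "vcnab",
    "high_ab_carrier_count",
    "reclassify_high_ab",
]

N_BINS = 20
BIN_WIDTH = 0.05
#: Half-open normal-AB window [0.40, 0.55): bins 8, 9 and 10.
NORMAL_AB_BINS = (8, 9, 10)


@dataclass(frozen=True)
class ABHistogram:
    """Carrier counts (or percentages) in 20 half-open AB bins [k·0.05, (k+1)·0.05)."""

    carriers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.carriers, dtype=float)
        if arr.shape != (N_BINS,):
            raise InvalidInputError(f"expected {N_BINS} AB bins, got shape {arr.shape}")
        if (arr < 0).any():
            raise InvalidInputError("AB bin counts must be non-negative")
        object.__setattr__(self, "carriers", arr)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, N_BINS + 1)

    @property
    def total(self) -> float:
        return float(self.carriers.sum())

    @classmethod
    def from_string(cls, text: str) -> "ABHistogram":
        """Parse a 20-value list; accepts comma- or pipe-separated values
        (the latter is the gnomAD ``ab_hist_alt_bin_freq`` convention)."""
        sep = "|" if "|" in text else ","
        values = [float(v) for v in text.strip().split(sep)]
        if len(values) != N_BINS:
            raise InvalidInputError(f"expected {N_BINS} AB values, got {len(values)}")
        return cls(np.array(values))

    def to_string(self) -> str:
        return ",".join(format(v, "g") for v in self.carriers)

    @classmethod
    def empty(cls) -> "ABHistogram":
        return cls(np.zeros(N_BINS))


@dataclass(frozen=True)
class ReclassificationOutcome:
    """Result of moving high-AB heterozygotes to the homozygous class."""

    n_reclassified_total: int
    per_population_moves: dict[str, int]
    adjusted_counts: dict[str, GenotypeCounts]
    capped: bool = False
    scaled: bool = False


def vcnab(hist: ABHistogram) -> float:
    """Percentage of heterozygous carriers with AB in [0.40, 0.55)."""
    total = hist.total
    if total <= 0:
        raise UndefinedMetricError("VCNAB is undefined for a histogram with no carriers")
    normal = float(hist.carriers[list(NORMAL_AB_BINS)].sum())
    return 100.0 * normal / total


def high_ab_carrier_count(hist: ABHistogram, threshold: float = 0.8) -> int:
    """Total carriers in bins at or above ``threshold`` (a 0.05 bin edge)."""
    k = threshold / BIN_WIDTH
    if abs(k - round(k)) > 1e-9 or not 0 <= round(k) <= N_BINS:
        raise InvalidInputError(f"threshold {threshold} is not a 0.05 bin edge")
    first_bin = int(round(k))
    return int(round(float(hist.carriers[first_bin:].sum())))


def _largest_remainder(weights: dict[str, float], k: int) -> dict[str, int]:
    """Apportion integer k across keys proportionally to ``weights`` using
    largest-remainder rounding; ties go to the lexically first key."""
    total = sum(weights.values())
    if total <= 0 or k <= 0:
        return {key: 0 for key in weights}
    quotas = {key: k * w / total for key, w in weights.items()}
    moves = {key: int(np.floor(q)) for key, q in quotas.items()}
    leftover = k - sum(moves.values())
    by_remainder = sorted(weights, key=lambda key: (-(quotas[key] - moves[key]), key))
    for key in by_remainder[:leftover]:
        moves[key] += 1
    return moves


def reclassify_high_ab(
    per_pop_counts: dict[str, GenotypeCounts],
    hist: ABHistogram,
    threshold: float = 0.8,
) -> ReclassificationOutcome:
    """Move heterozygotes with AB above ``threshold`` into the hom-alt class.

    The histogram describes the overall carrier pool; per-population AB is
    typically unavailable, so the reclassified individuals are apportioned
    across populations proportionally to each population's heterozygote
    count (largest-remainder rounding, deterministic lexical tie-break).
    Each moved individual contributes one extra alternate allele.

    If the histogram total disagrees with the summed het counts, the
    reclassified count is scaled proportionally and a warning is issued.
    """
    k = high_ab_carrier_count(hist, threshold)
    het_by_pop = {pop: c.n_het for pop, c in per_pop_counts.items()}
    total_het = sum(het_by_pop.values())
    scaled = False
    capped = False
    if k > 0 and hist.total > 0 and abs(hist.total - total_het) > 0.5:
        k = int(round(k * total_het / hist.total))
        scaled = True
        warnings.warn(
            "AB histogram total differs from summed heterozygote counts; "
            "reclassified count scaled proportionally",
            stacklevel=2,
        )
    if k > total_het:
        k = total_het
        capped = True

    moves = _largest_remainder(het_by_pop, k)
    # Largest-remainder can never exceed a population's het count when
    # k <= total_het, but guard anyway so counts stay non-negative.
    for pop, mv in moves.items():
        if mv > het_by_pop[pop]:  # pragma: no cover - defensive
            moves[pop] = het_by_pop[pop]
    adjusted = {
        pop: GenotypeCounts(c.n_hom_ref, c.n_het - moves[pop], c.n_hom_alt + moves[pop])
        for pop, c in per_pop_counts.items()
    }
    return ReclassificationOutcome(
        n_reclassified_total=sum(moves.values()),
        per_population_moves=moves,
        adjusted_counts=adjusted,
        capped=capped,
        scaled=scaled,
    )
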