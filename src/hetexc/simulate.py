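"""Synthetic panel-structured variant datasets with known ground truth.

The generator emulates the statistical structure the screen assumes: a
seven-population panel with per-population genotype counts drawn from
class-specific genotype frequencies, a 20-bin allele-balance histogram for
the pooled heterozygous carriers, and BED regions for variants planted in
segmental duplications.  Variant classes:

``hwe``
    Genotypes multinomial(p^2, 2pq, q^2) — the exact-test null.
``het_excess``
    Heterozygote frequency inflated to 2pq(1+d); both homozygote classes
    are shrunk by a common factor so frequencies stay on the simplex.
    This mimics selection against homozygotes / heterozygote advantage.
``het_deficit``
    Inbreeding-style deficit with coefficient F:
    (p^2 + Fpq, 2pq(1-F), q^2 + Fpq).
``ab_error``
    HWE genotypes in which a fraction ``e`` of hom-alt individuals is
    mis-genotyped as heterozygous; their allele balance concentrates above
    0.8 (discretised Beta(18, 3)) while true heterozygotes follow
    Beta(30, 30) centred on 0.5.
``segdup``
    Heterozygote-excess variants planted inside emitted segmental-
    duplication intervals (the region filter's true positives).

All randomness flows from ``SimulationSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .allele_balance import ABHistogram, N_BINS
from .errors import InvalidInputError
from .hwe import GenotypeCounts
from .variant_io import GNOMAD_V2_PANEL, PopulationData, PopulationPanel, VariantRecord

__all__ = ["SimulationSpec", "generate_dataset", "hbb_fixture", "genotype_frequencies"]

#: AB distribution of genuine heterozygous calls (mean 0.5, sd ~0.064).
TRUE_HET_AB = (30.0, 30.0)
#: AB distribution of hom-alt calls mis-labelled het (mean ~0.86).
ERROR_AB = (18.0, 3.0)

CLASSES = ("hwe", "het_excess", "het_deficit", "ab_error", "segdup")


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic dataset."""

    panel: PopulationPanel = GNOMAD_V2_PANEL
    panel_scale: float = 1.0
    n_variants: dict[str, int] = field(
        default_factory=lambda: {"hwe": 200, "het_excess": 100, "het_deficit": 100,
                                 "ab_error": 100, "segdup": 50}
    )
    af_min: float = 0.001
    af_max: float = 0.05
    excess_d: float = 1.5   # relative heterozygote inflation
    deficit_F: float = 0.1  # inbreeding coefficient
    error_e: float = 0.5    # fraction of hom-alt mis-genotyped as het
    seed: int = 0

    def effective_panel(self) -> PopulationPanel:
        return self.panel if self.panel_scale == 1.0 else self.panel.scaled(self.panel_scale)


def genotype_frequencies(variant_class: str, q: float, spec: SimulationSpec) -> np.ndarray:
    """Genotype frequency vector (hom_ref, het, hom_alt) for one class."""
    p = 1.0 - q
    if variant_class in ("hwe", "ab_error"):
        return np.array([p * p, 2 * p * q, q * q])
    if variant_class in ("het_excess", "segdup"):
        het = 2 * p * q * (1.0 + spec.excess_d)
        hom_total = p * p + q * q
        if het >= 1.0 or hom_total <= 0.0:
            raise InvalidInputError(
                f"infeasible het_excess parameters: q={q}, d={spec.excess_d}"
            )
        s = (1.0 - het) / hom_total  # common shrink keeps the simplex
        return np.array([p * p * s, het, q * q * s])
    if variant_class == "het_deficit":
        F = spec.deficit_F
        return np.array([p * p + F * p * q, 2 * p * q * (1.0 - F), q * q + F * p * q])
    raise InvalidInputError(f"unknown variant class {variant_class!r}")


def _discretized_beta_hist(rng: np.random.Generator, count: int, ab_params) -> np.ndarray:
    """Multinomial draw of ``count`` carriers over 20 AB bins with Beta mass."""
    edges = np.linspace(0.0, 1.0, N_BINS + 1)
    cdf = stats.beta.cdf(edges, *ab_params)
    probs = np.diff(cdf)
    probs /= probs.sum()
    return rng.multinomial(count, probs).astype(float)


def generate_dataset(
    spec: SimulationSpec,
) -> tuple[list[VariantRecord], pd.DataFrame, dict[str, list[tuple[str, int, int]]]]:
    """Generate variant records, truth labels and region BED intervals.

    Returns
    -------
    records
        One :class:`VariantRecord` per variant, with counts in every panel
        population, full coverage, PASS flags and an AB histogram.
    truth
        DataFrame with columns ``variant``, ``class`` and ``q`` (the
        latent alternate allele frequency each population was drawn at).
    beds
        ``{"segmental_duplication": [...], "tandem_repeat": [...]}`` with
        0-based half-open intervals enclosing the planted variants.
    """
    rng = np.random.default_rng(spec.seed)
    panel = spec.effective_panel()
    records: list[VariantRecord] = []
    truth_rows = []
    beds: dict[str, list[tuple[str, int, int]]] = {
        "segmental_duplication": [],
        "tandem_repeat": [],
    }

    idx = 0
    for variant_class in CLASSES:
        for _ in range(spec.n_variants.get(variant_class, 0)):
            idx += 1
            chrom = str(1 + (idx - 1) % 22)
            pos = 10_000 * idx + 500
            q = float(
                np.exp(rng.uniform(np.log(spec.af_min), np.log(spec.af_max)))
            )
            freqs = genotype_frequencies(variant_class, q, spec)

            per_pop: dict[str, PopulationData] = {}
            coverage: dict[str, float] = {}
            n_error_het = 0
            for pop in panel.populations:
                n = panel.sizes[pop]
                hr, het, ha = (int(x) for x in rng.multinomial(n, freqs))
                if variant_class == "ab_error" and ha > 0:
                    moved = int(rng.binomial(ha, spec.error_e))
                    het += moved
                    ha -= moved
                    n_error_het += moved
                per_pop[pop] = PopulationData(GenotypeCounts(hr, het, ha), 0.99)
                coverage[pop] = 0.99

            total_het = sum(d.counts.n_het for d in per_pop.values())
            clean_het = total_het - n_error_het
            hist = _discretized_beta_hist(rng, clean_het, TRUE_HET_AB)
            if n_error_het:
                hist += _discretized_beta_hist(rng, n_error_het, ERROR_AB)

            in_segdup = variant_class == "segdup"
            if in_segdup:
                beds["segmental_duplication"].append((chrom, pos - 50, pos + 50))

            rec = VariantRecord(
                chrom=chrom,
                pos=pos,
                ref="A",
                alt="T",
                gene=f"GENE{idx:05d}",
                is_canonical=True,
                consequence="missense_variant",
                per_population=per_pop,
                pass_exome=True,
                pass_genome=True,
                in_exome=True,
                in_genome=False,
                ab_hist=ABHistogram(hist),
                coverage=coverage,
                in_segdup=in_segdup,
            )
            records.append(rec)
            truth_rows.append({"variant": rec.key, "class": variant_class, "q": q})

    truth = pd.DataFrame(truth_rows, columns=["variant", "class", "q"])
    return records, truth, beds


def write_beds(beds: dict[str, list[tuple[str, int, int]]], out_dir: str) -> dict[str, str]:
    """Write the generated region intervals as BED files; returns paths."""
    import os

    paths = {}
    for label, intervals in beds.items():
        path = os.path.join(out_dir, f"{label}.bed")
        with open(path, "w") as fh:
            for chrom, start, end in intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        paths[label] = path
    return paths


def hbb_fixture() -> VariantRecord:
    """A sickle-cell-trait-like variant: ~9% heterozygous carriers in the
    African/African American population (counts 11365 / 1113 / 4), a small
    carrier-only presence elsewhere, a clean allele-balance profile, and
    location outside repeat regions.  Useful as a known true positive for
    the candidate-selection pipeline."""
    panel = GNOMAD_V2_PANEL
    afr = GenotypeCounts(11365, 1113, 4)
    per_pop = {"AFR": PopulationData(afr, 0.99)}
    # Carrier-only trickle in two other populations: heterozygote counts
    # marginally above the 2pq·n expectation, consistent with excess.
    for pop, het in (("NFE", 12), ("AMR", 20)):
        n = panel.sizes[pop]
        per_pop[pop] = PopulationData(GenotypeCounts(n - het, het, 0), 0.99)
    coverage = {pop: 0.99 for pop in panel.populations}

    total_het = sum(d.counts.n_het for d in per_pop.values())
    # Deterministic clean histogram: all carriers inside [0.30, 0.70), about
    # two thirds in the normal [0.40, 0.55) window, nothing above 0.8.
    hist = np.zeros(N_BINS)
    hist[6] = 0.06 * total_het   # [0.30, 0.35)
    hist[7] = 0.12 * total_het   # [0.35, 0.40)
    hist[8] = 0.20 * total_het   # [0.40, 0.45)
    hist[9] = 0.24 * total_het   # [0.45, 0.50)
    hist[10] = 0.22 * total_het  # [0.50, 0.55)
    hist[11] = 0.10 * total_het  # [0.55, 0.60)
    hist[12] = 0.06 * total_het  # [0.60, 0.65)
    hist[13] = 0.0               # remainder left at zero
    return VariantRecord(
        chrom="11",
        pos=5_248_232,
        ref="T",
        alt="A",
        gene="HBB",
        is_canonical=True,
        consequence="missense_variant",
        per_population=per_pop,
        pass_exome=True,
        pass_genome=True,
        in_exome=True,
        in_genome=True,
        ab_hist=ABHistogram(hist),
        coverage=coverage,
        annotations={"clinvar": "Pathogenic", "inheritance": "AR"},
    )
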