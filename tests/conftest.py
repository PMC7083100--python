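"""Shared fixtures: exact enumeration oracles and hand-built variant records."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from hetexc import (
    ABHistogram,
    GenotypeCounts,
    PopulationData,
    VariantRecord,
    GNOMAD_V2_PANEL,
)


def enumerate_het_distribution(n: int, m: int) -> dict[int, Fraction]:
    """Brute-force conditional null of the heterozygote count: enumerate all
    genotype configurations (hom_ref, het, hom_alt) compatible with n
    individuals and m minor alleles, weighted by the multinomial coefficient
    n! / (hom_ref! het! hom_alt!) times 2**het.  Exact rational arithmetic,
    fully independent of the ratio-recurrence implementation."""
    weights: dict[int, int] = {}
    for het in range(m % 2, min(m, 2 * n - m) + 1, 2):
        hom_alt = (m - het) // 2
        hom_ref = n - het - hom_alt
        if hom_ref < 0:
            continue
        weights[het] = comb(n, het) * comb(n - het, hom_alt) * 2**het
    total = sum(weights.values())
    return {het: Fraction(w, total) for het, w in weights.items()}


def enumerate_midp(n: int, m: int, observed_het: int) -> tuple[Fraction, Fraction]:
    """(mid_p, p_two_sided) from the exact enumeration oracle."""
    dist = enumerate_het_distribution(n, m)
    p_obs = dist[observed_het]
    p_two = sum(p for p in dist.values() if p <= p_obs)
    return p_two - Fraction(1, 2) * p_obs, p_two


def make_record(
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    het_by_pop=None,
    hom_alt_by_pop=None,
    n_by_pop=None,
    site_n=10_000,
    coverage=0.99,
    low_coverage_pop=None,
    ab_hist=None,
    **kwargs,
):
    """Variant record with per-site genotyped count ``site_n`` per population.

    ``het_by_pop`` maps population code -> heterozygote count; populations
    not listed are absent from the record (but still carry coverage)."""
    het_by_pop = het_by_pop or {}
    hom_alt_by_pop = hom_alt_by_pop or {}
    n_by_pop = n_by_pop or {}
    per_pop = {}
    cov_map = {}
    for pop in GNOMAD_V2_PANEL.populations:
        cov_map[pop] = 0.5 if pop == low_coverage_pop else coverage
        het = het_by_pop.get(pop, 0)
        ha = hom_alt_by_pop.get(pop, 0)
        if het + ha == 0:
            continue
        n = n_by_pop.get(pop, site_n)
        per_pop[pop] = PopulationData(GenotypeCounts(n - het - ha, het, ha), cov_map[pop])
    if ab_hist is None:
        total_het = sum(d.counts.n_het for d in per_pop.values())
        carriers = np.zeros(20)
        carriers[9] = total_het  # all carriers at AB ~0.475: clean profile
        ab_hist = ABHistogram(carriers)
    defaults = dict(
        gene="GENE", is_canonical=True, consequence="missense_variant",
        pass_exome=True, pass_genome=True, in_exome=True, in_genome=False,
    )
    defaults.update(kwargs)
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, per_population=per_pop,
        ab_hist=ab_hist, coverage=cov_map, **defaults,
    )


@pytest.fixture
def initial_filter_fixture():
    """Eight records engineered so tier one rejects exactly one per stage
    and one survives.  Stage order: canonical, autosomal, consequence,
    AF > 0.001, coverage, PASS, alt-allele collision."""
    records = [
        make_record(pos=1_000, het_by_pop={"NFE": 100}, is_canonical=False),
        make_record(chrom="X", pos=2_000, het_by_pop={"NFE": 100}),
        make_record(pos=3_000, het_by_pop={"NFE": 100}, consequence="intron_variant"),
        # AF exactly 0.001 in its only population: fails AF > 0.001, and its
        # allele also trips the collision rule for the sibling at pos 7000.
        make_record(pos=7_000, alt="G", het_by_pop={"NFE": 20}, site_n=10_000),
        make_record(pos=5_000, het_by_pop={"NFE": 100}, low_coverage_pop="FIN"),
        make_record(pos=6_000, het_by_pop={"NFE": 100}, pass_exome=False),
        make_record(pos=7_000, alt="T", het_by_pop={"NFE": 100}),  # collision victim
        make_record(pos=8_000, het_by_pop={"NFE": 100}),           # survivor
    ]
    return records
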