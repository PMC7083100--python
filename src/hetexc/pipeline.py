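"""Two-tier variant selection for heterozygote-excess screening.

Tier one (:func:`initial_filter`) restricts a raw variant table to
well-genotyped, protein-coding, autosomal biallelic sites suitable for the
exact HWE test.  Tier two (:func:`candidate_selection`) keeps variants
whose heterozygote excess is statistically significant, consistent across
populations, outside error-prone repeat regions, supported by a clean
allele-balance profile — and that remain significant after heterozygotes
with allele balance above 0.8 are conservatively reclassified as
homozygotes.

Each tier returns a :class:`FilterReport` with per-stage survivor counts
and, per rejected variant, the first stage that failed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .allele_balance import reclassify_high_ab, vcnab
from .errors import UndefinedMetricError
from .hwe import GenotypeCounts, HWETestResult, hwe_exact_midp
from .variant_io import (
    GNOMAD_V2_PANEL,
    PopulationPanel,
    VariantRecord,
    is_autosome,
    normalize_chrom,
)

__all__ = [
    "VEP_PROTEIN_CODING_CONSEQUENCES",
    "FilterConfig",
    "FilterReport",
    "initial_filter",
    "candidate_selection",
    "scan_population_deviations",
    "summarize_deviations",
    "population_tests",
]

#: VEP consequence terms counted as protein coding for tier-one filter (iii).
VEP_PROTEIN_CODING_CONSEQUENCES = frozenset(
    {
        "transcript_ablation",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "stop_gained",
        "frameshift_variant",
        "stop_lost",
        "start_lost",
        "transcript_amplification",
        "inframe_insertion",
        "inframe_deletion",
        "missense_variant",
        "protein_altering_variant",
        "splice_region_variant",
        "incomplete_terminal_codon_variant",
        "start_retained_variant",
        "stop_retained_variant",
        "synonymous_variant",
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for both filtering tiers (defaults are the screen's
    operating point)."""

    af_min: float = 0.001       # tier 1: AF must exceed this in >= 1 population
    af_max: float = 0.05        # tier 2: AF must not exceed this in any population
    coverage_min: float = 0.80  # fraction of individuals covered, every population
    vcnab_min: float = 50.0     # percent of carriers with AB in [0.40, 0.55)
    ab_hom_threshold: float = 0.8   # AB above which a het call is re-labelled hom
    alpha: float = 0.05         # mid-P significance level
    alt_collision_af: float = 0.001  # max summed AF of sibling alt alleles
    consequence_whitelist: frozenset[str] = VEP_PROTEIN_CODING_CONSEQUENCES
    autosomes_only: bool = True
    #: if True, tier-2 rule (iii) also blocks variants absent/untestable in
    #: some population; the default treats those populations as vacuously
    #: consistent (a variant private to one population can still pass).
    strict_all_pops: bool = False
    #: if True, AF filters are re-evaluated on the reclassified counts too;
    #: by default only the HWE re-test uses adjusted counts.
    reapply_af_after_reclassification: bool = False


@dataclass
class FilterReport:
    """Per-stage funnel counts plus each variant's first failing stage."""

    stages: list[dict] = field(default_factory=list)
    rejections: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, input_count: int, surviving_count: int) -> None:
        self.stages.append(
            {"stage": name, "input_count": input_count, "surviving_count": surviving_count}
        )

    def reject(self, key: str, reason: str) -> None:
        self.rejections.setdefault(key, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "input_count", "surviving_count"])

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def population_tests(
    record: VariantRecord, alpha: float = 0.05
) -> dict[str, HWETestResult | None]:
    """Exact HWE test per population; ``None`` marks untestable entries
    (no minor alleles in that population)."""
    out: dict[str, HWETestResult | None] = {}
    for pop, data in record.per_population.items():
        if data.counts.minor_allele_count == 0:
            out[pop] = None
        else:
            out[pop] = hwe_exact_midp(data.counts, alpha=alpha)
    return out


def _run_stages(records, stages, report: FilterReport):
    survivors = list(records)
    for name, predicate in stages:
        n_in = len(survivors)
        kept = []
        for rec in survivors:
            ok, reason = predicate(rec)
            if ok:
                kept.append(rec)
            else:
                report.reject(rec.key, reason or name)
        report.add_stage(name, n_in, len(kept))
        survivors = kept
    return survivors


# ---------------------------------------------------------------------------
# tier one
# ---------------------------------------------------------------------------

def initial_filter(
    records: list[VariantRecord],
    config: FilterConfig = FilterConfig(),
    panel: PopulationPanel = GNOMAD_V2_PANEL,
) -> tuple[list[VariantRecord], FilterReport]:
    """Tier-one selection of testable variants.

    Stages, in order: canonical transcript; autosomal; protein-coding
    consequence; AF above ``af_min`` in at least one population; site
    coverage at least ``coverage_min`` in every panel population; PASS in
    every dataset the variant appears in; and no frequent sibling
    alternate allele at the same position (summed AF of the other alt
    alleles below ``alt_collision_af`` in every population).
    """
    report = FilterReport()

    # Sibling alt-allele AFs, grouped by normalised position.
    by_pos: dict[tuple[str, int], list[VariantRecord]] = {}
    for rec in records:
        by_pos.setdefault((normalize_chrom(rec.chrom), rec.pos), []).append(rec)

    def canonical(rec):
        return rec.is_canonical, "not_canonical"

    def autosome(rec):
        if not config.autosomes_only:
            return True, None
        return is_autosome(rec.chrom), "not_autosomal"

    def consequence(rec):
        return rec.consequence in config.consequence_whitelist, (
            f"consequence_not_whitelisted:{rec.consequence or '<missing>'}"
        )

    def af_min(rec):
        ok = any(rec.af(pop) > config.af_min for pop in rec.per_population)
        return ok, f"af_not_above_{config.af_min}_in_any_population"

    def coverage(rec):
        for pop in panel.populations:
            cov = rec.coverage.get(pop)
            if cov is None:
                data = rec.per_population.get(pop)
                if data is None:
                    return False, f"missing_field:cov_{pop}"
                cov = data.coverage_fraction
            if cov < config.coverage_min:
                return False, f"low_coverage:{pop}"
        return True, None

    def pass_quality(rec):
        if rec.in_exome and not rec.pass_exome:
            return False, "non_pass:exome"
        if rec.in_genome and not rec.pass_genome:
            return False, "non_pass:genome"
        return True, None

    def alt_collision(rec):
        siblings = [
            other
            for other in by_pos[(normalize_chrom(rec.chrom), rec.pos)]
            if other.key != rec.key
        ]
        for pop in panel.populations:
            other_af = sum(o.af(pop) for o in siblings)
            if other_af >= config.alt_collision_af:
                return False, f"alt_allele_collision:{pop}"
        return True, None

    stages = [
        ("canonical_transcript", canonical),
        ("autosomal", autosome),
        ("protein_coding_consequence", consequence),
        ("af_above_min", af_min),
        ("coverage", coverage),
        ("pass_quality", pass_quality),
        ("alt_allele_collision", alt_collision),
    ]
    survivors = _run_stages(records, stages, report)
    return survivors, report


# ---------------------------------------------------------------------------
# tier two
# ---------------------------------------------------------------------------

def _sig_excess_somewhere(tests: dict[str, HWETestResult | None]) -> bool:
    return any(
        t is not None and t.significant and t.direction == "excess" for t in tests.values()
    )


def _excess_everywhere(
    tests: dict[str, HWETestResult | None],
    panel: PopulationPanel,
    strict: bool,
) -> bool:
    if strict:
        for pop in panel.populations:
            t = tests.get(pop)
            if t is None or t.direction != "excess":
                return False
        return True
    return all(t is None or t.direction == "excess" for t in tests.values())


def candidate_selection(
    records: list[VariantRecord],
    config: FilterConfig = FilterConfig(),
    panel: PopulationPanel = GNOMAD_V2_PANEL,
) -> tuple[list[VariantRecord], FilterReport]:
    """Tier-two selection of candidate heterozygote-advantage variants.

    Stages: AF at most ``af_max`` in every population; significant
    (mid-P <= alpha) heterozygote excess in at least one population;
    heterozygote excess (not necessarily significant) in every population
    where the test is defined; located outside segmental duplications and
    tandem repeats; VCNAB at least ``vcnab_min`` percent; and finally the
    allele-balance re-test — heterozygous carriers with AB above
    ``ab_hom_threshold`` are re-labelled homozygous (apportioned across
    populations proportionally to het counts) and the excess rules are
    re-checked on the adjusted counts.
    """
    report = FilterReport()
    tests_cache: dict[str, dict[str, HWETestResult | None]] = {}

    def tests_for(rec: VariantRecord) -> dict[str, HWETestResult | None]:
        if rec.key not in tests_cache:
            tests_cache[rec.key] = population_tests(rec, alpha=config.alpha)
        return tests_cache[rec.key]

    def af_max(rec):
        for pop in rec.per_population:
            if rec.af(pop) > config.af_max:
                return False, f"af_above_max:{pop}"
        return True, None

    def sig_excess(rec):
        return _sig_excess_somewhere(tests_for(rec)), "no_significant_excess"

    def all_excess(rec):
        ok = _excess_everywhere(tests_for(rec), panel, config.strict_all_pops)
        return ok, "not_excess_in_all_populations"

    def outside_regions(rec):
        if rec.in_segdup:
            return False, "in_segmental_duplication"
        if rec.in_repeat:
            return False, "in_tandem_repeat"
        return True, None

    def vcnab_ok(rec):
        try:
            value = vcnab(rec.ab_hist)
        except UndefinedMetricError:
            return False, "vcnab_undefined"
        return value >= config.vcnab_min, f"vcnab_below_{config.vcnab_min:g}"

    def ab_retest(rec):
        per_pop = {pop: d.counts for pop, d in rec.per_population.items()}
        outcome = reclassify_high_ab(per_pop, rec.ab_hist, config.ab_hom_threshold)
        if outcome.n_reclassified_total == 0:
            return True, None
        adjusted_tests: dict[str, HWETestResult | None] = {}
        for pop, counts in outcome.adjusted_counts.items():
            if counts.minor_allele_count == 0:
                adjusted_tests[pop] = None
            else:
                adjusted_tests[pop] = hwe_exact_midp(counts, alpha=config.alpha)
        if not _sig_excess_somewhere(adjusted_tests):
            return False, "not_significant_after_ab_reclassification"
        if not _excess_everywhere(adjusted_tests, panel, config.strict_all_pops):
            return False, "not_excess_everywhere_after_ab_reclassification"
        if config.reapply_af_after_reclassification:
            for pop, counts in outcome.adjusted_counts.items():
                if counts.alt_af > config.af_max:
                    return False, f"af_above_max_after_reclassification:{pop}"
        return True, None

    stages = [
        ("af_below_max", af_max),
        ("significant_excess_somewhere", sig_excess),
        ("excess_in_all_populations", all_excess),
        ("outside_segdup_and_repeats", outside_regions),
        ("vcnab", vcnab_ok),
        ("ab_reclassification_retest", ab_retest),
    ]
    survivors = _run_stages(records, stages, report)
    return survivors, report


# ---------------------------------------------------------------------------
# population-wide deviation scan
# ---------------------------------------------------------------------------

def scan_population_deviations(
    records: list[VariantRecord],
    config: FilterConfig = FilterConfig(),
    panel: PopulationPanel = GNOMAD_V2_PANEL,
) -> pd.DataFrame:
    """Exact HWE test for every (variant, population) pair with at least
    one minor allele.  Untestable pairs are recorded with
    ``testable=False`` and excluded from percentage denominators."""
    rows = []
    for rec in records:
        for pop, data in rec.per_population.items():
            if pop not in panel.sizes:
                continue
            counts = data.counts
            if counts.minor_allele_count == 0:
                rows.append(
                    {
                        "variant": rec.key,
                        "population": pop,
                        "n": counts.n,
                        "observed_het": counts.n_het,
                        "expected_het": counts.expected_het(),
                        "mid_p": float("nan"),
                        "direction": "untestable",
                        "significant": False,
                        "testable": False,
                    }
                )
                continue
            t = hwe_exact_midp(counts, alpha=config.alpha)
            rows.append(
                {
                    "variant": rec.key,
                    "population": pop,
                    "n": counts.n,
                    "observed_het": t.observed_het,
                    "expected_het": t.expected_het_uncond,
                    "mid_p": t.mid_p,
                    "direction": t.direction,
                    "significant": t.significant,
                    "testable": True,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variant", "population", "n", "observed_het", "expected_het",
            "mid_p", "direction", "significant", "testable",
        ],
    )


def summarize_deviations(scan: pd.DataFrame) -> pd.DataFrame:
    """Per-population percentages of tested variants significantly
    deviating towards heterozygote deficiency / excess."""
    rows = []
    for pop, grp in scan.groupby("population"):
        tested = grp[grp["testable"]]
        n = len(tested)
        sig = tested[tested["significant"]]
        rows.append(
            {
                "population": pop,
                "n_tested": n,
                "pct_het_deficit": 100.0 * (sig["direction"] == "deficit").sum() / n if n else 0.0,
                "pct_het_excess": 100.0 * (sig["direction"] == "excess").sum() / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["population", "n_tested", "pct_het_deficit", "pct_het_excess"])
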