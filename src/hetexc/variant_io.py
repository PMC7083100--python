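"""Reading and writing variant tables, BED region files and region annotation.

Two input formats are supported:

* a **canonical TSV** with one row per biallelic variant, per-population
  genotype counts (``hom_ref_<POP>``, ``het_<POP>``, ``hom_alt_<POP>``),
  per-population coverage fractions (``cov_<POP>``), quality flags and a
  20-value allele-balance histogram;
* a **gnomAD-style VCF** whose INFO fields carry ``AC_<pop>``,
  ``AN_<pop>``, ``nhomalt_<pop>`` and optionally
  ``ab_hist_alt_bin_freq``.  Genotype counts are reconstructed as
  ``hom_alt = nhomalt``, ``het = AC − 2·nhomalt``,
  ``hom_ref = AN/2 − het − hom_alt``.

Coordinates follow the usual conventions: variant positions are 1-based
(VCF), BED intervals are 0-based half-open, so a 1-based position P falls
inside (start, end) iff start < P <= end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from intervaltree import IntervalTree

from .allele_balance import ABHistogram
from .errors import FormatError, InvalidInputError, MalformedIntervalError
from .hwe import GenotypeCounts

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationData",
    "VariantRecord",
    "RegionIndex",
    "PopulationPanel",
    "GNOMAD_V2_PANEL",
    "read_variant_table",
    "write_variant_table",
    "load_bed",
    "annotate_regions",
]

_AUTOSOMES = {str(i) for i in range(1, 23)}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so 'chr1' and '1' compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in _AUTOSOMES


@dataclass(frozen=True)
class PopulationPanel:
    """Population codes and their sizes in individuals."""

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        for pop, n in self.sizes.items():
            if n <= 0:
                raise InvalidInputError(f"population {pop} has non-positive size {n}")

    @property
    def populations(self) -> list[str]:
        return sorted(self.sizes)

    @property
    def total(self) -> int:
        return sum(self.sizes.values())

    def scaled(self, factor: float) -> "PopulationPanel":
        """Panel with every size multiplied by ``factor`` (min size 2)."""
        return PopulationPanel({p: max(2, int(round(n * factor))) for p, n in self.sizes.items()})


#: The seven-population exome panel (137,842 individuals) used throughout.
GNOMAD_V2_PANEL = PopulationPanel(
    {
        "NFE": 64603,
        "AMR": 17720,
        "SAS": 15308,
        "FIN": 12562,
        "AFR": 12487,
        "EAS": 9977,
        "ASJ": 5185,
    }
)


@dataclass(frozen=True)
class PopulationData:
    counts: GenotypeCounts
    coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise InvalidInputError(
                f"coverage_fraction must lie in [0, 1], got {self.coverage_fraction}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with per-population counts and QC annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    is_canonical: bool = True
    consequence: str = ""
    per_population: dict[str, PopulationData] = field(default_factory=dict)
    pass_exome: bool = True
    pass_genome: bool = True
    in_exome: bool = True
    in_genome: bool = False
    ab_hist: ABHistogram = field(default_factory=ABHistogram.empty)
    #: site coverage fraction per panel population, including populations
    #: where the variant itself is absent (per_population lacks an entry)
    coverage: dict[str, float] = field(default_factory=dict)
    in_segdup: bool = False
    in_repeat: bool = False
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidInputError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InvalidInputError("alt allele must differ from ref")

    @property
    def key(self) -> str:
        return f"{normalize_chrom(self.chrom)}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def region_group(self) -> str:
        """segmental_duplication > tandem_repeat > Ref (stated precedence)."""
        if self.in_segdup:
            return "segmental_duplication"
        if self.in_repeat:
            return "tandem_repeat"
        return "Ref"

    def af(self, pop: str) -> float:
        """Alternate allele frequency in one population (0 if absent)."""
        data = self.per_population.get(pop)
        return data.counts.alt_af if data is not None else 0.0

    def global_af(self) -> float:
        """Allele frequency from counts summed over the whole panel."""
        ac = sum(d.counts.alt_allele_count for d in self.per_population.values())
        an = sum(2 * d.counts.n for d in self.per_population.values())
        return ac / an if an else 0.0

    def total_het(self) -> int:
        return sum(d.counts.n_het for d in self.per_population.values())


@dataclass
class RegionIndex:
    """Point-membership index over genomic intervals (e.g. segdups)."""

    label: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise MalformedIntervalError(f"interval start {start} >= end {end}")
        self.trees.setdefault(normalize_chrom(chrom), IntervalTree()).addi(start, end)

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based ``pos`` falls inside any interval (start < pos <= end)."""
        tree = self.trees.get(normalize_chrom(chrom))
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def load_bed(path: str, label: str) -> RegionIndex:
    """Load a 3+ column BED file (0-based half-open) into a RegionIndex."""
    index = RegionIndex(label=label)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start >= end:
                raise MalformedIntervalError(f"{path}:{lineno}: start {start} >= end {end}")
            index.add(fields[0], start, end)
    return index


def annotate_regions(
    records: list[VariantRecord],
    segdup: RegionIndex | None = None,
    repeats: RegionIndex | None = None,
) -> list[VariantRecord]:
    """Return records with in_segdup / in_repeat flags set by point lookup."""
    out = []
    for rec in records:
        out.append(
            replace(
                rec,
                in_segdup=bool(segdup and segdup.contains(rec.chrom, rec.pos)),
                in_repeat=bool(repeats and repeats.contains(rec.chrom, rec.pos)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# canonical TSV
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "canonical", "consequence"]
_FLAG_COLUMNS = ["pass_exome", "pass_genome", "in_exome", "in_genome"]


def _pop_columns(panel: PopulationPanel) -> list[str]:
    cols = []
    for pop in panel.populations:
        cols += [f"hom_ref_{pop}", f"het_{pop}", f"hom_alt_{pop}", f"cov_{pop}"]
    return cols


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"1", "true", "t", "yes"}


def read_variant_table(
    path: str,
    format: str | None = None,
    panel: PopulationPanel = GNOMAD_V2_PANEL,
) -> list[VariantRecord]:
    """Read variants from the canonical TSV or a gnomAD-style VCF.

    Malformed rows (inconsistent counts, odd AN, negative implied counts)
    are skipped with a logged reason; a missing mandatory column raises
    :class:`FormatError` naming the first offender.
    """
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "tsv":
        return _read_tsv(path, panel)
    if format == "vcf":
        return _read_vcf(path, panel)
    raise InvalidInputError(f"unknown variant table format {format!r}")


def _read_tsv(path: str, panel: PopulationPanel) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = _FIXED_COLUMNS + _pop_columns(panel) + _FLAG_COLUMNS + ["ab_hist"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    extra_cols = [c for c in df.columns if c not in required]

    records: list[VariantRecord] = []
    n_skipped = 0
    for i, row in df.iterrows():
        try:
            per_pop: dict[str, PopulationData] = {}
            coverage: dict[str, float] = {}
            for pop in panel.populations:
                hr = int(row[f"hom_ref_{pop}"])
                het = int(row[f"het_{pop}"])
                ha = int(row[f"hom_alt_{pop}"])
                cov = float(row[f"cov_{pop}"]) if row[f"cov_{pop}"] != "" else 0.0
                coverage[pop] = cov
                if hr + het + ha == 0:
                    continue  # variant absent from this population
                per_pop[pop] = PopulationData(GenotypeCounts(hr, het, ha), cov)
            hist = (
                ABHistogram.from_string(row["ab_hist"])
                if row["ab_hist"]
                else ABHistogram.empty()
            )
            records.append(
                VariantRecord(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    gene=row["gene"],
                    is_canonical=_parse_bool(row["canonical"]),
                    consequence=row["consequence"],
                    per_population=per_pop,
                    pass_exome=_parse_bool(row["pass_exome"]),
                    pass_genome=_parse_bool(row["pass_genome"]),
                    in_exome=_parse_bool(row["in_exome"]),
                    in_genome=_parse_bool(row["in_genome"]),
                    ab_hist=hist,
                    coverage=coverage,
                    annotations={c: row[c] for c in extra_cols},
                )
            )
        except (ValueError, InvalidInputError) as exc:
            n_skipped += 1
            logger.warning("%s: skipping row %d: %s", path, i + 2, exc)
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, n_skipped)
    return records


def write_variant_table(records: list[VariantRecord], path: str,
                        panel: PopulationPanel = GNOMAD_V2_PANEL) -> None:
    """Write records to the canonical TSV (lossless round-trip with
    :func:`read_variant_table`)."""
    extra_cols: list[str] = []
    for rec in records:
        for c in rec.annotations:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            "alt": rec.alt,
            "gene": rec.gene,
            "canonical": rec.is_canonical,
            "consequence": rec.consequence,
        }
        for pop in panel.populations:
            data = rec.per_population.get(pop)
            cov = rec.coverage.get(
                pop, data.coverage_fraction if data is not None else 0.0
            )
            if data is None:
                row |= {f"hom_ref_{pop}": 0, f"het_{pop}": 0, f"hom_alt_{pop}": 0,
                        f"cov_{pop}": cov}
            else:
                row |= {
                    f"hom_ref_{pop}": data.counts.n_hom_ref,
                    f"het_{pop}": data.counts.n_het,
                    f"hom_alt_{pop}": data.counts.n_hom_alt,
                    f"cov_{pop}": cov,
                }
        row |= {
            "pass_exome": rec.pass_exome,
            "pass_genome": rec.pass_genome,
            "in_exome": rec.in_exome,
            "in_genome": rec.in_genome,
            "ab_hist": rec.ab_hist.to_string(),
        }
        for c in extra_cols:
            row[c] = rec.annotations.get(c, "")
        rows.append(row)
    columns = (_FIXED_COLUMNS + _pop_columns(panel) + _FLAG_COLUMNS + ["ab_hist"] + extra_cols)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gnomAD-style VCF
# ---------------------------------------------------------------------------

def _info_per_alt(info_value, alt_index: int, n_alts: int) -> int | None:
    """INFO numbers with Number=A come back as tuples for multi-allelic rows."""
    if info_value is None:
        return None
    if isinstance(info_value, (tuple, list)):
        return int(info_value[alt_index])
    if n_alts > 1 and alt_index > 0:
        return None
    return int(info_value)


def _read_vcf(path: str, panel: PopulationPanel) -> list[VariantRecord]:
    from cyvcf2 import VCF  # deferred: htslib import is comparatively slow

    records: list[VariantRecord] = []
    n_skipped = 0
    vcf = VCF(path)
    for v in vcf:
        alts = v.ALT
        for ai, alt in enumerate(alts):
            try:
                per_pop: dict[str, PopulationData] = {}
                coverage: dict[str, float] = {}
                for pop in panel.populations:
                    key = pop.lower()
                    ac = _info_per_alt(v.INFO.get(f"AC_{key}"), ai, len(alts))
                    an = v.INFO.get(f"AN_{key}")
                    nhom = _info_per_alt(v.INFO.get(f"nhomalt_{key}"), ai, len(alts))
                    if ac is None or an is None:
                        continue
                    an = int(an)
                    nhom = int(nhom or 0)
                    if an % 2 != 0:
                        raise InvalidInputError(f"AN_{key}={an} is odd (diploid AN must be even)")
                    if ac < 2 * nhom:
                        raise InvalidInputError(
                            f"AC_{key}={ac} < 2*nhomalt_{key}={2 * nhom}"
                        )
                    n_het = ac - 2 * nhom
                    n_hom_ref = an // 2 - n_het - nhom
                    if n_hom_ref < 0:
                        raise InvalidInputError(f"negative implied hom-ref count in {pop}")
                    cov = v.INFO.get(f"cov_{key}")
                    cov = float(cov) if cov is not None else 1.0
                    coverage[pop] = cov
                    if ac == 0:
                        continue
                    per_pop[pop] = PopulationData(GenotypeCounts(n_hom_ref, n_het, nhom), cov)
                hist_raw = v.INFO.get("ab_hist_alt_bin_freq")
                hist = (
                    ABHistogram.from_string(str(hist_raw))
                    if hist_raw is not None
                    else ABHistogram.empty()
                )
                is_pass = v.FILTER is None or v.FILTER == "PASS"
                records.append(
                    VariantRecord(
                        chrom=str(v.CHROM),
                        pos=int(v.POS),
                        ref=str(v.REF),
                        alt=str(alt),
                        gene=str(v.INFO.get("gene") or ""),
                        is_canonical=bool(v.INFO.get("canonical", True)),
                        consequence=str(v.INFO.get("consequence") or ""),
                        per_population=per_pop,
                        pass_exome=is_pass,
                        pass_genome=True,
                        in_exome=True,
                        in_genome=False,
                        ab_hist=hist,
                        coverage=coverage,
                    )
                )
            except (ValueError, InvalidInputError) as exc:
                n_skipped += 1
                logger.warning("%s: skipping %s:%s %s>%s: %s", path, v.CHROM, v.POS, v.REF, alt, exc)
    if n_skipped:
        logger.warning("%s: skipped %d malformed VCF records", path, n_skipped)
    return records
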