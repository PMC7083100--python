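"""Variant table I/O, BED region indexes and region annotation."""

import numpy as np
import pytest

from hetexc import (
    FormatError,
    GenotypeCounts,
    MalformedIntervalError,
    RegionIndex,
    SimulationSpec,
    annotate_regions,
    generate_dataset,
    load_bed,
    read_variant_table,
    write_variant_table,
)
from conftest import make_record

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AC_afr,Number=A,Type=Integer,Description="">
##INFO=<ID=AN_afr,Number=1,Type=Integer,Description="">
##INFO=<ID=nhomalt_afr,Number=A,Type=Integer,Description="">
##INFO=<ID=AC_nfe,Number=A,Type=Integer,Description="">
##INFO=<ID=AN_nfe,Number=1,Type=Integer,Description="">
##INFO=<ID=nhomalt_nfe,Number=A,Type=Integer,Description="">
##INFO=<ID=ab_hist_alt_bin_freq,Number=1,Type=String,Description="">
##contig=<ID=11>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path, body_lines):
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in body_lines))
    return str(path)


class TestVCFReading:
    def test_genotype_counts_reconstructed_from_ac_an_nhomalt(self, tmp_path):
        path = write_vcf(
            tmp_path / "v.vcf",
            ["11\t5248232\trs334\tT\tA\t.\tPASS\tAC_afr=1121;AN_afr=24964;nhomalt_afr=4"],
        )
        (rec,) = read_variant_table(path, format="vcf")
        assert rec.per_population["AFR"].counts == GenotypeCounts(11365, 1113, 4)
        # 2*(hom_ref + het + hom_alt) == AN
        assert 2 * rec.per_population["AFR"].counts.n == 24964

    def test_odd_an_record_is_skipped(self, tmp_path):
        path = write_vcf(
            tmp_path / "v.vcf",
            [
                "11\t100\t.\tA\tC\t.\tPASS\tAC_afr=10;AN_afr=24963;nhomalt_afr=0",
                "11\t200\t.\tA\tC\t.\tPASS\tAC_afr=10;AN_afr=24964;nhomalt_afr=0",
            ],
        )
        records = read_variant_table(path, format="vcf")
        assert [r.pos for r in records] == [200]

    def test_ac_below_twice_nhomalt_is_skipped(self, tmp_path):
        path = write_vcf(
            tmp_path / "v.vcf",
            ["11\t300\t.\tA\tC\t.\tPASS\tAC_afr=3;AN_afr=1000;nhomalt_afr=2"],
        )
        assert read_variant_table(path, format="vcf") == []

    def test_ab_histogram_parsed_from_pipe_separated_info(self, tmp_path):
        bins = "|".join(["0"] * 9 + ["7"] + ["0"] * 10)
        path = write_vcf(
            tmp_path / "v.vcf",
            [f"11\t400\t.\tA\tC\t.\tPASS\tAC_nfe=7;AN_nfe=1000;nhomalt_nfe=0;"
             f"ab_hist_alt_bin_freq={bins}"],
        )
        (rec,) = read_variant_table(path, format="vcf")
        assert rec.ab_hist.carriers[9] == 7.0


class TestTSVRoundTrip:
    def test_generated_dataset_round_trips_losslessly(self, tmp_path):
        spec = SimulationSpec(
            panel_scale=0.02,
            n_variants={"hwe": 10, "het_excess": 5, "ab_error": 5},
            seed=11,
        )
        records, _, _ = generate_dataset(spec)
        path = tmp_path / "variants.tsv"
        write_variant_table(records, str(path), panel=spec.effective_panel())
        again = read_variant_table(str(path), panel=spec.effective_panel())
        assert len(again) == len(records)
        for before, after in zip(records, again):
            assert before.key == after.key
            assert before.per_population.keys() == after.per_population.keys()
            for pop in before.per_population:
                assert before.per_population[pop].counts == after.per_population[pop].counts
            assert np.array_equal(before.ab_hist.carriers, after.ab_hist.carriers)
            assert before.coverage == after.coverage
            assert (before.pass_exome, before.in_genome) == (after.pass_exome, after.in_genome)

    def test_annotations_survive_round_trip(self, tmp_path):
        rec = make_record(het_by_pop={"NFE": 50}, annotations={"clinvar": "Benign"})
        path = tmp_path / "v.tsv"
        write_variant_table([rec], str(path))
        (again,) = read_variant_table(str(path))
        assert again.annotations["clinvar"] == "Benign"

    def test_missing_mandatory_column_names_offender(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\tref\n1\t100\tA\n")
        with pytest.raises(FormatError, match="alt"):
            read_variant_table(str(path))

    def test_empty_table_with_valid_header(self, tmp_path):
        rec = make_record(het_by_pop={"NFE": 5})
        path = tmp_path / "empty.tsv"
        write_variant_table([rec], str(path))
        header = path.read_text().splitlines()[0]
        path.write_text(header + "\n")
        assert read_variant_table(str(path)) == []


class TestRegions:
    def test_bed_half_open_membership(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t100\t200\n")
        index = load_bed(str(bed), "segmental_duplication")
        # BED [100, 200) covers 1-based positions 101..200 exactly
        hits = [pos for pos in range(95, 206) if index.contains("1", pos)]
        assert hits == list(range(101, 201))
        assert not index.contains("1", 100)
        assert index.contains("1", 101)
        assert index.contains("1", 200)
        assert not index.contains("1", 201)

    def test_chrom_prefix_normalization_both_ways(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("2\t10\t20\n")
        index = load_bed(str(bed), "tandem_repeat")
        assert index.contains("chr2", 15)

    def test_malformed_interval_raises_with_line_number(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t100\t200\nchr1\t300\t300\n")
        with pytest.raises(MalformedIntervalError, match=":2"):
            load_bed(str(bed), "tandem_repeat")

    def test_region_group_precedence(self):
        segdup = RegionIndex("segmental_duplication")
        segdup.add("1", 0, 1000)
        repeats = RegionIndex("tandem_repeat")
        repeats.add("1", 0, 1000)
        records = [
            make_record(pos=500, het_by_pop={"NFE": 10}),
            make_record(pos=5000, het_by_pop={"NFE": 10}),
        ]
        inside, outside = annotate_regions(records, segdup=segdup, repeats=repeats)
        assert inside.in_segdup and inside.in_repeat
        assert inside.region_group == "segmental_duplication"  # precedence over repeat
        assert outside.region_group == "Ref"

    def test_annotation_against_hand_enumerated_fixture(self, tmp_path):
        bed = tmp_path / "sd.bed"
        bed.write_text("1\t1000\t2000\n1\t5000\t6000\n")
        index = load_bed(str(bed), "segmental_duplication")
        positions = [999, 1000, 1001, 1500, 2000, 2001, 5500, 7000, 6000, 4999]
        expected_inside = {1001, 1500, 2000, 5500, 6000}
        records = [make_record(pos=p, het_by_pop={"NFE": 10}) for p in positions]
        annotated = annotate_regions(records, segdup=index)
        got_inside = {r.pos for r in annotated if r.in_segdup}
        assert got_inside == expected_inside
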