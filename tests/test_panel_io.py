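"""Format reading, panel/genotype alignment and the allele-matching rules."""

import numpy as np
import pytest

from metareid import (
    MISSING,
    GenotypeSet,
    RegionMask,
    SiteKey,
    SitePanel,
    read_bed_mask,
    read_frequency_panel,
    read_genotypes,
    read_site_counts,
    write_site_counts,
)
from metareid.panel_io import PanelError, normalize_chrom
from metareid.site_observe import ObservationSet

from conftest import write_vcf


class TestSiteKey:
    def test_validation_rejects_bad_alleles(self):
        with pytest.raises(PanelError):
            SiteKey("1", 100, "A", "A").validate()
        with pytest.raises(PanelError):
            SiteKey("1", 100, "A", "AT").validate()
        with pytest.raises(PanelError):
            SiteKey("1", 0, "A", "G").validate()

    def test_chrom_normalization_strips_prefix(self):
        assert normalize_chrom("chrX") == "X"
        assert normalize_chrom("7") == "7"


class TestFrequencyPanel:
    def test_allele_count_frequency_from_genotypes(self, tmp_path):
        # EAS genotypes 0/0, 0/1, 1/1 -> alt count 3 of 6 alleles
        vcf = write_vcf(
            tmp_path / "p.vcf",
            [("1", 100, "A", "G", None, ["0/0", "0/1", "1/1"])],
            samples=["s1", "s2", "s3"],
        )
        panel = read_frequency_panel(
            vcf, ["EAS"], sample_populations={"s1": "EAS", "s2": "EAS", "s3": "EAS"}
        )
        assert panel.frequencies("EAS") == pytest.approx([0.5])

    def test_only_multiallelic_records_is_an_error(self, tmp_path):
        vcf = write_vcf(tmp_path / "p.vcf", [("1", 100, "A", "G,T", "AF=0.1,0.2", [])])
        with pytest.raises(PanelError, match="no biallelic"):
            read_frequency_panel(vcf, ["POP"])

    def test_biallelic_snv_filter_count(self, tmp_path):
        # 1000 records of which 50 are indels: 950 survive
        records = []
        for i in range(1000):
            pos = 100 + i
            if i % 20 == 0:
                records.append(("1", pos, "AT", "A", "AF=0.2", []))
            else:
                records.append(("1", pos, "A", "G", "AF=0.2", []))
        vcf = write_vcf(tmp_path / "p.vcf", records)
        panel = read_frequency_panel(vcf, ["POP"])
        assert len(panel) == 950

    def test_info_field_lookup_by_population_suffix(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "p.vcf", [("1", 100, "A", "G", "EAS_AF=0.25;EUR_AF=0.5", [])]
        )
        panel = read_frequency_panel(vcf, ["EAS", "EUR"])
        assert panel.frequencies("EAS") == pytest.approx([0.25])
        assert panel.frequencies("EUR") == pytest.approx([0.5])

    def test_unknown_population_from_sample_map(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "p.vcf",
            [("1", 100, "A", "G", None, ["0/0"])],
            samples=["s1"],
        )
        with pytest.raises(PanelError, match="no samples"):
            read_frequency_panel(vcf, ["AFR"], sample_populations={"s1": "EAS"})


class TestGenotypes:
    def test_dosage_swap_and_missing_rules(self, tmp_path, small_panel):
        vcf = write_vcf(
            tmp_path / "g.vcf",
            [
                ("1", 100, "A", "G", None, ["0/1"]),   # exact match: g = 1
                ("1", 200, "T", "C", None, ["1/1"]),   # ref/alt swapped: g = 2-2 = 0
                ("1", 300, "G", "A", None, ["./."]),   # missing call
                ("1", 400, "T", "G", None, ["0/0"]),   # allele mismatch: dropped
            ],
            samples=["s1"],
        )
        gset = read_genotypes(vcf, small_panel)
        assert list(gset.dosage[0]) == [1, 0, MISSING, MISSING]

    def test_no_overlap_is_an_alignment_error(self, tmp_path, small_panel):
        vcf = write_vcf(
            tmp_path / "g.vcf", [("2", 999, "A", "G", None, ["0/0"])], samples=["s1"]
        )
        with pytest.raises(PanelError, match="overlap"):
            read_genotypes(vcf, small_panel)

    def test_swap_rule_roundtrip_against_direct_read(self, tmp_path, small_panel):
        """Re-reading a deliberately swapped VCF complements every dosage."""
        direct = write_vcf(
            tmp_path / "direct.vcf",
            [("1", 100, "A", "G", None, ["0/0", "0/1", "1/1"])],
            samples=["a", "b", "c"],
        )
        swapped = write_vcf(
            tmp_path / "swapped.vcf",
            [("1", 100, "G", "A", None, ["1/1", "0/1", "0/0"])],
            samples=["a", "b", "c"],
        )
        g1 = read_genotypes(direct, small_panel)
        g2 = read_genotypes(swapped, small_panel)
        np.testing.assert_array_equal(g1.dosage[:, 0], g2.dosage[:, 0])


class TestSiteCounts:
    def test_read_matches_panel_and_drops_zero_depth(self, tmp_path, small_panel):
        table = tmp_path / "counts.tsv"
        table.write_text(
            "#chrom\tpos\tref\talt\tn_ref\tn_alt\n"
            "1\t100\tA\tG\t2\t1\n"
            "1\t200\tC\tT\t0\t0\n"   # zero depth: dropped
            "1\t999\tA\tG\t5\t0\n"   # not in panel: skipped
        )
        obs = read_site_counts(table, small_panel)
        assert obs.n_sites == 1
        assert obs.n[0] == 3 and obs.k[0] == 2

    def test_zero_depth_filter_count(self, tmp_path):
        sites = [SiteKey("1", 100 + i, "A", "G") for i in range(10)]
        panel = SitePanel(sites=sites, freq={})
        lines = ["#chrom\tpos\tref\talt\tn_ref\tn_alt"]
        for i in range(10):
            depth = 0 if i < 3 else 1
            lines.append(f"1\t{100+i}\tA\tG\t{depth}\t0")
        table = tmp_path / "c.tsv"
        table.write_text("\n".join(lines) + "\n")
        assert read_site_counts(table, panel).n_sites == 7

    def test_malformed_row_reports_line_number(self, tmp_path, small_panel):
        table = tmp_path / "bad.tsv"
        table.write_text("1\t100\tA\tG\tx\t1\n")
        with pytest.raises(PanelError, match="line 1"):
            read_site_counts(table, small_panel)

    def test_write_read_round_trip_is_exact(self, tmp_path, small_panel):
        obs = ObservationSet(
            sites=small_panel.sites,
            n=np.array([3, 1, 7, 2]),
            k=np.array([2, 0, 7, 1]),
        )
        path = tmp_path / "rt.tsv"
        write_site_counts(path, obs)
        back = read_site_counts(path, small_panel)
        assert back.sites == obs.sites
        np.testing.assert_array_equal(back.n, obs.n)
        np.testing.assert_array_equal(back.k, obs.k)


class TestBedMask:
    def test_basic_interval_and_empty_file(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("X\t60000\t2699520\n")
        mask = read_bed_mask(bed)
        assert mask.intervals == [("X", 60000, 2699520)]
        bed.write_text("")
        assert read_bed_mask(bed).intervals == []

    def test_overlapping_intervals_merged_against_union_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 1000, 20)
        ends = starts + rng.integers(1, 200, 20)
        bed = tmp_path / "m.bed"
        bed.write_text("".join(f"1\t{s}\t{e}\n" for s, e in zip(starts, ends)))
        mask = read_bed_mask(bed)
        # oracle: per-base union membership
        covered = np.zeros(2000, dtype=bool)
        for s, e in zip(starts, ends):
            covered[s:e] = True
        for zero_pos in range(2000):
            assert mask.contains("1", zero_pos + 1) == covered[zero_pos]
        # merged set is disjoint and sorted
        for (c1, s1, e1), (c2, s2, e2) in zip(mask.intervals, mask.intervals[1:]):
            assert e1 < s2

    def test_inverted_interval_is_a_format_error(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("X\t500\t100\n")
        with pytest.raises(PanelError, match="start"):
            read_bed_mask(bed)


class TestContainers:
    def test_duplicate_sites_rejected(self):
        with pytest.raises(PanelError, match="duplicate"):
            SitePanel(sites=[SiteKey("1", 5, "A", "G"), SiteKey("1", 5, "C", "T")])

    def test_genotype_set_validates_values(self):
        with pytest.raises(PanelError):
            GenotypeSet(individuals=["a"], dosage=np.array([[3]]))

    def test_region_mask_negative_coordinates(self):
        with pytest.raises(PanelError):
            RegionMask(intervals=[("1", -5, 10)])
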