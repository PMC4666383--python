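"""SNP/locus intersection and read-to-allele counting on constructive
alignment fixtures."""

from __future__ import annotations

import pysam
import pytest

import allelome as al
from allelome.counting import STRANDEDNESS_MODES
from allelome.formats_io import ValidationError

from conftest import make_bam


def seq_with(base_at: dict[int, str], start: int, length: int = 30) -> str:
    """Read sequence of 'A's with specific bases at given reference
    positions (full-match alignment starting at ``start``)."""
    chars = ["A"] * length
    for pos, base in base_at.items():
        chars[pos - start] = base
    return "".join(chars)


class TestIntersect:
    def test_containment_is_half_open(self):
        loci = [al.Locus("G", "chr1", "+", ((100, 200),))]
        snps = [
            al.SnpRecord("chr1", 150, "T", "C"),
            al.SnpRecord("chr1", 200, "A", "G"),  # end-exclusive
            al.SnpRecord("chr1", 99, "A", "G"),
        ]
        hit = al.intersect_snps_loci(snps, loci)
        assert [s.pos for s in hit["G"]] == [150]

    def test_snp_serves_all_overlapping_loci(self):
        loci = [
            al.Locus("GeneA", "chr1", "+", ((100, 300),)),
            al.Locus("GeneB", "chr1", "+", ((200, 400),)),
        ]
        snps = [al.SnpRecord("chr1", 250, "T", "C")]
        hit = al.intersect_snps_loci(snps, loci)
        assert [s.pos for s in hit["GeneA"]] == [250]
        assert [s.pos for s in hit["GeneB"]] == [250]

    def test_snp_free_locus_retained_with_empty_list(self):
        loci = [al.Locus("Empty", "chr2", "+", ((0, 100),))]
        assert al.intersect_snps_loci([], loci) == {"Empty": []}


class TestAssignReadToSnp:
    def _read(self, start, seq, cigar=None):
        header = pysam.AlignmentHeader.from_dict(
            {"SQ": [{"SN": "chr1", "LN": 100_000}]}
        )
        a = pysam.AlignedSegment(header)
        a.query_name = "r"
        a.query_sequence = seq
        a.reference_id = 0
        a.reference_start = start
        a.cigarstring = cigar or f"{len(seq)}M"
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        return a

    def test_leftmost_of_multiple_covered_snps_wins(self, toy_snps):
        # toy_snps at 1100 and 1500; read spanning both via long match
        read = self._read(1090, seq_with({1100: "T", 1500: "G"}, 1090, 420))
        snp, base, _ = al.assign_read_to_snp(read, toy_snps)
        assert snp.pos == 1100 and base == "T"

    def test_intron_spanning_snp_not_covered(self, toy_snps):
        # 10M at 1090..1100, 400N skips over both SNPs, 10M at 1500+... no:
        # intron 1100..1500 skips SNP@1100? 10M covers 1090-1099, N covers
        # 1100-1499 (SNP@1100 inside intron), 10M covers 1500-1509 (SNP@1500)
        read = self._read(1090, "A" * 10 + "G" + "A" * 9, "10M400N10M")
        snp, base, _ = al.assign_read_to_snp(read, toy_snps)
        assert snp.pos == 1500 and base == "G"

    def test_read_without_snp_returns_none(self, toy_snps):
        assert al.assign_read_to_snp(self._read(2000, "A" * 30), toy_snps) is None

    def test_low_quality_base_does_not_count_as_covered(self, toy_snps):
        read = self._read(1095, seq_with({1100: "T"}, 1095))
        read.query_qualities = pysam.qualitystring_to_array("#" * 30)  # Q2
        assert al.assign_read_to_snp(read, toy_snps, min_base_quality=20) is None


class TestPileup:
    def test_allele_and_third_base_tallies(self, tmp_path, toy_locus, toy_snps):
        reads = [
            {"name": "r1", "start": 1095, "seq": seq_with({1100: "T"}, 1095)},
            {"name": "r2", "start": 1095, "seq": seq_with({1100: "C"}, 1095)},
            {"name": "r3", "start": 1095, "seq": seq_with({1100: "G"}, 1095)},
            {"name": "r4", "start": 1490, "seq": seq_with({1500: "G"}, 1490)},
        ]
        bam = make_bam(tmp_path / "t.bam", reads)
        pile = al.pileup_alleles(bam, {"GeneA": toy_snps}, [toy_locus], 0)
        c0, c1 = pile["GeneA"]
        assert (c0.n1, c0.n2, c0.n_other) == (1, 1, 1)
        assert (c1.n1, c1.n2, c1.n_other) == (0, 1, 0)

    def test_mates_on_same_snp_counted_once(self, tmp_path, toy_locus, toy_snps):
        seq = seq_with({1100: "T"}, 1095)
        reads = [
            {"name": "f1", "start": 1095, "seq": seq, "flag": 99, "next_start": 1095},
            {"name": "f1", "start": 1095, "seq": seq, "flag": 147, "next_start": 1095},
        ]
        bam = make_bam(tmp_path / "t.bam", reads)
        pile = al.pileup_alleles(bam, {"GeneA": toy_snps}, [toy_locus], 0)
        c0 = pile["GeneA"][0]
        assert (c0.n1, c0.n2, c0.n_other) == (1, 0, 0)

    def test_discordant_mates_count_as_other(self, tmp_path, toy_locus, toy_snps):
        reads = [
            {"name": "f1", "start": 1095, "seq": seq_with({1100: "T"}, 1095),
             "flag": 99, "next_start": 1095},
            {"name": "f1", "start": 1095, "seq": seq_with({1100: "C"}, 1095),
             "flag": 147, "next_start": 1095},
        ]
        bam = make_bam(tmp_path / "t.bam", reads)
        c0 = al.pileup_alleles(bam, {"GeneA": toy_snps}, [toy_locus], 0)["GeneA"][0]
        assert (c0.n1, c0.n2, c0.n_other) == (0, 0, 1)

    def test_fragment_spanning_two_snps_counts_at_leftmost_only(
        self, tmp_path, toy_locus, toy_snps
    ):
        reads = [
            {"name": "f1", "start": 1095, "seq": seq_with({1100: "T"}, 1095),
             "flag": 99, "next_start": 1490},
            {"name": "f1", "start": 1490, "seq": seq_with({1500: "G"}, 1490),
             "flag": 147, "next_start": 1095},
        ]
        bam = make_bam(tmp_path / "t.bam", reads)
        c0, c1 = al.pileup_alleles(bam, {"GeneA": toy_snps}, [toy_locus], 0)["GeneA"]
        assert (c0.n1, c0.n2) == (1, 0)
        assert (c1.n1, c1.n2, c1.n_other) == (0, 0, 0)

    @pytest.mark.parametrize("flag", [4, 256, 2048, 512, 1024])
    def test_non_primary_and_flagged_reads_excluded(
        self, tmp_path, toy_locus, toy_snps, flag
    ):
        reads = [
            {"name": "r1", "start": 1095, "seq": seq_with({1100: "T"}, 1095),
             "flag": flag},
        ]
        bam = make_bam(tmp_path / "t.bam", reads)
        c0 = al.pileup_alleles(bam, {"GeneA": toy_snps}, [toy_locus], 0)["GeneA"][0]
        assert c0.n1 + c0.n2 + c0.n_other == 0

    def test_duplicates_counted_when_requested(self, tmp_path, toy_locus, toy_snps):
        reads = [
            {"name": "r1", "start": 1095, "seq": seq_with({1100: "T"}, 1095),
             "flag": 1024},
        ]
        bam = make_bam(tmp_path / "t.bam", reads)
        c0 = al.pileup_alleles(
            bam, {"GeneA": toy_snps}, [toy_locus], 0, include_duplicates=True
        )["GeneA"][0]
        assert c0.n1 == 1

    def test_strandedness_filters_by_fragment_strand(self, tmp_path, toy_snps):
        plus_locus = al.Locus("GeneA", "chr1", "+", ((1000, 2000),))
        seq = seq_with({1100: "T"}, 1095)
        reads = [
            {"name": "fwd", "start": 1095, "seq": seq, "flag": 0},
            {"name": "rev", "start": 1095, "seq": seq, "flag": 16},
        ]
        bam = make_bam(tmp_path / "t.bam", reads)

        def n_counted(mode):
            c0 = al.pileup_alleles(
                bam, {"GeneA": toy_snps}, [plus_locus], 0, strandedness=mode
            )["GeneA"][0]
            return c0.n1 + c0.n2 + c0.n_other

        assert n_counted("unstranded") == 2
        assert n_counted("forward") == 1  # only the + read
        assert n_counted("reverse") == 1  # only the - read (dUTP)

    def test_reverse_mode_uses_opposite_of_mate1_for_pairs(self, tmp_path, toy_snps):
        plus_locus = al.Locus("GeneA", "chr1", "+", ((1000, 2000),))
        seq = seq_with({1100: "T"}, 1095)
        # proper pair with mate1 on the minus strand: flags 83/163
        reads = [
            {"name": "f1", "start": 1095, "seq": seq, "flag": 83, "next_start": 1095},
            {"name": "f1", "start": 1095, "seq": seq, "flag": 163, "next_start": 1095},
        ]
        bam = make_bam(tmp_path / "t.bam", reads)
        c_rev = al.pileup_alleles(
            bam, {"GeneA": toy_snps}, [plus_locus], 0, strandedness="reverse"
        )["GeneA"][0]
        c_fwd = al.pileup_alleles(
            bam, {"GeneA": toy_snps}, [plus_locus], 0, strandedness="forward"
        )["GeneA"][0]
        assert c_rev.n1 == 1  # mate1 on '-', dUTP fragment is '+'
        assert c_fwd.n1 + c_fwd.n2 + c_fwd.n_other == 0

    def test_unknown_mode_rejected(self, tmp_path, toy_locus, toy_snps):
        bam = make_bam(tmp_path / "t.bam", [])
        with pytest.raises(ValidationError, match="strandedness"):
            al.pileup_alleles(bam, {}, [], 0, strandedness="sideways")

    def test_missing_contig_warns_not_raises(self, tmp_path):
        locus = al.Locus("G", "chrZ", "+", ((0, 100),))
        snps = [al.SnpRecord("chrZ", 50, "T", "C")]
        bam = make_bam(tmp_path / "t.bam", [])
        with pytest.warns(UserWarning, match="chrZ"):
            pile = al.pileup_alleles(bam, {"G": snps}, [locus], 0)
        assert pile["G"][0].n1 == 0


class TestAggregate:
    def _pile(self, counts):
        snps = [al.SnpRecord("chr1", 100 + i, "T", "C") for i in range(len(counts))]
        return {
            "G": [
                al.SnpSampleCounts(s, "G", 0, n1=c[0], n2=c[1], n_other=c[2])
                for s, c in zip(snps, counts)
            ]
        }

    def test_minread_inclusion_is_per_snp(self):
        pile = self._pile([(1, 0, 0), (3, 1, 2)])
        agg1 = al.aggregate_locus_counts(pile, 0, minread=1)["G"]
        agg2 = al.aggregate_locus_counts(pile, 0, minread=2)["G"]
        assert (agg1.N1, agg1.N2, agg1.snps_covered) == (4, 1, 2)
        assert (agg2.N1, agg2.N2, agg2.snps_covered) == (3, 1, 1)

    def test_other_bases_never_enter_sums(self):
        agg = al.aggregate_locus_counts(self._pile([(3, 1, 5)]), 0)["G"]
        assert (agg.N1, agg.N2) == (3, 1)

    def test_all_snps_below_minread_gives_empty_sum(self):
        agg = al.aggregate_locus_counts(self._pile([(1, 0, 0)]), 0, minread=3)["G"]
        assert (agg.N1, agg.N2, agg.snps_covered) == (0, 0, 0)

    def test_minread_below_one_rejected(self):
        with pytest.raises(ValidationError, match="minread"):
            al.aggregate_locus_counts({}, 0, minread=0)

    def test_raising_minread_never_raises_coverage(self):
        pile = self._pile([(2, 1, 0), (1, 0, 0), (5, 5, 1)])
        cov = [
            al.aggregate_locus_counts(pile, 0, minread=m)["G"].snps_covered
            for m in (1, 2, 3, 4)
        ]
        assert cov == sorted(cov, reverse=True)


class TestConservationAndSymmetry:
    @pytest.fixture()
    def toy20(self, tmp_path, toy_locus, toy_snps):
        """20 single-end reads with known composition: 8 T + 5 C + 2 G at
        SNP@1100 (T|C), 3 G + 1 A at SNP@1500 (A|G), 1 read with no SNP."""
        reads = []
        for i in range(8):
            reads.append({"name": f"t{i}", "start": 1090 + i, "seq": seq_with({1100: "T"}, 1090 + i)})
        for i in range(5):
            reads.append({"name": f"c{i}", "start": 1085 + i, "seq": seq_with({1100: "C"}, 1085 + i)})
        for i in range(2):
            reads.append({"name": f"g{i}", "start": 1080 + i, "seq": seq_with({1100: "G"}, 1080 + i)})
        for i in range(3):
            reads.append({"name": f"h{i}", "start": 1480 + i, "seq": seq_with({1500: "G"}, 1480 + i)})
        reads.append({"name": "i0", "start": 1495, "seq": seq_with({1500: "A"}, 1495)})
        reads.append({"name": "nosnp", "start": 1200, "seq": "A" * 30})
        assert len(reads) == 20
        return make_bam(tmp_path / "toy20.bam", reads)

    def test_counts_conserve_fragments(self, toy20, toy_locus, toy_snps):
        pile = al.pileup_alleles(toy20, {"GeneA": toy_snps}, [toy_locus], 0)
        total = sum(c.n1 + c.n2 + c.n_other for c in pile["GeneA"])
        assert total == 19  # 20 reads, one covers no SNP
        c0, c1 = pile["GeneA"]
        assert (c0.n1, c0.n2, c0.n_other) == (8, 5, 2)
        assert (c1.n1, c1.n2, c1.n_other) == (1, 3, 0)

    def test_aggregation_conserves_included_snp_counts(self, toy20, toy_locus, toy_snps):
        pile = al.pileup_alleles(toy20, {"GeneA": toy_snps}, [toy_locus], 0)
        agg = al.aggregate_locus_counts(pile, 0, minread=1)["GeneA"]
        assert (agg.N1, agg.N2) == (8 + 1, 5 + 3)

    def test_allele_label_swap_swaps_counts_exactly(self, toy20, toy_locus, toy_snps):
        swapped = [
            al.SnpRecord(s.chrom, s.pos, s.allele2, s.allele1) for s in toy_snps
        ]
        orig = al.pileup_alleles(toy20, {"GeneA": toy_snps}, [toy_locus], 0)["GeneA"]
        swap = al.pileup_alleles(toy20, {"GeneA": swapped}, [toy_locus], 0)["GeneA"]
        for o, s in zip(orig, swap):
            assert (o.n1, o.n2, o.n_other) == (s.n2, s.n1, s.n_other)
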