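"""Coordinate contract, FASTA/BED/bedGraph/VCF I/O and cleavage extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from footprintkit.tracks_io import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    CleavageProfile,
    GenomicInterval,
    VariantRecord,
    bed_intervals,
    extract_cleavages,
    read_bed,
    read_bedgraph,
    read_genome,
    read_variants,
    write_bedgraph,
    write_fasta,
    write_vcf,
)


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("c", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("c", -1, 4)
        assert len(GenomicInterval("c", 5, 15)) == 10

    def test_overlap_length_matches_bruteforce(self, rng):
        for _ in range(200):
            a = sorted(rng.integers(0, 50, size=2))
            b = sorted(rng.integers(0, 50, size=2))
            if a[0] == a[1] or b[0] == b[1]:
                continue
            iv1 = GenomicInterval("c", int(a[0]), int(a[1]))
            iv2 = GenomicInterval("c", int(b[0]), int(b[1]))
            brute = len(set(range(*a)) & set(range(*b)))
            assert iv1.overlap_length(iv2) == brute
            assert iv1.overlaps(iv2) == (brute > 0)


class TestReadGenome:
    def test_case_folding_and_order(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nacgt\n>c2\nGGNT\n")
        g = read_genome(p)
        assert g["c1"] == "ACGT"
        assert list(g.contigs) == ["c1", "c2"]
        assert g["c2"] == "GGNT"  # N preserved

    def test_illegal_character_names_contig_and_position(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGR\n")
        with pytest.raises(ValueError, match=r"c1.*position 3"):
            read_genome(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_genome(tmp_path / "absent.fa")

    def test_fasta_round_trip(self, tmp_path, random_genome):
        p = tmp_path / "rt.fa"
        write_fasta(p, random_genome.contigs)
        assert read_genome(p).contigs == random_genome.contigs


class TestExtractCleavages:
    CONTIGS = {"chr1": 1000}

    def test_plus_strand_read_counts_at_leftmost_base(self, bam_factory):
        bam = bam_factory("a.bam", self.CONTIGS, [{"contig": "chr1", "start": 100}])
        prof = extract_cleavages(bam, GenomicInterval("chr1", 50, 200))
        assert prof.counts_plus[100 - 50] == 1
        assert prof.counts_plus.sum() == 1 and prof.counts_minus.sum() == 0

    def test_minus_strand_read_counts_at_rightmost_base(self, bam_factory):
        # read aligned over 100-135 inclusive => 5' end of the minus strand at 135
        bam = bam_factory(
            "b.bam", self.CONTIGS, [{"contig": "chr1", "start": 100, "length": 36, "reverse": True}]
        )
        prof = extract_cleavages(bam, GenomicInterval("chr1", 50, 200))
        assert prof.counts_minus[135 - 50] == 1
        assert prof.counts_plus.sum() == 0

    def test_minus_offset_shifts_minus_strand_only(self, bam_factory):
        bam = bam_factory(
            "c.bam", self.CONTIGS, [{"contig": "chr1", "start": 100, "length": 36, "reverse": True}]
        )
        prof = extract_cleavages(
            bam, GenomicInterval("chr1", 50, 200), minus_offset=1
        )
        assert prof.counts_minus[136 - 50] == 1

    @pytest.mark.parametrize("flag", ["duplicate", "qcfail", "secondary"])
    def test_flagged_reads_excluded(self, bam_factory, flag):
        bam = bam_factory(
            f"{flag}.bam", self.CONTIGS, [{"contig": "chr1", "start": 100, flag: True}]
        )
        prof = extract_cleavages(bam, GenomicInterval("chr1", 50, 200))
        assert prof.combined.sum() == 0

    def test_min_mapq_filter(self, bam_factory):
        bam = bam_factory(
            "mq.bam",
            self.CONTIGS,
            [
                {"contig": "chr1", "start": 100, "mapq": 5},
                {"contig": "chr1", "start": 110, "mapq": 50},
            ],
        )
        prof = extract_cleavages(bam, GenomicInterval("chr1", 50, 200), min_mapq=30)
        assert prof.combined.sum() == 1
        assert prof.counts_plus[110 - 50] == 1

    def test_count_conservation_on_random_reads(self, bam_factory, rng):
        reads = [
            {
                "contig": "chr1",
                "start": int(rng.integers(0, 900)),
                "length": 36,
                "reverse": bool(rng.integers(0, 2)),
            }
            for _ in range(150)
        ]
        bam = bam_factory("rand.bam", self.CONTIGS, reads)
        iv = GenomicInterval("chr1", 0, 1000)
        prof = extract_cleavages(bam, iv)
        # every retained read's 5' end lies on the contig
        assert prof.combined.sum() == len(reads)
        assert prof.total_tags == len(reads)


class TestBedgraph:
    def test_exact_zero_omitting_lines(self, tmp_path):
        p = tmp_path / "t.bg"
        iv = GenomicInterval("c1", 10, 14)
        write_bedgraph(p, iv, [0, 3, 0, 2])
        assert p.read_text().splitlines() == ["c1\t11\t12\t3", "c1\t13\t14\t2"]
        assert read_bedgraph(p, iv).tolist() == [0, 3, 0, 2]

    def test_invalid_interval_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bg"
        p.write_text("c1\t5\t5\t1\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bedgraph(p, GenomicInterval("c1", 0, 10))

    @given(
        values=st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=80),
        start=st.integers(min_value=0, max_value=100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_integer_round_trip(self, tmp_path_factory, values, start):
        p = tmp_path_factory.mktemp("bg") / "rt.bg"
        iv = GenomicInterval("cX", start, start + len(values))
        write_bedgraph(p, iv, values)
        assert read_bedgraph(p, iv).tolist() == values

    def test_real_valued_round_trip_to_precision(self, tmp_path, rng):
        p = tmp_path / "real.bg"
        iv = GenomicInterval("c", 0, 40)
        vals = np.round(rng.uniform(0.1, 5, 40), 4)
        write_bedgraph(p, iv, vals, precision=6)
        assert np.allclose(read_bedgraph(p, iv), vals, atol=1e-6)


class TestBed:
    def test_parse_intervals(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("c1\t5\t15\nc2\t0\t7\tname\t3\t+\n")
        ivs = bed_intervals(p)
        assert ivs[0] == GenomicInterval("c1", 5, 15)
        df = read_bed(p)
        assert list(df.columns[:3]) == ["contig", "start", "end"]

    def test_invalid_bounds_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("c1\t9\t3\n")
        with pytest.raises(ValueError):
            read_bed(p)


class TestVariants:
    def test_vcf_round_trip_genotype_classes(self, tmp_path):
        variants = [
            VariantRecord(
                "c1", 41, "A", "G", {"ind1": GT_HET, "ind2": GT_HOM_REF}
            ),
            VariantRecord(
                "c1", 99, "C", "T", {"ind1": GT_HOM_ALT, "ind2": GT_HET}
            ),
        ]
        p = tmp_path / "v.vcf"
        write_vcf(p, variants, ["ind1", "ind2"], {"c1": 200})
        back = read_variants(p)
        assert [(v.contig, v.position, v.ref, v.alt) for v in back] == [
            ("c1", 41, "A", "G"),
            ("c1", 99, "C", "T"),
        ]
        assert back[0].genotypes == {"ind1": GT_HET, "ind2": GT_HOM_REF}
        assert back[1].genotypes == {"ind1": GT_HOM_ALT, "ind2": GT_HET}

    def test_variant_record_validation(self):
        with pytest.raises(ValueError):
            VariantRecord("c", 1, "A", "A")
        with pytest.raises(ValueError):
            VariantRecord("c", 1, "A", "AG")


class TestCleavageProfile:
    def test_invariants(self):
        iv = GenomicInterval("c", 0, 4)
        with pytest.raises(ValueError):
            CleavageProfile(iv, np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            CleavageProfile(iv, np.array([1, 0, 0, 0]), np.zeros(4), total_tags=0)
        prof = CleavageProfile(iv, np.array([1, 0, 2, 0]), np.array([0, 1, 0, 0]))
        assert prof.total_tags == 4
        assert prof.combined.tolist() == [1, 1, 2, 0]

    def test_slice(self):
        iv = GenomicInterval("c", 10, 20)
        prof = CleavageProfile(iv, np.arange(10), np.zeros(10, dtype=int), total_tags=100)
        sub = prof.slice(GenomicInterval("c", 12, 15))
        assert sub.counts_plus.tolist() == [2, 3, 4]
        assert sub.total_tags == 100
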