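import numpy as np
import pytest

from acylprofiler.errors import ParseError, ValidationError
from acylprofiler.genome_io import (CoverageTrack, GenomicInterval, Peak,
                                    PeakSet, derive_intergenic,
                                    derive_promoters, read_coverage,
                                    read_expression, read_gff3, read_peaks,
                                    write_coverage, write_expression,
                                    write_gff3, write_peaks)

from conftest import make_peaks

TOY_GFF3 = """\
##gff-version 3
##sequence-region chr1 1 20000
##sequence-region chr2 1 10000
chr1\t.\tgene\t1001\t4000\t.\t+\t.\tID=gA
chr1\t.\tmRNA\t1001\t4000\t.\t+\t.\tID=gA.1;Parent=gA
chr1\t.\texon\t1001\t2000\t.\t+\t.\tParent=gA.1
chr1\t.\texon\t2501\t4000\t.\t+\t.\tParent=gA.1
chr1\t.\tfive_prime_UTR\t1001\t1200\t.\t+\t.\tParent=gA.1
chr1\t.\tCDS\t1201\t2000\t.\t+\t0\tParent=gA.1
chr1\t.\tCDS\t2501\t3700\t.\t+\t0\tParent=gA.1
chr1\t.\tthree_prime_UTR\t3701\t4000\t.\t+\t.\tParent=gA.1
chr1\t.\tgene\t6001\t9000\t.\t-\t.\tID=gB
chr1\t.\tmRNA\t6001\t9000\t.\t-\t.\tID=gB.1;Parent=gB
chr1\t.\texon\t6001\t7000\t.\t-\t.\tParent=gB.1
chr1\t.\texon\t8001\t9000\t.\t-\t.\tParent=gB.1
chr1\t.\tCDS\t6101\t7000\t.\t-\t0\tParent=gB.1
chr1\t.\tCDS\t8001\t8900\t.\t-\t0\tParent=gB.1
chr2\t.\tgene\t501\t1500\t.\t+\t.\tID=gC
chr2\t.\tmRNA\t501\t1500\t.\t+\t.\tID=gC.1;Parent=gC
chr2\t.\texon\t501\t1500\t.\t+\t.\tParent=gC.1
chr2\t.\tCDS\t601\t1400\t.\t+\t0\tParent=gC.1
"""

# hand-derived internal feature table for the fixture above
EXPECTED_FEATURES = {
    "gA": [("five_prime_utr", 1000, 1200), ("cds", 1200, 2000),
           ("intron", 2000, 2500), ("cds", 2500, 3700),
           ("three_prime_utr", 3700, 4000)],
    # minus strand: the genomic-left UTR is the 3' one
    "gB": [("three_prime_utr", 6000, 6100), ("cds", 6100, 7000),
           ("intron", 7000, 8000), ("cds", 8000, 8900),
           ("five_prime_utr", 8900, 9000)],
    "gC": [("five_prime_utr", 500, 600), ("cds", 600, 1400),
           ("three_prime_utr", 1400, 1500)],
}


@pytest.fixture
def toy_gff(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF3)
    return p


class TestReadGff3:
    def test_coordinate_convention_and_tss(self, toy_gff):
        ann = read_gff3(toy_gff)
        ga = {g.gene_id: g for g in ann.genes}
        assert (ga["gA"].interval.start, ga["gA"].interval.end) == (1000, 4000)
        assert ga["gA"].tss == 1000
        assert ga["gB"].tss == 8999  # minus strand: last base of the interval

    def test_intron_is_exon_gap(self, toy_gff):
        ann = read_gff3(toy_gff)
        ga = {g.gene_id: g for g in ann.genes}
        introns = [(iv.start, iv.end) for c, iv in ga["gA"].features if c == "intron"]
        assert introns == [(2000, 2500)]

    def test_toy_fixture_matches_hand_table(self, toy_gff):
        ann = read_gff3(toy_gff)
        for g in ann.genes:
            got = [(c, iv.start, iv.end) for c, iv in g.features]
            assert got == EXPECTED_FEATURES[g.gene_id], g.gene_id

    def test_feature_partition_of_gene_span(self, toy_gff):
        # union of 5'UTR+CDS+intron+3'UTR equals the transcript span, disjointly
        ann = read_gff3(toy_gff)
        for g in ann.genes:
            ivs = sorted((iv.start, iv.end) for _, iv in g.features)
            assert ivs[0][0] == g.interval.start
            assert ivs[-1][1] == g.interval.end
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 == s2  # contiguous and non-overlapping

    def test_sequence_region_lengths(self, toy_gff):
        ann = read_gff3(toy_gff)
        assert ann.chrom_lengths == {"chr1": 20000, "chr2": 10000}

    def test_roundtrip_exact(self, toy_gff, tmp_path):
        ann = read_gff3(toy_gff)
        out = tmp_path / "rt.gff3"
        write_gff3(ann, out)
        ann2 = read_gff3(out)
        by_id = {g.gene_id: g for g in ann2.genes}
        for g in ann.genes:
            g2 = by_id[g.gene_id]
            assert g2.interval == g.interval
            assert [(c, iv.start, iv.end) for c, iv in g2.features] == \
                   [(c, iv.start, iv.end) for c, iv in g.features]

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tonly\tthree\n")
        with pytest.raises(ParseError, match=":2"):
            read_gff3(p)

    def test_child_outside_parent_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n##sequence-region chr1 1 10000\n"
            "chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g\n"
            "chr1\t.\tmRNA\t100\t200\t.\t+\t.\tID=g.1;Parent=g\n"
            "chr1\t.\texon\t100\t300\t.\t+\t.\tParent=g.1\n")
        with pytest.raises(ValidationError, match="outside parent"):
            read_gff3(p)


class TestDerivedIntervals:
    def test_promoter_plus_strand(self, toy_annotation):
        proms = {(p.chrom, p.start, p.end) for p in derive_promoters(toy_annotation)}
        assert ("chr1", 4000, 5000) in proms       # geneA [5000,8000) +
        assert ("chr1", 15000, 16000) in proms     # geneB [12000,15000) -
        assert ("chr2", 0, 300) in proms           # geneC truncated at chrom start

    def test_promoter_truncation_length(self, toy_annotation):
        proms = [p for p in derive_promoters(toy_annotation) if p.chrom == "chr2"]
        assert len(proms) == 1 and len(proms[0]) == 300

    def test_intergenic_empty_annotation(self):
        from acylprofiler.genome_io import GenomeAnnotation
        ann = GenomeAnnotation(chrom_lengths={"chr1": 500}, genes=[])
        inter = derive_intergenic(ann)
        assert [(i.chrom, i.start, i.end) for i in inter] == [("chr1", 0, 500)]

    def test_partition_covers_each_base_once(self, toy_annotation):
        # genebody + promoter + intergenic hit every base exactly once here
        for chrom, L in toy_annotation.chrom_lengths.items():
            cover = np.zeros(L, dtype=int)
            for g in toy_annotation.genes:
                if g.interval.chrom == chrom:
                    cover[g.interval.start:g.interval.end] += 1
            for p in derive_promoters(toy_annotation):
                if p.chrom == chrom:
                    cover[p.start:p.end] += 1
            for p in derive_intergenic(toy_annotation):
                if p.chrom == chrom:
                    cover[p.start:p.end] += 1
            assert (cover == 1).all()

    def test_intergenic_matches_bruteforce_on_random_genome(self):
        from acylprofiler.synthetic_data import SimConfig, simulate_genome
        cfg = SimConfig(seed=5, n_chroms=1, chrom_length=120_000, n_genes=20)
        ann = simulate_genome(cfg)
        mask = np.zeros(cfg.chrom_length, dtype=bool)
        for g in ann.genes:
            mask[g.interval.start:g.interval.end] = True
        for p in derive_promoters(ann):
            mask[p.start:p.end] = True
        expected = ~mask
        got = np.zeros(cfg.chrom_length, dtype=bool)
        for p in derive_intergenic(ann):
            got[p.start:p.end] = True
        assert (got == expected).all()


class TestReadPeaks:
    def test_broadpeak_column_mapping(self, tmp_path):
        p = tmp_path / "a.broadPeak"
        p.write_text("chr1\t100\t200\tp1\t0\t.\t12.0\t5.0\t3.0\n")
        ps = read_peaks(p, dialect="broadPeak")
        pk = ps.peaks[0]
        assert (pk.fold_enrichment, pk.neg_log10_p, pk.neg_log10_q) == (12.0, 5.0, 3.0)
        assert pk.name == "p1"

    def test_plain_bed_has_missing_scores(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t50\n")
        pk = read_peaks(p, dialect="bed").peaks[0]
        assert pk.fold_enrichment is None and pk.neg_log10_q is None

    def test_macs_placeholder_minus_one_is_missing(self, tmp_path):
        p = tmp_path / "a.broadPeak"
        p.write_text("chr1\t0\t50\t.\t0\t.\t-1\t5.0\t-1\n")
        pk = read_peaks(p, dialect="broadPeak").peaks[0]
        assert pk.fold_enrichment is None and pk.neg_log10_q is None
        assert pk.neg_log10_p == 5.0

    def test_unsorted_input_is_sorted(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = [("chr%d" % rng.integers(1, 4), int(s), int(s) + 10)
                for s in rng.integers(0, 10_000, 50)]
        p = tmp_path / "u.bed"
        p.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in rows))
        ps = read_peaks(p, dialect="bed")
        got = [(pk.interval.chrom, pk.interval.start, pk.interval.end)
               for pk in ps.peaks]
        assert got == sorted(rows)

    def test_invalid_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValidationError):
            read_peaks(p, dialect="bed")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_peaks(tmp_path / "x.bed", dialect="gappedPeak")

    def test_roundtrip_identity(self, tmp_path):
        ps = PeakSet(mark="m", sample="s", peaks=[
            Peak(GenomicInterval("chr1", 10, 60), 4.5, 2.0, 1.5, "a"),
            Peak(GenomicInterval("chr1", 100, 160), None, None, None, "b"),
        ])
        out = tmp_path / "rt.broadPeak"
        write_peaks(ps, out, dialect="broadPeak")
        back = read_peaks(out, dialect="broadPeak", mark="m")
        assert [(p.interval, p.fold_enrichment, p.neg_log10_p, p.neg_log10_q)
                for p in back.peaks] == \
               [(p.interval, p.fold_enrichment, p.neg_log10_p, p.neg_log10_q)
                for p in ps.peaks]


class TestCoverageAndExpression:
    def test_bedgraph_basic(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("chr1\t0\t100\t5\n")
        track = read_coverage(p, total_mapped=100)
        assert track.mean_depth("chr1", 0, 100) == 5.0
        assert track.mass("chr1", 20, 40)[0] == 100.0

    def test_mass_matches_per_base_oracle(self):
        rng = np.random.default_rng(7)
        # random non-overlapping RLE
        bounds = np.sort(rng.choice(np.arange(1, 1000), size=40, replace=False))
        starts, ends, vals, base = [], [], [], np.zeros(1000)
        for s, e in zip(bounds[::2], bounds[1::2]):
            v = float(rng.integers(0, 9))
            starts.append(s); ends.append(e); vals.append(v)
            base[s:e] = v
        track = CoverageTrack({"chr1": (np.array(starts), np.array(ends),
                                        np.array(vals))}, total_mapped=10)
        qs = rng.integers(0, 900, 60)
        qe = qs + rng.integers(1, 100, 60)
        got = track.mass("chr1", qs, qe)
        expected = np.array([base[s:e].sum() for s, e in zip(qs, qe)])
        np.testing.assert_allclose(got, expected)

    def test_coverage_roundtrip(self, tmp_path):
        track = CoverageTrack({"chr1": (np.array([5, 50]), np.array([20, 80]),
                                        np.array([2.0, 7.0]))}, total_mapped=42)
        out = tmp_path / "c.bedGraph"
        write_coverage(track, out)
        back = read_coverage(out)
        assert back.total_mapped == 42
        np.testing.assert_allclose(back.mass("chr1", 0, 100), track.mass("chr1", 0, 100))

    def test_negative_coverage_rejected(self, tmp_path):
        p = tmp_path / "c.bedGraph"
        p.write_text("chr1\t0\t10\t-3\n")
        with pytest.raises(ValidationError):
            read_coverage(p, total_mapped=1)

    def test_duplicate_gene_id_names_gene(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tfpkm\ng1\t5\ng1\t6\n")
        with pytest.raises(ValidationError, match="g1"):
            read_expression(p)

    def test_expression_roundtrip(self, tmp_path):
        from acylprofiler.genome_io import ExpressionTable
        expr = ExpressionTable(fpkm={"g1": 0.0, "g2": 12.5})
        out = tmp_path / "e.tsv"
        write_expression(expr, out)
        assert read_expression(out).fpkm == expr.fpkm


class TestIntervalInvariants:
    def test_interval_validation(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 10)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValidationError):
            Peak(GenomicInterval("chr1", 0, 10), fold_enrichment=-2.0)
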