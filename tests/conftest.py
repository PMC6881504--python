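import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acylprofiler.genome_io import (GeneModel, GenomeAnnotation,
                                    GenomicInterval, Peak, PeakSet)
from acylprofiler.synthetic_data import SimConfig, simulate_genome

settings.register_profile(
    "default", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


def make_gene(gene_id, chrom, start, end, strand, exons, utr5=None, utr3=None):
    """Hand-build a gene: exons as (start, end) tuples; UTRs carved from the
    first/last transcribed exon ends unless given explicitly."""
    exons = sorted(exons)
    features = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        features.append(("intron", GenomicInterval(chrom, e1, s2, strand)))
    utr5 = utr5 or []
    utr3 = utr3 or []
    for s, e in utr5:
        features.append(("five_prime_utr", GenomicInterval(chrom, s, e, strand)))
    for s, e in utr3:
        features.append(("three_prime_utr", GenomicInterval(chrom, s, e, strand)))
    carved = sorted([*utr5, *utr3])
    for s, e in exons:
        pieces = [(s, e)]
        for cs, ce in carved:
            nxt = []
            for ps, pe in pieces:
                if ce <= ps or cs >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < cs:
                    nxt.append((ps, cs))
                if ce < pe:
                    nxt.append((ce, pe))
            pieces = nxt
        for ps, pe in pieces:
            if ps < pe:
                features.append(("cds", GenomicInterval(chrom, ps, pe, strand)))
    return GeneModel(gene_id=gene_id, interval=GenomicInterval(chrom, start, end, strand),
                     features=sorted(features, key=lambda f: f[1].start))


@pytest.fixture
def toy_annotation():
    """Two chromosomes, three hand-built genes with known structure."""
    g1 = make_gene("geneA", "chr1", 5000, 8000, "+",
                   exons=[(5000, 6000), (6500, 8000)],
                   utr5=[(5000, 5200)], utr3=[(7800, 8000)])
    g2 = make_gene("geneB", "chr1", 12000, 15000, "-",
                   exons=[(12000, 13000), (14000, 15000)],
                   utr5=[(14800, 15000)], utr3=[(12000, 12100)])
    g3 = make_gene("geneC", "chr2", 300, 2300, "+",
                   exons=[(300, 2300)], utr5=[(300, 400)])
    ann = GenomeAnnotation(chrom_lengths={"chr1": 30000, "chr2": 20000},
                           genes=[g1, g2, g3], promoter_flank=1000)
    ann.validate()
    return ann


def make_peaks(intervals, mark="test"):
    return PeakSet(mark=mark, sample="", peaks=[
        Peak(GenomicInterval(c, s, e), name=f"{mark}_{i}")
        for i, (c, s, e) in enumerate(intervals)])


def random_peaks(rng, ann, n, min_len=20, max_len=500, mark="rand"):
    chroms = sorted(ann.chrom_lengths)
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        L = ann.chrom_lengths[chrom]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, L - length))
        out.append((chrom, start, start + length))
    return make_peaks(out, mark=mark)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared across tests."""
    from acylprofiler.synthetic_data import simulate_all

    cfg = SimConfig(seed=11, n_chroms=2, chrom_length=1_500_000,
                    n_genes=250, n_peaks=500)
    return cfg, simulate_all(cfg)
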