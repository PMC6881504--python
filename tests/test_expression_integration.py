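import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special

from acylprofiler.errors import ValidationError
from acylprofiler.expression_integration import (combination_analysis,
                                                 expression_groups,
                                                 format_pvalue, kolmogorov_sf,
                                                 ks_two_sample,
                                                 metagene_profile)
from acylprofiler.genome_io import CoverageTrack, ExpressionTable

from helpers_oracles import ks_d_bruteforce


class TestExpressionGroups:
    def test_silent_plus_quintiles(self):
        fpkm = {f"g{i}": 0.0 for i in range(5)}
        fpkm.update({f"h{i}": float(i + 1) for i in range(5)})
        groups = expression_groups(ExpressionTable(fpkm=fpkm))
        assert sum(1 for v in groups.values() if v == "silent") == 5
        labels = [groups[f"h{i}"] for i in range(5)]
        assert len(set(labels)) == 5  # each expressed gene in its own quintile
        assert groups["h4"] == "top20"  # highest FPKM in the top group

    def test_quintile_boundaries_match_sort_oracle(self):
        rng = np.random.default_rng(31)
        fpkm = {f"g{i:03d}": float(v)
                for i, v in enumerate(rng.lognormal(1, 2, 200))}
        groups = expression_groups(ExpressionTable(fpkm=fpkm))
        order = sorted(fpkm, key=lambda g: (-fpkm[g], g))
        for i, g in enumerate(order):
            expected = ["top20", "q20_40", "q40_60", "q60_80", "q80_100"][i // 40]
            assert groups[g] == expected

    def test_ties_deterministic_and_balanced(self):
        fpkm = {f"g{i}": 3.0 for i in range(11)}
        g1 = expression_groups(ExpressionTable(fpkm=fpkm))
        g2 = expression_groups(ExpressionTable(fpkm=dict(reversed(list(fpkm.items())))))
        assert g1 == g2
        sizes = [sum(1 for v in g1.values() if v == lab)
                 for lab in ("top20", "q20_40", "q40_60", "q60_80", "q80_100")]
        assert max(sizes) - min(sizes) <= 1

    def test_partition_every_gene_once(self):
        rng = np.random.default_rng(32)
        fpkm = {f"g{i}": float(max(v, 0))
                for i, v in enumerate(rng.normal(2, 3, 100))}
        groups = expression_groups(ExpressionTable(fpkm=fpkm))
        assert set(groups) == set(fpkm)


def flat_track(ann, depth, total_mapped):
    segs = {c: (np.array([0]), np.array([L]), np.array([float(depth)]))
            for c, L in ann.chrom_lengths.items()}
    return CoverageTrack(segs, total_mapped=total_mapped)


class TestMetageneProfile:
    def test_uniform_depth_gives_flat_analytic_value(self, toy_annotation):
        d, tm = 3.0, 1_000_000
        track = flat_track(toy_annotation, d, tm)
        groups = {g.gene_id: "all" for g in toy_annotation.genes}
        prof = metagene_profile(track, toy_annotation, groups)
        expected = d * (1e6 / tm) * 50  # per-kb, per-million normalisation
        np.testing.assert_allclose(prof.density[0], expected)

    def test_zero_coverage_zero_profile(self, toy_annotation):
        track = CoverageTrack({"chr1": (np.array([0]), np.array([1]),
                                        np.array([0.0]))}, total_mapped=10)
        groups = {g.gene_id: "all" for g in toy_annotation.genes}
        prof = metagene_profile(track, toy_annotation, groups)
        assert (prof.density == 0).all()

    def test_rectangular_block_downstream_of_plus_tss(self, toy_annotation):
        # geneA: + strand, TSS 5000.  Depth h on [5000, 5200) only.
        h, tm = 4.0, 2_000_000
        track = CoverageTrack({"chr1": (np.array([5000]), np.array([5200]),
                                        np.array([h]))}, total_mapped=tm)
        prof = metagene_profile(track, toy_annotation, {"geneA": "g"})
        dens = prof.density[0]
        expected_bin = h / 0.02 / (tm / 1e6)
        # bins 50..59 cover [TSS, TSS+200); everything else is zero
        np.testing.assert_allclose(dens[50:60], expected_bin)
        assert (dens[:50] == 0).all() and (dens[60:] == 0).all()

    def test_mass_conservation_per_gene(self, toy_annotation):
        rng = np.random.default_rng(33)
        starts = np.sort(rng.choice(np.arange(4000, 9000), 20, replace=False))
        segs = (starts[::2], starts[1::2], rng.integers(1, 6, 10).astype(float))
        track = CoverageTrack({"chr1": segs}, total_mapped=500)
        prof = metagene_profile(track, toy_annotation, {"geneA": "g"})
        # sum(density * 0.02 kb * total_mapped/1e6) = mean-depth sum = mass/20
        recovered = prof.density[0].sum() * 0.02 * (500 / 1e6)
        window_mass = track.mass("chr1", 4000, 6000)[0]
        assert recovered == pytest.approx(window_mass / 20.0)

    def test_strand_equivariance_under_genome_mirroring(self, toy_annotation):
        # mirror chr1 and flip strands: profiles must be unchanged
        from acylprofiler.genome_io import (GeneModel, GenomeAnnotation,
                                            GenomicInterval)
        L = toy_annotation.chrom_lengths["chr1"]
        rng = np.random.default_rng(34)
        bounds = np.sort(rng.choice(np.arange(3000, 17000), 40, replace=False))
        vals = rng.integers(1, 5, 20).astype(float)
        track = CoverageTrack({"chr1": (bounds[::2], bounds[1::2], vals)},
                              total_mapped=100)

        def mirror_iv(iv):
            flip = {"+": "-", "-": "+", ".": "."}
            return GenomicInterval(iv.chrom, L - iv.end, L - iv.start,
                                   flip[iv.strand])

        genes1 = [g for g in toy_annotation.genes if g.interval.chrom == "chr1"]
        mirrored = [GeneModel(g.gene_id, mirror_iv(g.interval),
                              [(c, mirror_iv(iv)) for c, iv in g.features])
                    for g in genes1]
        ann_m = GenomeAnnotation(chrom_lengths={"chr1": L}, genes=mirrored)
        track_m = CoverageTrack(
            {"chr1": ((L - bounds[1::2])[::-1], (L - bounds[::2])[::-1],
                      vals[::-1])}, total_mapped=100)
        groups = {g.gene_id: "all" for g in genes1}
        ann1 = GenomeAnnotation(chrom_lengths={"chr1": L}, genes=genes1)
        p1 = metagene_profile(track, ann1, groups)
        p2 = metagene_profile(track_m, ann_m, groups)
        np.testing.assert_allclose(p1.density, p2.density, atol=1e-9)

    def test_zero_total_mapped_rejected(self, toy_annotation):
        with pytest.raises(ValidationError):
            CoverageTrack({}, total_mapped=0)


class TestKsTwoSample:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        d, p = ks_two_sample(x, x)
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_d_matches_ecdf_sweep_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(3, 40))
            y = rng.normal(0.4, 1.3, rng.integers(3, 40))
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(ks_d_bruteforce(list(x), list(y)), abs=1e-12)

    def test_p_matches_reference_kolmogorov_sf(self):
        # the in-package theta-series tail vs scipy's independent implementation
        for x in np.linspace(0.01, 3.5, 300):
            assert kolmogorov_sf(float(x)) == pytest.approx(
                float(special.kolmogorov(x)), abs=1e-9)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=25),
           st.lists(st.floats(-50, 50), min_size=2, max_size=25))
    def test_symmetry(self, x, y):
        assert ks_two_sample(x, y) == ks_two_sample(y, x)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 25)
        d1, _ = ks_two_sample(x, y)
        d2, _ = ks_two_sample(np.exp(x), np.exp(y))
        assert d1 == pytest.approx(d2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([], [1.0])

    def test_floor_display(self):
        assert format_pvalue(1e-20) == "< 2.2e-16"
        assert format_pvalue(0.5) == "0.5"


class TestCombinationAnalysis:
    def make_expr(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionTable(fpkm={f"g{i}": float(v) for i, v in
                                     enumerate(rng.lognormal(1, 1, n))})

    def test_empty_other_gives_na_comparisons(self):
        expr = self.make_expr()
        res = combination_analysis({"g0", "g1"}, set(), expr)
        assert res.group("both").n == 0
        both_tests = [t for t in res.tests if "both" in (t.group_a, t.group_b)]
        assert all(t.p is None for t in both_tests)

    def test_disjoint_marks_empty_both(self):
        expr = self.make_expr()
        res = combination_analysis({"g0"}, {"g1"}, expr)
        assert res.group("both").n == 0

    def test_groups_partition_universe(self):
        expr = self.make_expr(50)
        res = combination_analysis({f"g{i}" for i in range(20)},
                                   {f"g{i}" for i in range(10, 30)}, expr)
        parts = [res.group(l).n for l in ("both", "kbu_only", "other_only",
                                          "neither")]
        assert sum(parts) == res.group("all").n == 50

    def test_simulated_coupling_orders_medians(self, small_sim):
        cfg, data = small_sim
        from acylprofiler.peak_annotation import assign_genes
        ann = data["annotation"]
        kbu = assign_genes(data["peaks"]["Kbu"], ann)
        other = assign_genes(data["peaks"]["H3K9ac"], ann)
        res = combination_analysis(kbu, other, data["expression"])
        med = {l: res.group(l).summary["median"]
               for l in ("both", "kbu_only", "neither")}
        assert med["both"] >= med["kbu_only"] >= med["neither"]
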