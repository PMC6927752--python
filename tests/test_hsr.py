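import numpy as np
import pandas as pd
import pytest

from hsekit.core import GeneModel, GenomicInterval
from hsekit.hsr import (
    call_hsr_genes,
    call_up_genes,
    count_upstream_hses,
    min_upstream_distances,
    partition_orthologs,
    proximity_profile,
    upstream_distance,
)


def mk_gene(gid, contig, start, end, strand):
    return GeneModel(gid, GenomicInterval(contig, start, end, strand), strand)


def site(contig, start, end):
    return GenomicInterval(contig, start, end)


class TestCallUpGenes:
    def test_strict_boundaries(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d", "e", "f"],
                "fold_change": [2.0, 21.0, 3.0, 1.5, 5.0, 2.5],
                "padj": [0.001, 1e-6, 0.01, 1e-9, 0.001, 0.5],
            }
        )
        up = call_up_genes(df)
        # a: fc exactly 2 excluded; c: padj exactly 0.01 excluded;
        # d: fc too low; f: padj too high
        assert up == {"b", "e"}

    def test_missing_column_errors(self):
        with pytest.raises(ValueError):
            call_up_genes(pd.DataFrame({"gene_id": ["a"], "fold_change": [3.0]}))

    def test_configurable_thresholds(self):
        df = pd.DataFrame({"gene_id": ["a"], "fold_change": [1.6], "padj": [0.04]})
        assert call_up_genes(df) == set()
        assert call_up_genes(df, fc_threshold=1.5, padj_threshold=0.05) == {"a"}


class TestUpstreamDistance:
    def test_plus_gene_arithmetic(self):
        g = mk_gene("g", "c1", 5000, 6000, "+")
        # nearest base of the site is 2414; 5000 - 2414 = 2586
        assert upstream_distance(g, site("c1", 2400, 2415)) == 2586

    def test_overlap_tss_is_zero(self):
        g = mk_gene("g", "c1", 5000, 6000, "+")
        assert upstream_distance(g, site("c1", 4995, 5010)) == 0
        gm = mk_gene("g", "c1", 4000, 5001, "-")  # tss = 5000
        assert upstream_distance(gm, site("c1", 4995, 5010)) == 0

    def test_downstream_absent(self):
        g = mk_gene("g", "c1", 5000, 6000, "+")
        assert upstream_distance(g, site("c1", 6000, 6015)) is None
        gm = mk_gene("g", "c1", 4000, 5001, "-")
        assert upstream_distance(gm, site("c1", 3000, 3015)) is None

    def test_minus_gene_mirrored(self):
        gm = mk_gene("g", "c1", 4000, 5001, "-")  # tss 5000
        assert upstream_distance(gm, site("c1", 7000, 7015)) == 2000

    def test_other_contig_absent(self):
        g = mk_gene("g", "c1", 5000, 6000, "+")
        assert upstream_distance(g, site("c2", 2400, 2415)) is None

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(8)
        genes = [
            mk_gene(f"g{i}", "c1", int(s), int(s) + 500, "+-"[i % 2])
            for i, s in enumerate(rng.integers(600, 90_000, 60))
        ]
        sites = [site("c1", int(s), int(s) + 15) for s in rng.integers(0, 95_000, 200)]
        got = min_upstream_distances(genes, sites)
        for gi, g in enumerate(genes):
            ds = [upstream_distance(g, s) for s in sites]
            ds = [d for d in ds if d is not None]
            expect = min(ds) if ds else np.inf
            assert got[gi] == expect


class TestProximityProfile:
    def _toy(self):
        genes = []
        sites = [site("c1", 10_000, 10_015), site("c1", 50_000, 50_015)]
        rng = np.random.default_rng(1)
        for i in range(60):
            tss = 10_100 + i * 37  # within 2.5 kb of first site
            genes.append(mk_gene(f"near{i}", "c1", tss, tss + 300, "+"))
        for i, s in enumerate(rng.integers(100_000, 400_000, 140)):
            genes.append(mk_gene(f"far{i}", "c1", int(s), int(s) + 300, "+"))
        return genes, sites

    def test_up_equals_all_matches_background(self):
        genes, sites = self._toy()
        up = {g.gene_id for g in genes}
        prof = proximity_profile(up, genes, sites, n_reps=5, seed=0)
        np.testing.assert_allclose(prof.observed, prof.background_mean)
        assert prof.enrichment.p_value == 1.0

    def test_planted_signal_enriched(self):
        genes, sites = self._toy()
        up = {f"near{i}" for i in range(40)} | {f"far{i}" for i in range(5)}
        prof = proximity_profile(up, genes, sites, seed=2)
        assert prof.enrichment.p_value < 0.01
        assert prof.observed_within > prof.expected_within

    def test_seed_reproducible(self):
        genes, sites = self._toy()
        up = {f"near{i}" for i in range(10)}
        p1 = proximity_profile(up, genes, sites, seed=42)
        p2 = proximity_profile(up, genes, sites, seed=42)
        np.testing.assert_array_equal(p1.background_mean, p2.background_mean)
        assert p1.enrichment.p_value == p2.enrichment.p_value

    def test_each_gene_in_at_most_one_bin(self):
        genes, sites = self._toy()
        up = {g.gene_id for g in genes[:80]}
        prof = proximity_profile(up, genes, sites, seed=0)
        assert prof.observed.sum() <= len(up)

    def test_background_converges_to_scaled_frequencies(self):
        genes, sites = self._toy()
        up = {g.gene_id for g in list(genes)[:50]}
        prof = proximity_profile(up, genes, sites, n_reps=400, seed=3)
        dists = min_upstream_distances(genes, sites, max_bp=prof.max_bp)
        frac_within = np.mean(dists < prof.within_cutoff_bp)
        expect = frac_within * len(up)
        sd = np.sqrt(len(up) * frac_within * (1 - frac_within)) / np.sqrt(400)
        assert abs(prof.expected_within - expect) < 3 * sd + 1e-9

    def test_unknown_up_gene_errors(self):
        genes, sites = self._toy()
        with pytest.raises(ValueError):
            proximity_profile({"nope"}, genes, sites)


class TestCallHsrGenes:
    def test_boundary_2499_vs_2500(self):
        # + gene, tss = 5000; site end-1 at 2501 -> distance 2499
        g1 = mk_gene("in", "c1", 5000, 6000, "+")
        s1 = site("c1", 2487, 2502)
        assert upstream_distance(g1, s1) == 2499
        # site end-1 at 2500 -> distance 2500
        s2 = site("c1", 2486, 2501)
        g2 = mk_gene("out", "c1", 5000, 6000, "+")
        up = {"in", "out"}
        assert call_hsr_genes([g1], up, [s1]) == {"in"}
        assert call_hsr_genes([g2], up, [s2]) == set()

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(6)
        genes = [
            mk_gene(f"g{i}", "c1", int(s), int(s) + 200, "+")
            for i, s in enumerate(rng.integers(500, 80_000, 50))
        ]
        sites = [site("c1", int(s), int(s) + 15) for s in rng.integers(0, 80_000, 40)]
        up = {g.gene_id for g in genes}
        prev: set[str] = set()
        for cutoff in (500, 1000, 2500, 5000, 10_000):
            cur = call_hsr_genes(genes, up, sites, cutoff_bp=cutoff)
            assert prev <= cur
            prev = cur

    def test_only_up_genes_called(self):
        g = mk_gene("g", "c1", 5000, 6000, "+")
        s = site("c1", 4000, 4015)
        assert call_hsr_genes([g], set(), [s]) == set()


class TestCountUpstreamHses:
    def test_cluster_of_ten(self):
        g = mk_gene("g", "c1", 5000, 6000, "+")
        sites = [site("c1", 3000 + 20 * i, 3015 + 20 * i) for i in range(10)]
        assert count_upstream_hses(g, sites) == 10

    def test_none_upstream(self):
        g = mk_gene("g", "c1", 5000, 6000, "+")
        assert count_upstream_hses(g, [site("c1", 7000, 7015)]) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(10)
        g = mk_gene("g", "c1", 50_000, 51_000, "-")
        sites = [site("c1", int(s), int(s) + 15) for s in rng.integers(40_000, 60_000, 100)]
        expect = sum(
            1
            for s in sites
            if (d := upstream_distance(g, s)) is not None and d < 2500
        )
        assert count_upstream_hses(g, sites) == expect


class TestPartitionOrthologs:
    def test_disjoint_up_sets_no_shared(self):
        pairs = [("a1", "b1"), ("a2", "b2")]
        part = partition_orthologs({"a1"}, {"b2"}, {"a1"}, {"b2"}, pairs)
        assert part.shared == set()
        assert part.unique_a == {("a1", "b1")}
        assert part.unique_b == {("a2", "b2")}

    def test_identical_sets_all_shared(self):
        pairs = [(f"a{i}", f"b{i}") for i in range(5)]
        ups_a = {f"a{i}" for i in range(5)}
        ups_b = {f"b{i}" for i in range(5)}
        part = partition_orthologs(ups_a, ups_b, ups_a, ups_b, pairs)
        assert part.shared == set(pairs)
        assert not part.unique_a and not part.unique_b

    def test_hand_enumerated_toy(self):
        pairs = [(f"a{i}", f"b{i}") for i in range(10)]
        up_a = {"a0", "a1", "a2", "a3", "a4"}
        up_b = {"b0", "b1", "b5", "b6"}
        hse_a = {"a0", "a2", "a3", "a7"}
        hse_b = {"b0", "b5", "b9"}
        part = partition_orthologs(up_a, up_b, hse_a, hse_b, pairs)
        # qualified A: a0, a2, a3; qualified B: b0, b5
        assert part.shared == {("a0", "b0")}
        assert part.unique_a == {("a2", "b2"), ("a3", "b3")}
        assert part.unique_b == {("a5", "b5")}
        assert part.test.total == 10

    def test_unknown_pairs_skipped(self):
        pairs = [("a1", "b1"), ("aX", "b2")]
        part = partition_orthologs(
            {"a1"}, set(), {"a1"}, set(), pairs, known_a={"a1"}, known_b={"b1", "b2"}
        )
        assert part.test.total == 1
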