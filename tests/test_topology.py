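"""Graph topology: census oracle, rewiring, metrics, motif significance."""

import itertools

import networkx as nx
import numpy as np
import pytest

import spikeconn.topology as topo


def brute_force_census(adj):
    """Count connected-triad classes by explicit isomorphism matching."""
    n = adj.shape[0]
    # canonical signatures of the 13 patterns under all node permutations
    sig_by_id = {}
    for mid, edges in topo.MOTIF_PATTERNS.items():
        a = np.zeros((3, 3), dtype=int)
        for (u, v) in edges:
            a[u, v] = 1
        forms = set()
        for perm in itertools.permutations(range(3)):
            p = np.array(perm)
            forms.add(tuple(a[np.ix_(p, p)].ravel()))
        sig_by_id[mid] = forms
    counts = np.zeros(13, dtype=int)
    extra = 0
    for trio in itertools.combinations(range(n), 3):
        sub = adj[np.ix_(trio, trio)].astype(int)
        np.fill_diagonal(sub, 0)
        sig = tuple(sub.ravel())
        for mid, forms in sig_by_id.items():
            if sig in forms:
                counts[mid - 1] += 1
                break
        else:
            extra += 1
    return counts, extra


def random_digraph(n, p, seed):
    rng = np.random.default_rng(seed)
    a = rng.random((n, n)) < p
    np.fill_diagonal(a, False)
    return a


class TestTriadCensus:
    def test_single_motif_identities(self):
        for mid, edges in topo.MOTIF_PATTERNS.items():
            a = np.zeros((3, 3), dtype=bool)
            for (u, v) in edges:
                a[u, v] = True
            c = topo.triad_census(a)
            assert c[mid - 1] == 1, f"motif {mid} misclassified"
            assert c.sum() == 1

    def test_census_matches_brute_force_enumeration(self):
        g = random_digraph(12, 0.3, seed=5)
        ours = topo.triad_census(g)
        oracle, extra = brute_force_census(g)
        np.testing.assert_array_equal(ours, oracle)

    def test_class_conservation(self):
        g = random_digraph(12, 0.3, seed=6)
        ours = topo.triad_census(g)
        oracle, extra = brute_force_census(g)
        n = g.shape[0]
        assert ours.sum() + extra == n * (n - 1) * (n - 2) // 6


class TestRewiring:
    def test_degrees_and_density_preserved(self):
        g = random_digraph(15, 0.2, seed=7)
        r = topo.rewire_preserving_degrees(g, seed=1)
        assert r.sum() == g.sum()
        np.testing.assert_array_equal(r.sum(0), g.sum(0))
        np.testing.assert_array_equal(r.sum(1), g.sum(1))
        assert not np.any(np.diag(r))

    def test_rewiring_destroys_planted_cliques(self):
        # graph rich in reciprocal cliques: dense blocks on 12 nodes
        g = np.zeros((18, 18), dtype=bool)
        for base in (0, 3, 6, 9):
            trio = range(base, base + 3)
            for u in trio:
                for v in trio:
                    if u != v:
                        g[u, v] = True
        rng = np.random.default_rng(8)
        extra = rng.random((18, 18)) < 0.08
        np.fill_diagonal(extra, False)
        g = g | extra
        before = topo.triad_census(g)[12]
        after = np.mean([topo.triad_census(
            topo.rewire_preserving_degrees(g, seed=k))[12]
            for k in range(5)])
        assert before >= 4
        assert after < before

    def test_too_few_edges_raises(self):
        g = np.zeros((4, 4), dtype=bool)
        g[0, 1] = True
        with pytest.raises(ValueError):
            topo.rewire_preserving_degrees(g, seed=0)


class TestGlobalMetrics:
    def test_complete_and_empty(self):
        n = 6
        full = ~np.eye(n, dtype=bool)
        m = topo.global_metrics(full, small_world=False)
        assert m["density"] == 1.0
        assert m["clustering"] == pytest.approx(1.0)
        empty = np.zeros((n, n), dtype=bool)
        m0 = topo.global_metrics(empty, small_world=False)
        assert m0["density"] == 0.0
        assert m0["efficiency"] == 0.0

    def test_directed_ring_efficiency(self):
        n = 10
        g = np.zeros((n, n), dtype=bool)
        for k in range(n):
            g[k, (k + 1) % n] = True
        m = topo.global_metrics(g, small_world=False)
        # directed ring: d(i, j) = (j - i) mod n; harmonic mean by hand
        oracle = np.mean([1.0 / d for d in range(1, n)])
        assert m["efficiency"] == pytest.approx(oracle)

    def test_binarize_monotone(self):
        rng = np.random.default_rng(9)
        S = rng.uniform(0, 1, (8, 8))
        hi = topo.binarize(S, 0.8)
        lo = topo.binarize(S, 0.2)
        assert not np.any(hi & ~lo)
        assert not topo.binarize(S, 2.0).any()
        full = topo.binarize(S, -1.0)
        assert full.sum() == 8 * 7


class TestNodalMetrics:
    def test_complete_digraph_degrees(self):
        g = ~np.eye(5, dtype=bool)
        nm = topo.nodal_metrics(g)
        assert np.all(nm["in_degree"] == 4)
        assert np.all(nm["out_degree"] == 4)

    def test_isolated_node_zeroes(self):
        g = np.zeros((4, 4), dtype=bool)
        g[0, 1] = g[1, 0] = True
        nm = topo.nodal_metrics(g)
        assert nm["in_degree"][3] == 0
        assert nm["efficiency"][3] == 0

    def test_independent_recomputation(self):
        g = random_digraph(10, 0.25, seed=10)
        nm = topo.nodal_metrics(g)
        G = nx.from_numpy_array(g.astype(int), create_using=nx.DiGraph)
        for v in range(10):
            assert nm["in_degree"][v] == G.in_degree(v)
            assert nm["out_degree"][v] == G.out_degree(v)
            s = 0.0
            lengths = nx.single_source_shortest_path_length(G, v)
            s = sum(1.0 / d for d in lengths.values() if d > 0)
            assert nm["efficiency"][v] == pytest.approx(s / 9)


class TestMotifSignificance:
    def test_null_graph_has_no_flags(self):
        # a graph drawn from the rewired null itself shows ~0 significant
        # motifs at alpha 0.001
        g = random_digraph(14, 0.25, seed=11)
        g = topo.rewire_preserving_degrees(g, seed=12)
        out = topo.motif_significance(g, n_surrogates=50, alpha=0.001,
                                      seed=13)
        assert out["significant"].sum() == 0

    def test_fdr_flags_subset_of_raw(self):
        g = random_digraph(14, 0.3, seed=14)
        out = topo.motif_significance(g, n_surrogates=30, alpha=0.05,
                                      seed=15)
        raw = out["p_raw"] < 0.05
        assert np.all(out["significant"] <= raw)


class TestCompareToGroundTruth:
    def test_identity_comparison(self):
        g = random_digraph(12, 0.2, seed=16)
        cmp_ = topo.compare_to_ground_truth(g, g)
        for k, v in cmp_.global_rel_diff.items():
            assert v == pytest.approx(0.0, abs=1e-12)
        for k, v in cmp_.nodal_pearson.items():
            if not np.isnan(v):
                assert v == pytest.approx(1.0)
        assert np.all(cmp_.motif_abs_diff == 0)

    def test_random_inference_decorrelates(self):
        rhos = []
        gt = random_digraph(15, 0.2, seed=17)
        for k in range(20):
            gi = random_digraph(15, 0.2, seed=100 + k)
            cmp_ = topo.compare_to_ground_truth(gi, gt)
            v = cmp_.nodal_pearson["in_degree"]
            if not np.isnan(v):
                rhos.append(v)
        assert abs(np.mean(rhos)) < 0.15

    def test_denser_inference_positive_density_difference(self):
        gt = random_digraph(12, 0.15, seed=18)
        gi = gt | random_digraph(12, 0.2, seed=19)
        np.fill_diagonal(gi, False)
        cmp_ = topo.compare_to_ground_truth(gi, gt)
        assert cmp_.global_rel_diff["density"] > 0


class TestDistanceDecay:
    def test_single_bin_when_equidistant(self):
        pos = np.array([[0, 0], [100, 0], [50, 50 * np.sqrt(3)]])
        g = np.ones((3, 3), dtype=bool)
        np.fill_diagonal(g, False)
        centers, prob, npairs = topo.distance_decay_curve(
            g, pos, np.array([0, 50, 150]))
        assert npairs[0] == 0 and npairs[1] == 6
        assert prob[1] == 1.0

    def test_exponential_decay_recovery(self):
        rng = np.random.default_rng(20)
        n = 120
        pos = rng.uniform(0, 1500, (n, 2))
        d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
        lam = 300.0
        p = 0.9 * np.exp(-d / lam)
        g = rng.random((n, n)) < p
        np.fill_diagonal(g, False)
        edges = np.arange(0, 1200, 100.0)
        centers, prob, npairs = topo.distance_decay_curve(g, pos, edges)
        ok = (npairs > 200) & (prob > 0)
        slope = np.polyfit(centers[ok], np.log(prob[ok]), 1)[0]
        assert -1.0 / slope == pytest.approx(lam, rel=0.2)

    def test_empty_graph_and_missing_positions(self):
        g = np.zeros((4, 4), dtype=bool)
        pos = np.zeros((4, 2))
        pos[:, 0] = np.arange(4)
        _, prob, _ = topo.distance_decay_curve(g, pos, np.array([0, 2, 4.0]))
        assert np.all(prob == 0)
        with pytest.raises(ValueError):
            topo.distance_decay_curve(g, None, np.array([0, 1.0]))
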