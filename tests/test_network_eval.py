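import numpy as np
import pytest

from scing.data_io import EdgeList
from scing.network_eval import (
    batch_f1,
    batch_mix_f1,
    betweenness_stats,
    degree_preserved_null,
    disease_recovery_gain,
    holdout_cosine,
    neighborhood_score,
    overlap_score,
    scale_free_r2,
    _rwr,
)


def _edge_list(pairs, weights=None):
    return EdgeList(
        source=[p[0] for p in pairs],
        target=[p[1] for p in pairs],
        weight=np.ones(len(pairs)) if weights is None else np.asarray(weights),
    )


class TestHoldoutCosine:
    def test_deterministic_child_scores_high(self, rng):
        parent = rng.normal(5.0, 2.0, 400)
        child = parent.copy()
        noise = rng.normal(5.0, 1.0, (400, 1))
        X = np.column_stack([parent, child, noise])
        res = holdout_cosine(X[:200], X[200:], ["P", "C", "N"],
                             _edge_list([("P", "C")]), seed=0)
        assert res.mean_cosine_train > 0.95
        assert res.mean_cosine_test > 0.9
        assert res.ratio_test_over_train == pytest.approx(1.0, abs=0.1)

    def test_shuffled_test_collapses_ratio(self, rng):
        parent = rng.normal(5.0, 2.0, 400)
        child = parent + 0.3 * rng.normal(size=400)
        X = np.column_stack([parent, child])
        test = X[200:].copy()
        test[:, 1] = rng.permutation(test[:, 1])  # break the relationship
        res = holdout_cosine(X[:200], test, ["P", "C"],
                             _edge_list([("P", "C")]), seed=0)
        assert res.ratio_test_over_train < 0.3

    def test_no_parents_rejected(self, rng):
        X = rng.random((20, 2))
        empty = EdgeList(source=[], target=[], weight=np.empty(0))
        with pytest.raises(ValueError, match="no gene has parents"):
            holdout_cosine(X, X, ["a", "b"], empty)


class TestScaleFreeR2:
    def test_exact_power_law_r2_one(self):
        # a graph whose degree histogram follows p(k) ∝ k^-2 exactly over
        # k in {1,2,4,8} is exactly linear in log-log: R^2 = 1
        import networkx as nx

        seq = [1] * 64 + [2] * 16 + [4] * 4 + [8]  # counts ∝ 1/k^2
        g = nx.havel_hakimi_graph(seq)
        pairs = [(f"n{a}", f"n{b}") for a, b in g.edges]
        assert scale_free_r2(_edge_list(pairs)) == pytest.approx(1.0,
                                                                 abs=1e-12)

    def test_regular_graph_rejected(self):
        # 4-cycle: all degrees equal -> undefined fit
        grn = _edge_list([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        with pytest.raises(ValueError):
            scale_free_r2(grn)

    def test_matches_hand_regression(self, rng):
        from scipy.stats import linregress

        # star plus chain gives >= 3 distinct degrees
        pairs = [("hub", f"leaf{i}") for i in range(6)]
        pairs += [("leaf0", "leaf1"), ("leaf1", "leaf2")]
        grn = _edge_list(pairs)
        r2 = scale_free_r2(grn)
        import networkx as nx

        g = nx.Graph(pairs)
        degs = np.array([d for _, d in g.degree()])
        uniq, cnt = np.unique(degs, return_counts=True)
        fit = linregress(np.log10(uniq), np.log10(cnt / cnt.sum()))
        assert r2 == pytest.approx(fit.rvalue**2, abs=1e-10)

    def test_sparsity_threshold_excludes_genes(self):
        pairs = [("hub", f"leaf{i}") for i in range(5)]
        pairs += [("leaf0", "leaf1"), ("leaf1", "leaf2"), ("leaf2", "leaf3")]
        sparsity = {f"leaf{i}": 0.0 for i in range(5)}
        sparsity["hub"] = 0.9  # excluded
        grn = _edge_list(pairs)
        r2_all = scale_free_r2(grn)
        r2_filtered = scale_free_r2(grn, gene_sparsity=sparsity,
                                    sparsity_threshold=0.7)
        assert r2_all != pytest.approx(r2_filtered)


class TestBetweenness:
    def test_star_graph_hand_count(self):
        grn = _edge_list([("c", f"l{i}") for i in range(4)])
        var = betweenness_stats(grn)
        vals = np.array([1.0, 0, 0, 0, 0])
        assert var == pytest.approx(vals.var())

    def test_complete_graph_zero_variance(self):
        nodes = ["a", "b", "c", "d"]
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        assert betweenness_stats(_edge_list(pairs)) == pytest.approx(0.0)

    def test_path_of_three(self):
        grn = _edge_list([("a", "b"), ("b", "c")])
        vals = np.array([0.0, 1.0, 0.0])
        assert betweenness_stats(grn) == pytest.approx(vals.var())

    def test_matches_brute_force_small_graphs(self, rng):
        import itertools
        import networkx as nx

        g = nx.gnp_random_graph(12, 0.3, seed=4)
        pairs = [(f"n{a}", f"n{b}") for a, b in g.edges]
        var = betweenness_stats(_edge_list(pairs))
        # brute force: count shortest paths through each node
        nodes = list(g.nodes)
        bc = dict.fromkeys(nodes, 0.0)
        for s, t in itertools.combinations(nodes, 2):
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                frac = sum(v in p for p in paths) / len(paths)
                bc[v] += frac
        norm = (len(nodes) - 1) * (len(nodes) - 2) / 2
        vals = np.array([bc[v] / norm for v in nodes])
        assert var == pytest.approx(vals.var(), abs=1e-12)


class TestOverlapScore:
    def test_identical_complete_graphs_score_one(self):
        nodes = [f"g{i}" for i in range(6)]
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        assert overlap_score(_edge_list(pairs), _edge_list(pairs), 6) == \
            pytest.approx(1.0)

    def test_disjoint_edge_sets_score_zero(self):
        a = _edge_list([("a", "b"), ("c", "d")])
        b = _edge_list([("a", "c"), ("b", "d")])
        assert overlap_score(a, b, 4) == 0.0

    def test_random_pairs_calibrated_to_one(self):
        rng = np.random.default_rng(0)
        n_genes, m = 30, 50
        genes = [f"g{i}" for i in range(n_genes)]
        all_pairs = [(a, b) for i, a in enumerate(genes)
                     for b in genes[i + 1 :]]
        scores = []
        for _ in range(1000):
            ia = rng.choice(len(all_pairs), m, replace=False)
            ib = rng.choice(len(all_pairs), m, replace=False)
            a = _edge_list([all_pairs[i] for i in ia])
            b = _edge_list([all_pairs[i] for i in ib])
            scores.append(overlap_score(a, b, n_genes))
        scores = np.array(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean() - 1.0) <= 3 * se

    def test_self_overlap_closed_form(self, rng):
        genes = [f"g{i}" for i in range(10)]
        all_pairs = [(a, b) for i, a in enumerate(genes)
                     for b in genes[i + 1 :]]
        idx = rng.choice(len(all_pairs), 12, replace=False)
        net = _edge_list([all_pairs[i] for i in idx])
        M = 10 * 9 / 2
        assert overlap_score(net, net, 10) == pytest.approx(M / 12)


class TestRwrAndDiseaseRecovery:
    def test_rwr_probability_conservation(self, rng):
        import networkx as nx

        g = nx.gnp_random_graph(20, 0.3, seed=1)
        A = nx.to_numpy_array(g)
        seeds = np.zeros(20)
        seeds[[0, 3, 7]] = 1.0
        p = _rwr(A, seeds, restart=0.5)
        assert p.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(p >= 0)

    def test_null_degree_sequence_preserved(self):
        import networkx as nx

        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        pairs = set()
        while len(pairs) < 60:
            a, b = rng.choice(30, 2, replace=False)
            pairs.add((genes[min(a, b)], genes[max(a, b)]))
        grn = _edge_list(sorted(pairs))
        g0 = nx.Graph(sorted(pairs))
        orig = sorted(dict(g0.degree()).items())
        for b in range(10):
            null = degree_preserved_null(grn, seed=b)
            assert sorted(dict(null.degree()).items()) == orig

    def test_planted_community_gene_set_recovers(self):
        rng = np.random.default_rng(3)
        # dense 20-gene community inside a 120-node sparse background
        comm = [f"c{i}" for i in range(20)]
        rest = [f"r{i}" for i in range(100)]
        pairs = set()
        for i, a in enumerate(comm):
            for b in comm[i + 1 :]:
                if rng.random() < 0.4:
                    pairs.add((a, b))
        nodes = comm + rest
        while len(pairs) < 260:
            a, b = rng.choice(120, 2, replace=False)
            if a != b:
                pairs.add((nodes[min(a, b)], nodes[max(a, b)]))
        grn = _edge_list(sorted(pairs))
        res = disease_recovery_gain(grn, comm, n_null=20, n_splits=5, seed=0)
        assert res.gain_z > 2

    def test_random_gene_sets_mostly_null(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(60)]
        pairs = set()
        while len(pairs) < 150:
            a, b = rng.choice(60, 2, replace=False)
            pairs.add((genes[min(a, b)], genes[max(a, b)]))
        grn = _edge_list(sorted(pairs))
        inside = 0
        trials = 8
        for t in range(trials):
            gene_set = list(rng.choice(genes, 14, replace=False))
            res = disease_recovery_gain(grn, gene_set, n_null=15, n_splits=5,
                                        seed=t)
            inside += abs(res.gain_z) <= 2
        assert inside >= int(0.7 * trials)


class TestNeighborhoodScoreAndF1:
    def test_uniform_labels_score_one(self, rng):
        coords = rng.random((20, 3))
        ns = neighborhood_score(coords, np.zeros(20, dtype=int), k=5)
        assert ns.neigh_score == pytest.approx(1.0)

    def test_alternating_ring_k2_exactly_zero(self):
        # alternating labels on a ring: both nearest neighbors always have
        # the opposite label
        theta = 2 * np.pi * np.arange(10) / 10
        coords = np.column_stack([np.cos(theta), np.sin(theta)])
        labels = np.arange(10) % 2
        ns = neighborhood_score(coords, labels, k=2)
        assert ns.neigh_score == pytest.approx(0.0)

    def test_alternating_line_k2_hand_count(self):
        # interior points see two opposite-parity neighbors; each endpoint's
        # second-nearest neighbor shares its parity -> mean = 2*(1/2)/10
        coords = np.arange(10, dtype=float)[:, None]
        labels = np.arange(10) % 2
        ns = neighborhood_score(coords, labels, k=2)
        assert ns.neigh_score == pytest.approx(0.1)

    def test_segregated_blocks_near_one(self):
        coords = np.concatenate([np.arange(10.0), np.arange(100.0, 110.0)])
        labels = np.repeat([0, 1], 10)
        ns = neighborhood_score(coords[:, None], labels, k=2)
        assert ns.neigh_score == pytest.approx(1.0)

    def test_f1_direct_substitution(self):
        assert batch_mix_f1(0.0, 0.0, 1.0) == pytest.approx(2 / 3)

    def test_f1_zero_when_factor_zero(self):
        assert batch_mix_f1(1.0, 0.0, 1.0) == 0.0
        assert batch_mix_f1(0.0, 0.0, 0.0) == 0.0

    def test_f1_sample_batch_swap_symmetry(self, rng):
        for _ in range(20):
            a, b, c = rng.random(3)
            assert batch_mix_f1(a, b, c) == pytest.approx(batch_mix_f1(b, a, c))

    def test_batch_f1_pipeline(self):
        from scing.synthetic import simulate_batched_phenotypes

        X, labels = simulate_batched_phenotypes(
            300, phenotype_effect=4.0, batch_effect=0.0, seed=0
        )
        res = batch_f1(X, labels, neighbor_fracs=(0.02, 0.08), n_pcs=5)
        assert len(res) == 2
        for r in res:
            assert 0 <= r.F1_phenotype <= 1
            assert r.neigh_score_phenotype > 0.5  # signal separates phenotypes

    def test_k_below_one_rejected(self, rng):
        X, labels = np.random.default_rng(0).random((50, 4)), {
            "sample": np.zeros(50), "batch": np.zeros(50),
            "phenotype": np.zeros(50)}
        with pytest.raises(ValueError):
            batch_f1(X, labels, neighbor_fracs=(0.001,), n_pcs=2)
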