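import numpy as np
import pytest
from scipy.stats import chi2

from scing.consensus import (
    ConsensusGRN,
    discretize_equal_frequency,
    estimate_cmi,
    merge_networks,
    prune_triads,
    remove_cycles,
    resolve_bidirectional,
)
from scing.grn_subsample import SubsampleNetwork
from scing.supercell import SupercellMatrix


def _net(edges, index=0):
    return SubsampleNetwork(
        regulators=[e[0] for e in edges],
        targets=[e[1] for e in edges],
        importances=np.array([e[2] for e in edges], dtype=float),
        subsample_index=index,
    )


def _grn(edges):
    return ConsensusGRN(
        edges={(s, t): w for s, t, w in edges},
        support={(s, t): 1 for s, t, _ in edges},
        n_networks=1,
    )


def brute_force_cmi(counts: np.ndarray) -> float:
    """Independent plug-in CMI oracle from a 3-way contingency table."""
    n = counts.sum()
    I = 0.0
    Bx, By, Bz = counts.shape
    for k in range(Bz):
        nz = counts[:, :, k].sum()
        for i in range(Bx):
            for j in range(By):
                c = counts[i, j, k]
                if c > 0:
                    nxz = counts[i, :, k].sum()
                    nyz = counts[:, j, k].sum()
                    I += (c / n) * np.log(c * nz / (nxz * nyz))
    return I


class TestMergeNetworks:
    def test_twenty_percent_threshold_inclusive(self):
        nets = [_net([("A", "B", 0.1)], i) for i in range(20)]
        nets += [_net([("C", "D", 0.1), ("A", "B", 0.1)], 20 + i)
                 for i in range(0)]
        filler = [_net([("X", "Y", 0.5)], 100 + i) for i in range(80)]
        grn = merge_networks(nets + filler, consensus_frac=0.2)
        assert ("A", "B") in grn.edges  # 20/100 kept
        nets19 = [_net([("A", "B", 0.1)], i) for i in range(19)]
        filler81 = [_net([("X", "Y", 0.5)], 100 + i) for i in range(81)]
        grn19 = merge_networks(nets19 + filler81, consensus_frac=0.2)
        assert ("A", "B") not in grn19.edges  # 19/100 dropped

    def test_weight_is_sum_over_supporting_networks(self):
        nets = [
            _net([("A", "B", 0.2)], 0),
            _net([("A", "B", 0.3)], 1),
            _net([("C", "D", 0.1)], 2),
            _net([("C", "D", 0.1)], 3),
            _net([("E", "F", 0.1)], 4),
        ]
        grn = merge_networks(nets, consensus_frac=0.2)
        assert grn.edges[("A", "B")] == pytest.approx(0.5)
        assert grn.support[("A", "B")] == 2

    def test_single_network_identity(self):
        grn = merge_networks([_net([("A", "B", 0.4), ("B", "C", 0.6)])], 0.2)
        assert set(grn.edges) == {("A", "B"), ("B", "C")}


class TestResolveBidirectional:
    def test_25_percent_stronger_removes_reverse(self):
        grn = _grn([("A", "B", 1.3), ("B", "A", 1.0)])
        out = resolve_bidirectional(grn, ratio=1.25)
        assert ("A", "B") in out.edges and ("B", "A") not in out.edges
        assert ((("B", "A"), "direction")) in out.prune_log

    def test_below_ratio_keeps_both(self):
        out = resolve_bidirectional(_grn([("A", "B", 1.2), ("B", "A", 1.0)]))
        assert len(out.edges) == 2

    def test_equal_weights_keep_both(self):
        out = resolve_bidirectional(_grn([("A", "B", 1.0), ("B", "A", 1.0)]))
        assert len(out.edges) == 2


class TestRemoveCycles:
    def test_triangle_min_weight_edge_removed(self):
        out = remove_cycles(_grn([("A", "B", 3.0), ("B", "C", 2.0),
                                  ("C", "A", 1.0)]))
        assert ("C", "A") not in out.edges
        assert len(out.edges) == 2

    def test_dag_unchanged(self):
        edges = [("A", "B", 1.0), ("A", "C", 2.0), ("B", "C", 3.0)]
        out = remove_cycles(_grn(edges))
        assert len(out.edges) == 3

    def test_two_cycle_preserved(self):
        out = remove_cycles(_grn([("A", "B", 1.0), ("B", "A", 2.0)]))
        assert len(out.edges) == 2

    def test_long_cycle_through_bidirectional_pair(self):
        # cycle A->B->C->A of length 3 where A<->B is a kept pair: only the
        # cycle's minimum-weight edge goes, not the whole pair
        edges = [("A", "B", 5.0), ("B", "A", 4.5), ("B", "C", 2.0),
                 ("C", "A", 3.0)]
        out = remove_cycles(_grn(edges))
        assert ("B", "C") not in out.edges  # min weight in the 3-cycle
        assert ("A", "B") in out.edges and ("B", "A") in out.edges

    def test_no_length3_cycle_remains(self, rng):
        # independent acyclicity check with networkx on random graphs
        import networkx as nx

        for seed in range(5):
            r = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(10)]
            edges = {}
            for _ in range(30):
                a, b = r.choice(10, 2, replace=False)
                edges[(genes[a], genes[b])] = float(r.random()) + 0.01
            out = remove_cycles(
                ConsensusGRN(edges=dict(edges),
                             support={k: 1 for k in edges}, n_networks=1)
            )
            G = nx.DiGraph(list(out.edges))
            for cyc in nx.simple_cycles(G):
                assert len(cyc) <= 2


class TestEstimateCmi:
    def test_independent_bits_exact_product_counts(self):
        # X,Y independent uniform bits with exact product counts, Z constant
        x = np.repeat([0, 0, 1, 1], 25)
        y = np.tile(np.repeat([0, 1], 25), 2)
        z = np.zeros(100, dtype=int)
        res = estimate_cmi(x, y, z)
        assert res.I_hat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_perfect_copy_highly_significant(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 1000)
        res = estimate_cmi(x, x.copy(), np.zeros(1000, dtype=int))
        # closed form: I = H(X) for a perfect copy
        p = np.array([(x == v).mean() for v in (0, 1)])
        H = float(-(p * np.log(p)).sum())
        assert res.I_hat == pytest.approx(H, abs=1e-12)
        assert res.G > 100
        assert res.p_value < 1e-6

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(20, 200))
            bx, by, bz = rng.integers(2, 5, size=3)
            x = rng.integers(0, bx, n)
            y = rng.integers(0, by, n)
            z = rng.integers(0, bz, n)
            res = estimate_cmi(x, y, z)
            counts = np.zeros((bx, by, bz))
            np.add.at(counts, (x, y, z), 1.0)
            # drop empty symbol planes to mirror observed-symbol convention
            counts = counts[counts.sum(axis=(1, 2)) > 0]
            counts = counts[:, counts.sum(axis=(0, 2)) > 0, :]
            counts = counts[:, :, counts.sum(axis=(0, 1)) > 0]
            I = brute_force_cmi(counts)
            assert res.I_hat == pytest.approx(I, abs=1e-9)
            Bx, By, Bz = counts.shape
            df = (Bx - 1) * (By - 1) * Bz
            if df > 0 and I > 0:
                assert res.p_value == pytest.approx(
                    chi2.sf(2 * n * I, df), abs=1e-9
                )

    def test_single_symbol_variable(self):
        res = estimate_cmi(np.zeros(20, int), np.arange(20) % 2,
                           np.arange(20) % 3)
        assert res.I_hat == 0.0 and res.p_value == 1.0

    def test_nonnegative_and_relabel_invariant(self, rng):
        x = rng.integers(0, 3, 150)
        y = rng.integers(0, 3, 150)
        z = rng.integers(0, 2, 150)
        a = estimate_cmi(x, y, z)
        b = estimate_cmi(2 - x, 10 * y + 5, 1 - z)
        assert a.I_hat >= 0
        assert a.I_hat == pytest.approx(b.I_hat, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_cmi(np.zeros(5), np.zeros(5), np.zeros(5))


class TestDiscretize:
    def test_equal_frequency_bins(self):
        bins = discretize_equal_frequency(np.arange(100, dtype=float), 4)
        assert np.bincount(bins).tolist() == [25, 25, 25, 25]

    def test_boundary_ties_to_lower_bin(self):
        values = np.array([0.0, 1.0, 1.0, 2.0])
        bins = discretize_equal_frequency(values, 2)
        assert bins[1] == bins[2] == bins[0] == 0  # median ties fall low
        assert bins[3] == 1


class TestPruneTriads:
    def _expression(self, cols):
        X = np.column_stack(list(cols.values()))
        return SupercellMatrix(values=X, gene_ids=list(cols), membership=np.arange(X.shape[0]))

    def test_fork_with_spurious_edge_removed(self):
        removed = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=500)
            x = z + 0.3 * rng.normal(size=500)
            y = z + 0.3 * rng.normal(size=500)
            expr = self._expression({"Z": z, "X": x, "Y": y})
            grn = _grn([("Z", "X", 1.0), ("Z", "Y", 1.0), ("X", "Y", 0.5)])
            out = prune_triads(grn, expr, alpha=0.05, bins=4)
            removed += ("X", "Y") not in out.edges
        assert removed >= 9

    def test_direct_effect_retained(self):
        retained = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=500)
            x = z + 0.3 * rng.normal(size=500)
            y = z + 2.0 * x + 0.3 * rng.normal(size=500)
            expr = self._expression({"Z": z, "X": x, "Y": y})
            grn = _grn([("Z", "X", 1.0), ("Z", "Y", 1.0), ("X", "Y", 0.5)])
            out = prune_triads(grn, expr, alpha=0.05, bins=4)
            retained += ("X", "Y") in out.edges
        assert retained >= 9

    def test_no_triads_identity(self, rng):
        expr = self._expression({g: rng.normal(size=50) for g in "ABCD"})
        grn = _grn([("A", "B", 1.0), ("C", "D", 1.0)])
        out = prune_triads(grn, expr)
        assert set(out.edges) == {("A", "B"), ("C", "D")}

    def test_idempotent_on_own_output(self, rng):
        cols = {g: rng.normal(size=300) for g in "ABCDEF"}
        cols["B"] = cols["A"] + 0.2 * rng.normal(size=300)
        cols["C"] = cols["A"] + 0.2 * rng.normal(size=300)
        expr = self._expression(cols)
        grn = _grn([("A", "B", 1.0), ("A", "C", 1.0), ("B", "C", 0.4),
                    ("D", "E", 1.0)])
        once = prune_triads(grn, expr)
        twice = prune_triads(once, expr)
        assert set(once.edges) == set(twice.edges)
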