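"""Consensus GRN assembly: edge-frequency merge of subsample networks,
reversed-edge resolution, cycle removal and conditional-mutual-information
triad pruning.

The fixed order is merge -> resolve_bidirectional -> remove_cycles ->
prune_triads.  Bidirectional pairs whose weights are within the direction
ratio are kept as 2-cycles; only directed cycles with three or more edges
are broken, each by deleting its minimum-weight edge.  Triad pruning tests
the dependence left between two linked genes X and Y after conditioning on
a shared network parent Z, via a G-test on the plug-in conditional mutual
information of equal-frequency-discretized supercell expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .data_io import EdgeList
from .grn_subsample import SubsampleNetwork
from .supercell import SupercellMatrix

logger = logging.getLogger("scing")


@dataclass
class ConsensusGRN:
    """Directed weighted consensus network with per-edge support counts.

    ``weight`` is the sum of subsample importances, ``support`` the number of
    subsample networks containing the edge.  ``prune_log`` records removed
    edges with reason 'direction', 'cycle' or 'cmi'.
    """

    edges: dict[tuple[str, str], float]
    support: dict[tuple[str, str], int]
    n_networks: int
    prune_log: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> list[str]:
        out: set[str] = set()
        for s, t in self.edges:
            out.add(s)
            out.add(t)
        return sorted(out)

    def remove_edge(self, edge: tuple[str, str], reason: str) -> None:
        del self.edges[edge]
        self.support.pop(edge, None)
        self.prune_log.append((edge, reason))

    def to_edge_list(self) -> EdgeList:
        items = sorted(self.edges.items())
        return EdgeList(
            source=[e[0][0] for e in items],
            target=[e[0][1] for e in items],
            weight=np.array([e[1] for e in items], dtype=float),
            support=np.array([self.support[e[0]] for e in items], dtype=int),
        )

    def copy(self) -> "ConsensusGRN":
        return ConsensusGRN(
            edges=dict(self.edges),
            support=dict(self.support),
            n_networks=self.n_networks,
            prune_log=list(self.prune_log),
        )


@dataclass
class CmiTestResult:
    """G-test of conditional independence X ⟂ Y | Z on discrete symbols."""

    x: str
    y: str
    z: str
    I_hat: float  # plug-in conditional mutual information, nats
    G: float  # 2 n I_hat
    df: int
    p_value: float
    n: int
    bins: tuple[int, int, int]


def merge_networks(
    nets: list[SubsampleNetwork], consensus_frac: float = 0.2
) -> ConsensusGRN:
    """Keep edges appearing in at least ``consensus_frac`` of the subsample
    networks (inclusive threshold); weights sum over supporting networks."""
    if not nets:
        raise ValueError("need at least one subsample network")
    weight: dict[tuple[str, str], float] = {}
    support: dict[tuple[str, str], int] = {}
    for net in nets:
        for reg, tgt, imp in net.edges():
            key = (reg, tgt)
            weight[key] = weight.get(key, 0.0) + float(imp)
            support[key] = support.get(key, 0) + 1
    n = len(nets)
    threshold = consensus_frac * n - 1e-9
    kept = {k: w for k, w in weight.items() if support[k] >= threshold}
    return ConsensusGRN(
        edges=kept,
        support={k: support[k] for k in kept},
        n_networks=n,
    )


def resolve_bidirectional(grn: ConsensusGRN, ratio: float = 1.25) -> ConsensusGRN:
    """Where both directions of a pair survive consensus, drop the weaker
    direction if the stronger is at least ``ratio`` times its weight;
    otherwise keep the pair bidirectional."""
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    out = grn.copy()
    for s, t in sorted(grn.edges):
        if s >= t:
            continue
        fwd, rev = (s, t), (t, s)
        if fwd in out.edges and rev in out.edges:
            w_f, w_r = out.edges[fwd], out.edges[rev]
            hi, lo = (fwd, rev) if w_f >= w_r else (rev, fwd)
            if out.edges[hi] >= ratio * out.edges[lo] and out.edges[hi] > out.edges[lo]:
                out.remove_edge(lo, "direction")
    return out


def _find_long_cycle(
    edges: dict[tuple[str, str], float],
) -> list[tuple[str, str]] | None:
    """Locate a simple directed cycle with >= 3 edges, deterministically.

    For each edge (u, v) in sorted order, search for a shortest path v -> u
    that does not use the direct edge (v, u); any such path plus (u, v)
    closes a simple cycle of length >= 3.  BFS with sorted adjacency keeps
    the result deterministic.
    """
    adj: dict[str, list[str]] = {}
    for s, t in sorted(edges):
        adj.setdefault(s, []).append(t)
    for u, v in sorted(edges):
        # BFS from v to u, forbidding the single-step v -> u edge
        parent: dict[str, str | None] = {v: None}
        queue = [v]
        found = False
        while queue and not found:
            node = queue.pop(0)
            for nxt in adj.get(node, []):
                if node == v and nxt == u:
                    continue  # would close a 2-cycle
                if nxt in parent:
                    continue
                parent[nxt] = node
                if nxt == u:
                    found = True
                    break
                queue.append(nxt)
        if found:
            path = [u]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])  # type: ignore[arg-type]
            path.reverse()  # v ... u
            cycle = [(path[i], path[i + 1]) for i in range(len(path) - 1)]
            cycle.append((u, v))
            return cycle
    return None


def remove_cycles(grn: ConsensusGRN) -> ConsensusGRN:
    """Break every directed cycle of length >= 3 by deleting its
    minimum-weight edge; 2-cycles (kept bidirectional pairs) survive."""
    out = grn.copy()
    while True:
        cycle = _find_long_cycle(out.edges)
        if cycle is None:
            return out
        victim = min(cycle, key=lambda e: (out.edges[e], e))
        out.remove_edge(victim, "cycle")


def estimate_cmi(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> CmiTestResult:
    """Plug-in conditional mutual information I(X;Y|Z) in nats, with a
    G-test p-value: G = 2 n I, df = (Bx-1)(By-1)Bz using observed distinct
    symbol counts."""
    x = np.asarray(x)
    y = np.asarray(y)
    z = np.asarray(z)
    n = len(x)
    if not (len(y) == len(z) == n):
        raise ValueError("x, y, z must have equal length")
    if n < 8:
        raise ValueError("need at least 8 observations")
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    zs, zi = np.unique(z, return_inverse=True)
    Bx, By, Bz = len(xs), len(ys), len(zs)
    counts = np.zeros((Bx, By, Bz))
    np.add.at(counts, (xi, yi, zi), 1.0)
    I = _cmi_from_counts(counts)
    df = (Bx - 1) * (By - 1) * Bz
    if df <= 0 or I <= 0:
        I = max(I, 0.0)
        p = 1.0
        G = 2.0 * n * I
    else:
        G = 2.0 * n * I
        p = float(chi2.sf(G, df))
    return CmiTestResult(
        x="x", y="y", z="z", I_hat=I, G=G, df=max(df, 0), p_value=p,
        n=n, bins=(Bx, By, Bz),
    )


def _cmi_from_counts(counts: np.ndarray) -> float:
    """I(X;Y|Z) from a Bx x By x Bz contingency array, in nats."""
    n = counts.sum()
    nz = counts.sum(axis=(0, 1))  # per z
    nxz = counts.sum(axis=1)  # Bx x Bz
    nyz = counts.sum(axis=0)  # By x Bz
    I = 0.0
    Bx, By, Bz = counts.shape
    for k in range(Bz):
        if nz[k] == 0:
            continue
        for i in range(Bx):
            for j in range(By):
                c = counts[i, j, k]
                if c == 0:
                    continue
                I += (c / n) * np.log(c * nz[k] / (nxz[i, k] * nyz[j, k]))
    return max(float(I), 0.0)


def discretize_equal_frequency(values: np.ndarray, bins: int = 4) -> np.ndarray:
    """Equal-frequency binning; ties at a bin boundary go to the lower bin."""
    values = np.asarray(values, dtype=float)
    edges = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="left")


def prune_triads(
    grn: ConsensusGRN,
    expression: SupercellMatrix,
    alpha: float = 0.05,
    bins: int = 4,
) -> ConsensusGRN:
    """Remove an edge X-Y when X and Y are conditionally independent given a
    shared network parent Z (CMI G-test p >= alpha).

    Triads are enumerated once from the input graph (Z, then X, Y in
    ascending gene order); each X-Y pair is tested at most once per shared
    parent and removed (both directions, the statistic being symmetric) on
    its first non-significant test.
    """
    out = grn.copy()
    gene_index = {g: j for j, g in enumerate(expression.gene_ids)}
    missing = [g for g in grn.genes() if g not in gene_index]
    if missing:
        raise ValueError(f"expression missing genes: {missing[:5]}")
    disc: dict[str, np.ndarray] = {}

    def symbols(g: str) -> np.ndarray:
        if g not in disc:
            disc[g] = discretize_equal_frequency(
                expression.values[:, gene_index[g]], bins
            )
        return disc[g]

    children: dict[str, list[str]] = {}
    for s, t in grn.edges:
        children.setdefault(s, []).append(t)
    pair_edges: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for s, t in grn.edges:
        key = (min(s, t), max(s, t))
        pair_edges.setdefault(key, []).append((s, t))

    # snapshot of triads in deterministic order
    triads: list[tuple[str, str, str]] = []
    for z in sorted(children):
        kids = sorted(set(children[z]))
        for a_i in range(len(kids)):
            for b_i in range(a_i + 1, len(kids)):
                x, y = kids[a_i], kids[b_i]
                if (x, y) in pair_edges:
                    triads.append((z, x, y))

    removed_pairs: set[tuple[str, str]] = set()
    for z, x, y in triads:
        if (x, y) in removed_pairs:
            continue
        res = estimate_cmi(symbols(x), symbols(y), symbols(z))
        if res.p_value >= alpha:
            for edge in pair_edges[(x, y)]:
                if edge in out.edges:
                    out.remove_edge(edge, "cmi")
            removed_pairs.add((x, y))
    return out
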