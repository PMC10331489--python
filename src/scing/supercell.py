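"""Supercell construction: Leiden partition of the cell kNN graph with a
resolution binary search targeting a requested supercell count, then
within-group averaging of log-normalized expression."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp

from .preprocessing import (
    Embedding,
    LogNormMatrix,
    NeighborGraph,
    neighbor_adjacency,
    normalize_log1p,
    pca,
    scale_features,
    select_hvg,
    knn_graph,
)

logger = logging.getLogger("scing")


@dataclass
class Partition:
    labels: np.ndarray  # entity -> community id, 0-based contiguous
    resolution: float
    quality: float
    seed: int

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


@dataclass
class SupercellMatrix:
    """Supercells x genes mean log-normalized expression."""

    values: np.ndarray
    gene_ids: list[str]
    membership: np.ndarray  # cell -> supercell id

    @property
    def n_supercells(self) -> int:
        return self.values.shape[0]


def _graph_from_adjacency(A: sp.spmatrix) -> ig.Graph:
    A = sp.coo_matrix(A)
    mask = A.row < A.col  # undirected: keep upper triangle
    edges = list(zip(A.row[mask].tolist(), A.col[mask].tolist()))
    g = ig.Graph(n=A.shape[0], edges=edges)
    g.es["weight"] = A.data[mask].tolist()
    return g


def leiden_partition(
    graph: NeighborGraph | sp.spmatrix,
    resolution: float,
    seed: int = 0,
) -> Partition:
    """Leiden community detection (RB-configuration quality) at a resolution."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    A = neighbor_adjacency(graph) if isinstance(graph, NeighborGraph) else graph
    if A.shape[0] == 0:
        raise ValueError("empty graph")
    g = _graph_from_adjacency(A)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=int)
    return Partition(
        labels=labels, resolution=resolution, quality=part.quality(), seed=seed
    )


def find_resolution_for_count(
    graph: NeighborGraph | sp.spmatrix,
    target_n: int,
    max_iter: int = 50,
    seed: int = 0,
    tol_frac: float = 0.05,
) -> tuple[float, Partition]:
    """Binary search on the Leiden resolution for a target community count.

    The bracket starts at [1e-4, 1.0]; the upper bound doubles until it
    yields at least ``target_n`` communities.  Because Leiden counts are not
    strictly monotone in resolution, the probe whose count is closest to the
    target wins (exact match returned immediately); a final count more than
    5% off the target is logged as a warning.
    """
    A = neighbor_adjacency(graph) if isinstance(graph, NeighborGraph) else graph
    n = A.shape[0]
    if not (1 <= target_n <= n):
        raise ValueError(f"target_n={target_n} must lie in [1, {n}]")

    def probe(res: float) -> Partition:
        return leiden_partition(A, res, seed=seed)

    lo, hi = 1e-4, 1.0
    best: tuple[int, float, Partition] | None = None

    def consider(res: float, part: Partition):
        nonlocal best
        gap = abs(part.n_communities - target_n)
        if best is None or gap < best[0]:
            best = (gap, res, part)

    p_lo = probe(lo)
    consider(lo, p_lo)
    if p_lo.n_communities == target_n:
        return lo, p_lo
    p_hi = probe(hi)
    consider(hi, p_hi)
    grow = 0
    while p_hi.n_communities < target_n and grow < 30:
        hi *= 2
        p_hi = probe(hi)
        consider(hi, p_hi)
        grow += 1
    if p_hi.n_communities == target_n:
        return hi, p_hi

    for _ in range(max_iter):
        mid = (lo + hi) / 2
        p_mid = probe(mid)
        consider(mid, p_mid)
        if p_mid.n_communities == target_n:
            return mid, p_mid
        if p_mid.n_communities < target_n:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-8:
            break

    assert best is not None
    gap, res, part = best
    if gap > tol_frac * target_n:
        logger.warning(
            "resolution search reached %d communities for target %d",
            part.n_communities,
            target_n,
        )
    return res, part


def make_supercells(lognorm: LogNormMatrix, partition: Partition) -> SupercellMatrix:
    """Average log-normalized expression within each community.

    Supercell rows follow ascending community id.
    """
    labels = np.asarray(partition.labels)
    if len(labels) != lognorm.n_cells:
        raise ValueError("partition does not cover all cells")
    n_sc = int(labels.max()) + 1
    values = np.zeros((n_sc, lognorm.n_genes))
    for s in range(n_sc):
        members = labels == s
        values[s] = lognorm.values[members].mean(axis=0)
    return SupercellMatrix(
        values=values, gene_ids=list(lognorm.gene_ids), membership=labels
    )


def build_supercells(
    counts,
    n_supercells: int = 500,
    n_hvg: int = 2000,
    n_pcs: int = 20,
    n_neighbors: int = 10,
    seed: int = 0,
) -> tuple[SupercellMatrix, LogNormMatrix]:
    """Full supercell path: normalize -> log1p -> HVG -> scale -> PCA ->
    10-neighbor cell graph -> Leiden at a searched resolution -> group means.

    Returns the supercell matrix (over ALL genes) and the cell-level
    log-normalized matrix it was averaged from.
    """
    lognorm = normalize_log1p(counts)
    hvg = select_hvg(lognorm, method="dispersion", n_top=min(n_hvg, lognorm.n_genes))
    cols = [lognorm.gene_ids.index(g) for g in hvg]
    X = scale_features(lognorm.values[:, cols])
    k = min(n_pcs, min(X.shape) - 1) if min(X.shape) > 1 else 1
    emb = pca(X, k=max(k, 1), entity_ids=lognorm.cell_ids, seed=seed)
    graph = knn_graph(emb, k=min(n_neighbors, lognorm.n_cells - 1))
    _, part = find_resolution_for_count(graph, n_supercells, seed=seed)
    return make_supercells(lognorm, part), lognorm
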