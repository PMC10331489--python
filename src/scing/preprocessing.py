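"""Normalization, gene filtering, HVG selection, scaling, PCA and kNN graphs.

Two preprocessing paths feed the pipeline:

* cells: normalize to 10k counts -> log1p -> top 2000 HVG -> scale ->
  20 PCs -> 10-neighbor cell graph (input to supercell construction);
* genes: same normalization, then the matrix is transposed and scaled so
  each gene becomes an observation, embedded in 10 PCs; each gene's 100
  nearest neighbors become its candidate regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import CountMatrix

logger = logging.getLogger("scing")


@dataclass
class LogNormMatrix:
    """Cells x genes log1p(CP10K) expression."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    target_sum: float = 1e4

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class Embedding:
    """Entities x k PC coordinates with non-increasing explained variance.

    ``components`` (k x features) and ``mean`` are retained so new
    observations can be projected into the same space.
    """

    coords: np.ndarray
    entity_ids: list[str]
    explained_variance: np.ndarray
    components: np.ndarray | None = None
    mean: np.ndarray | None = None

    def project(self, X: np.ndarray) -> np.ndarray:
        if self.components is None or self.mean is None:
            raise ValueError("embedding does not carry projection components")
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


@dataclass
class NeighborGraph:
    """Exact k-nearest-neighbor lists (self excluded, index tie-break)."""

    neighbors: np.ndarray  # n x k int indices, ordered by distance
    entity_ids: list[str]
    metric: str = "euclidean"

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]


def dedupe_genes(counts: CountMatrix) -> CountMatrix:
    """Drop duplicate gene columns, keeping the first occurrence."""
    if not counts.has_duplicate_genes:
        return counts
    seen: set[str] = set()
    keep = []
    for j, g in enumerate(counts.gene_ids):
        if g not in seen:
            seen.add(g)
            keep.append(j)
    return CountMatrix(
        values=counts.values[:, keep],
        cell_ids=counts.cell_ids,
        gene_ids=[counts.gene_ids[j] for j in keep],
    )


def normalize_log1p(counts: CountMatrix, target_sum: float = 1e4) -> LogNormMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Cells with zero total counts stay all-zero (logged as a warning).
    Duplicate gene columns are removed first (first occurrence kept).
    """
    counts = dedupe_genes(counts)
    totals = counts.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d cells have zero total counts", int(zero.sum()))
    scale = np.where(zero, 0.0, target_sum / np.where(zero, 1.0, totals))
    values = np.log1p(counts.values * scale[:, None])
    return LogNormMatrix(
        values=values,
        cell_ids=list(counts.cell_ids),
        gene_ids=list(counts.gene_ids),
        target_sum=target_sum,
    )


def filter_genes_by_prevalence(
    counts: CountMatrix,
    min_frac: float,
    keep_genes: set[str] | None = None,
) -> CountMatrix:
    """Keep genes with nonzero counts in at least ``min_frac`` of cells.

    ``keep_genes`` (e.g. disease gene sets) are exempt from removal.
    """
    if not (0 <= min_frac <= 1):
        raise ValueError("min_frac must lie in [0, 1]")
    frac = (counts.values > 0).mean(axis=0)
    keep = frac >= min_frac
    if keep_genes:
        keep |= np.array([g in keep_genes for g in counts.gene_ids])
    if not keep.any():
        raise ValueError("no genes pass the prevalence filter")
    idx = np.flatnonzero(keep)
    return CountMatrix(
        values=counts.values[:, idx],
        cell_ids=list(counts.cell_ids),
        gene_ids=[counts.gene_ids[j] for j in idx],
    )


def select_hvg(
    matrix,
    method: str = "dispersion",
    n_top: int | None = 2000,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_disp: float = 0.5,
    n_bins: int = 20,
    clip: float | None = None,
) -> list[str]:
    """Highly variable gene selection.

    method='dispersion'
        expects log-normalized input; genes are ranked by dispersion
        (variance/mean of expm1 expression) normalized within mean bins.
        With ``n_top=None`` the (min_mean, max_mean, min_disp) cutoffs are
        applied to log1p(mean) and the z-scored dispersion instead.
    method='vst'
        expects raw counts; a lowess trend of log10(variance) on
        log10(mean) is fit, counts are standardized under the trend and
        clipped at sqrt(n), and genes are ranked by the clipped variance.
    """
    values = matrix.values
    gene_ids = matrix.gene_ids
    n_cells = values.shape[0]

    if method == "dispersion":
        expr = np.expm1(values)
        mean = expr.mean(axis=0)
        var = expr.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
        log_mean = np.log1p(mean)
        # normalize dispersion within mean bins (z-score per bin)
        order = np.argsort(log_mean, kind="stable")
        bins = np.array_split(order, n_bins)
        norm_disp = np.zeros_like(disp)
        for b in bins:
            if len(b) == 0:
                continue
            d = disp[b]
            sd = d.std()
            # degenerate bins (constant dispersion) are centered only, which
            # preserves within-bin ordering
            norm_disp[b] = (d - d.mean()) / (sd if sd > 0 else 1.0)
        norm_disp[mean == 0] = -np.inf
        if n_top is None:
            keep = (
                (log_mean > min_mean)
                & (log_mean < max_mean)
                & (norm_disp > min_disp)
            )
            return [gene_ids[j] for j in np.flatnonzero(keep)]
        score = norm_disp
    elif method == "vst":
        mean = values.mean(axis=0)
        var = values.var(axis=0, ddof=1) if n_cells > 1 else values.var(axis=0)
        score = _vst_variance(values, mean, var, clip or np.sqrt(n_cells))
    else:
        raise ValueError(f"unknown HVG method {method!r}")

    if n_top is None:
        raise ValueError("n_top required for ranked selection")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    # tolerance absorbs float summation noise on constant columns
    nonconstant = values.var(axis=0) > 1e-12
    candidates = np.flatnonzero(nonconstant)
    if n_top >= len(candidates):
        if n_top > len(candidates):
            logger.warning(
                "requested %d HVGs but only %d non-constant genes", n_top, len(candidates)
            )
        chosen = candidates
    else:
        # rank by score desc, gene index asc for ties
        order = np.lexsort((candidates, -score[candidates]))
        chosen = candidates[order[:n_top]]
    chosen = np.sort(chosen)
    return [gene_ids[j] for j in chosen]


def _vst_variance(
    values: np.ndarray, mean: np.ndarray, var: np.ndarray, clip: float
) -> np.ndarray:
    """Variance of clipped standardized counts under a lowess mean-variance trend."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    score = np.zeros_like(mean)
    ok = (var > 1e-12) & (mean > 0)
    if ok.sum() < 2:
        return score
    x = np.log10(mean[ok])
    y = np.log10(var[ok])
    if np.ptp(x) == 0:
        fitted = np.full_like(y, y.mean())
    else:
        sm = lowess(y, x, frac=0.3, return_sorted=True)
        fitted = np.interp(x, sm[:, 0], sm[:, 1])
    reg_sd = np.sqrt(10**fitted)
    n = values.shape[0]
    z = (values[:, ok] - mean[ok]) / reg_sd
    z = np.clip(z, -clip, clip)
    score[ok] = (z**2).sum(axis=0) / max(n - 1, 1)
    return score


def scale_features(matrix: np.ndarray) -> np.ndarray:
    """Center each column and scale to unit population (ddof=0) variance.

    Zero-variance columns become all-zero.
    """
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    out = X - mean
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def pca(
    matrix: np.ndarray,
    k: int,
    entity_ids: list[str] | None = None,
    seed: int = 0,
) -> Embedding:
    """Exact-SVD principal components of the centered matrix.

    Deterministic: each component's sign is flipped so the largest-magnitude
    loading entry is positive.  A seeded randomized solver is used above
    5000 entities.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if not (1 <= k <= min(n, p)):
        raise ValueError(f"k={k} must lie in [1, {min(n, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    if n > 5000:
        from sklearn.utils.extmath import randomized_svd

        U, S, Vt = randomized_svd(Xc, n_components=k, random_state=seed)
    else:
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention: largest-|loading| entry positive per component
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    coords = U * S
    explained = S**2 / n
    ids = entity_ids if entity_ids is not None else [str(i) for i in range(n)]
    return Embedding(
        coords=coords,
        entity_ids=list(ids),
        explained_variance=explained,
        components=Vt,
        mean=mean,
    )


def knn_graph(
    embedding: Embedding, k: int, metric: str = "euclidean"
) -> NeighborGraph:
    """Exact k nearest neighbors, self excluded, ties broken by entity index."""
    if k <= 0:
        raise ValueError("k must be positive")
    X = embedding.coords
    n = X.shape[0]
    if k >= n:
        logger.warning("k=%d >= %d entities; using all others", k, n)
        k = n - 1
    D = cdist(X, X, metric=metric)
    np.fill_diagonal(D, np.inf)
    idx = np.arange(n)
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((idx, D[i]))
        neighbors[i] = order[:k]
    return NeighborGraph(
        neighbors=neighbors, entity_ids=list(embedding.entity_ids), metric=metric
    )


def candidate_regulators(
    gene_embedding: Embedding, K: int = 100
) -> dict[str, list[str]]:
    """Candidate regulator map: each gene's K nearest genes in PC space."""
    n = gene_embedding.coords.shape[0]
    if K >= n:
        logger.warning("K=%d >= %d genes; using all other genes", K, n)
        K = n - 1
    graph = knn_graph(gene_embedding, K)
    ids = gene_embedding.entity_ids
    return {
        ids[i]: [ids[j] for j in graph.neighbors[i]] for i in range(n)
    }


def neighbor_adjacency(graph: NeighborGraph) -> "scipy.sparse.csr_matrix":  # noqa: F821
    """Symmetrized unweighted adjacency of a kNN graph (union of directions)."""
    import scipy.sparse as sp

    n = len(graph.entity_ids)
    rows = np.repeat(np.arange(n), graph.k)
    cols = graph.neighbors.ravel()
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)
    return A
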