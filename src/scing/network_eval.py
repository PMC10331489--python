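"""Network evaluation: hold-out prediction robustness, topology metrics,
split-half overlap, disease-gene random-walk recovery, and batch-mixing F1.

The batch-mixing score follows the neighborhood-score / F1 definitions:

    neigh_score = (1/n_cell) * sum_cells similar_neighbors / n_neighbors
    F1 = 2 (1-ns_sample)(1-ns_batch) ns_pheno
         / [(1-ns_sample) + (1-ns_batch) + ns_pheno]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import linregress

from .data_io import EdgeList
from .grn_subsample import GBRHyperparams, fit_target_importances
from .preprocessing import pca

logger = logging.getLogger("scing")


@dataclass
class HoldoutResult:
    mean_cosine_train: float
    mean_cosine_test: float
    ratio_test_over_train: float
    n_genes_scored: int


@dataclass
class NetworkMetrics:
    n_edges: int
    n_genes: int
    scale_free_r2: float
    betweenness_variance: float
    sparsity_threshold: float = 0.7


@dataclass
class NeighborhoodScore:
    neigh_score: float
    similar_neighbors: np.ndarray
    n_neighbors: int
    n_cell: int


@dataclass
class BatchMixF1:
    F1_phenotype: float
    neigh_score_sample: float
    neigh_score_batch: float
    neigh_score_phenotype: float
    neighbor_frac: float = 0.0


@dataclass
class DiseaseRecoveryResult:
    performance: float
    null_mean: float
    null_sd: float
    gain_z: float
    null_performances: np.ndarray


def _centered_cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of mean-removed vectors (equals Pearson r)."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def holdout_cosine(
    train_expr: np.ndarray,
    test_expr: np.ndarray,
    gene_ids: list[str],
    grn: EdgeList,
    hp: GBRHyperparams | None = None,
    seed: int = 0,
) -> HoldoutResult:
    """Per-gene GBR fit on training cells from the gene's network parents;
    mean centered-cosine between predicted and observed expression on train
    and test cells (parentless genes excluded)."""
    hp = hp or GBRHyperparams()
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    parents: dict[str, list[str]] = {}
    for s, t in grn.pairs():
        if s in gene_index and t in gene_index:
            parents.setdefault(t, []).append(s)
    scored = sorted(g for g in parents if g in gene_index)
    if not scored:
        raise ValueError("no gene has parents")
    from sklearn.ensemble import GradientBoostingRegressor

    train_cos, test_cos = [], []
    ss = np.random.SeedSequence(seed)
    for i, gene in enumerate(scored):
        cols = sorted(gene_index[p] for p in set(parents[gene]))
        y_tr = train_expr[:, gene_index[gene]]
        if np.ptp(y_tr) == 0:
            continue
        child_seed = int(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        model = GradientBoostingRegressor(
            n_estimators=hp.n_estimators,
            max_depth=hp.max_depth,
            learning_rate=hp.learning_rate,
            subsample=hp.subsample,
            max_features=hp.max_features,
            random_state=child_seed,
        )
        from .grn_subsample import _early_stop_monitor

        model.fit(
            train_expr[:, cols], y_tr, monitor=_early_stop_monitor(hp.early_stop_window)
        )
        train_cos.append(_centered_cosine(model.predict(train_expr[:, cols]), y_tr))
        test_cos.append(
            _centered_cosine(
                model.predict(test_expr[:, cols]), test_expr[:, gene_index[gene]]
            )
        )
    mean_tr = float(np.mean(train_cos))
    mean_te = float(np.mean(test_cos))
    ratio = mean_te / mean_tr if mean_tr > 0 else float("nan")
    return HoldoutResult(
        mean_cosine_train=mean_tr,
        mean_cosine_test=mean_te,
        ratio_test_over_train=ratio,
        n_genes_scored=len(train_cos),
    )


def _undirected_graph(grn: EdgeList) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(grn.genes())
    for s, t in grn.pairs():
        if s != t:
            g.add_edge(s, t)
    return g


def scale_free_r2(
    grn: EdgeList,
    gene_sparsity: dict[str, float] | None = None,
    sparsity_threshold: float = 0.7,
) -> float:
    """R-squared of the log10 degree-proportion vs log10 degree regression
    (undirected projection), excluding genes above the sparsity threshold."""
    g = _undirected_graph(grn)
    nodes = list(g.nodes)
    if gene_sparsity is not None:
        nodes = [n for n in nodes if gene_sparsity.get(n, 0.0) <= sparsity_threshold]
    degrees = np.array([g.degree(n) for n in nodes])
    degrees = degrees[degrees > 0]
    if len(degrees) == 0:
        raise ValueError("no nodes with positive degree after exclusion")
    uniq, counts = np.unique(degrees, return_counts=True)
    if len(uniq) < 3:
        raise ValueError("fewer than 3 distinct degrees; fit undefined")
    prop = counts / counts.sum()
    fit = linregress(np.log10(uniq), np.log10(prop))
    return float(fit.rvalue**2)


def betweenness_stats(grn: EdgeList) -> float:
    """Population variance of normalized shortest-path betweenness on the
    unweighted undirected projection."""
    g = _undirected_graph(grn)
    if g.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    bc = nx.betweenness_centrality(g, normalized=True)
    vals = np.array(list(bc.values()))
    return float(vals.var())


def overlap_score(netA: EdgeList, netB: EdgeList, n_genes: int) -> float:
    """Observed/expected overlap of unordered edge pairs; the expectation is
    the hypergeometric mean mA*mB/M with M = C(n_genes, 2)."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    pairsA = {frozenset(p) for p in netA.pairs() if p[0] != p[1]}
    pairsB = {frozenset(p) for p in netB.pairs() if p[0] != p[1]}
    mA, mB = len(pairsA), len(pairsB)
    if mA == 0 or mB == 0:
        raise ValueError("both networks must have edges")
    M = n_genes * (n_genes - 1) / 2
    observed = len(pairsA & pairsB)
    expected = mA * mB / M
    return observed / expected


def _rwr(
    A: np.ndarray, seeds: np.ndarray, restart: float = 0.5, tol: float = 1e-6
) -> np.ndarray:
    """Random walk with restart on a column-normalized transition matrix."""
    col = A.sum(axis=0)
    col[col == 0] = 1.0
    W = A / col
    p0 = seeds / seeds.sum()
    p = p0.copy()
    for _ in range(10_000):
        p_new = (1 - restart) * (W @ p) + restart * p0
        if np.abs(p_new - p).sum() < tol:
            return p_new
        p = p_new
    return p


def _auprc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    order = np.argsort(-scores, kind="stable")
    labels = positives[order]
    tp = np.cumsum(labels)
    precision = tp / np.arange(1, len(labels) + 1)
    n_pos = labels.sum()
    if n_pos == 0:
        return 0.0
    recall = tp / n_pos
    # AP: sum precision at each positive hit
    return float(precision[labels.astype(bool)].sum() / n_pos)


def degree_preserved_null(
    grn: EdgeList, seed: int = 0, swaps_per_edge: int = 10
) -> nx.Graph:
    """Degree-preserved randomization of the undirected projection via
    double-edge swaps (10 accepted swaps per edge)."""
    g = _undirected_graph(grn)
    m = g.number_of_edges()
    if m < 2:
        return g
    nx.double_edge_swap(
        g, nswap=swaps_per_edge * m, max_tries=100 * swaps_per_edge * m, seed=seed
    )
    return g


def _recovery_performance(
    g: nx.Graph,
    members: list[str],
    n_splits: int,
    restart: float,
    rng: np.random.Generator,
) -> float:
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    A = nx.to_numpy_array(g, nodelist=nodes)
    perfs = []
    for _ in range(n_splits):
        perm = rng.permutation(len(members))
        half = len(members) // 2
        seed_set = [members[i] for i in perm[:half]]
        held_out = [members[i] for i in perm[half:]]
        seeds = np.zeros(len(nodes))
        seeds[[index[m] for m in seed_set]] = 1.0
        p = _rwr(A, seeds, restart=restart)
        candidates = [n for n in nodes if n not in seed_set]
        scores = np.array([p[index[n]] for n in candidates])
        positives = np.array([n in held_out for n in candidates], dtype=float)
        perfs.append(_auprc(scores, positives))
    return float(np.mean(perfs))


def disease_recovery_gain(
    grn: EdgeList,
    gene_set: list[str],
    n_null: int = 50,
    restart: float = 0.5,
    n_splits: int = 10,
    seed: int = 0,
) -> DiseaseRecoveryResult:
    """Random-walk recovery of a held-out half of a gene set, z-scored
    against degree-preserved randomized networks.

    performance = mean AUPRC over ``n_splits`` 50/50 splits of ranking the
    held-out members by steady-state RWR probability seeded at the other
    half; gain_z = (performance - null_mean)/null_sd over ``n_null``
    degree-preserved edge-swap randomizations.
    """
    g = _undirected_graph(grn)
    members = sorted(set(gene_set) & set(g.nodes))
    if len(members) < 10:
        raise ValueError("need >= 10 gene-set members present in the network")
    rng = np.random.default_rng(seed)
    perf = _recovery_performance(g, members, n_splits, restart, rng)
    null_perfs = np.empty(n_null)
    for b in range(n_null):
        gb = degree_preserved_null(grn, seed=seed + 1 + b)
        null_perfs[b] = _recovery_performance(
            gb, members, n_splits, restart, np.random.default_rng(seed + 1 + b)
        )
    null_mean = float(null_perfs.mean())
    null_sd = float(null_perfs.std(ddof=1))
    if null_sd == 0:
        raise ValueError("null performance has zero variance")
    return DiseaseRecoveryResult(
        performance=perf,
        null_mean=null_mean,
        null_sd=null_sd,
        gain_z=(perf - null_mean) / null_sd,
        null_performances=null_perfs,
    )


def neighborhood_score(
    coords: np.ndarray, labels: np.ndarray, k: int
) -> NeighborhoodScore:
    """Average fraction of each cell's k nearest neighbors sharing its label."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = coords.shape[0]
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    idx = np.arange(n)
    similar = np.empty(n, dtype=int)
    for i in range(n):
        order = np.lexsort((idx, D[i]))[:k]
        similar[i] = int((labels[order] == labels[i]).sum())
    ns = float(similar.mean() / k)
    return NeighborhoodScore(
        neigh_score=ns, similar_neighbors=similar, n_neighbors=k, n_cell=n
    )


def batch_mix_f1(
    ns_sample: float, ns_batch: float, ns_phenotype: float
) -> float:
    """F1 combining batch/sample mixing with phenotype separation."""
    a, b, c = 1 - ns_sample, 1 - ns_batch, ns_phenotype
    num = 2 * a * b * c
    den = a + b + c
    if num == 0:
        return 0.0
    return num / den


def batch_f1(
    features: np.ndarray,
    labels: dict[str, np.ndarray],
    neighbor_fracs: tuple[float, ...] = (0.0025, 0.005, 0.01, 0.02, 0.04, 0.08, 0.16),
    n_pcs: int = 20,
    seed: int = 0,
) -> list[BatchMixF1]:
    """Batch-mixing F1 per neighbor fraction on the top ``n_pcs`` PCs of a
    cells x features table.

    ``labels`` must provide 'sample', 'batch' and 'phenotype' arrays.
    """
    for key in ("sample", "batch", "phenotype"):
        if key not in labels:
            raise ValueError(f"missing label array {key!r}")
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    k_emb = min(n_pcs, min(X.shape) - 1)
    coords = pca(X, k=max(k_emb, 1), seed=seed).coords
    out = []
    for frac in neighbor_fracs:
        k = int(round(frac * n))
        if k < 1:
            raise ValueError(f"neighbor fraction {frac} gives k < 1 at n={n}")
        ns = {
            key: neighborhood_score(coords, np.asarray(labels[key]), k).neigh_score
            for key in ("sample", "batch", "phenotype")
        }
        out.append(
            BatchMixF1(
                F1_phenotype=batch_mix_f1(ns["sample"], ns["batch"], ns["phenotype"]),
                neigh_score_sample=ns["sample"],
                neigh_score_batch=ns["batch"],
                neigh_score_phenotype=ns["phenotype"],
                neighbor_frac=frac,
            )
        )
    return out
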