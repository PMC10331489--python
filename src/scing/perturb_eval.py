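"""Perturbation-screen effect estimation and depth-based network scoring.

Per-guide effects are estimated by elastic-net regression of every gene's
expression on guide indicators plus continuous cell-state probabilities
(states come from Leiden clusters of unperturbed cells, propagated to all
cells by a calibrated linear SVM).  Significance is assessed with a
per-guide permutation null and BH FDR, and any network is scored against
the resulting downstream-perturbed gene sets via breadth-first depth
layers, yielding a TPR/FPR curve, its AUROC, and TPR at FPR 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import ElasticNet
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .data_io import EdgeList
from .preprocessing import LogNormMatrix, knn_graph, pca, scale_features, select_hvg
from .supercell import leiden_partition

logger = logging.getLogger("scing")


@dataclass
class GuideMatrix:
    """Cells x guides binary assignment plus guide -> intended target map."""

    values: np.ndarray
    cell_ids: list[str]
    guide_ids: list[str]
    target_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("guide matrix entries must be 0/1")

    def single_guide_cells(self) -> np.ndarray:
        """Indices of cells with at most one positive guide (multi-guide
        cells are excluded before effect estimation)."""
        return np.flatnonzero(self.values.sum(axis=1) <= 1)

    def unperturbed_cells(self) -> np.ndarray:
        return np.flatnonzero(self.values.sum(axis=1) == 0)


@dataclass
class StateProbabilities:
    values: np.ndarray  # cells x states, rows sum to 1
    cell_ids: list[str]

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("state probability rows must sum to 1")


@dataclass
class DepthCurve:
    points: list[tuple[int, float, float]]  # (depth, TPR, FPR)
    auroc: float
    tpr_at_fpr05: float


def fit_cell_states(
    lognorm: LogNormMatrix,
    guides: GuideMatrix,
    leiden_resolution: float = 1.0,
    n_pcs: int = 50,
    svm_C: float = 1.0,
    seed: int = 0,
) -> StateProbabilities:
    """Cell-state probabilities for every cell.

    States are Leiden clusters of the unperturbed cells (HVG thresholds
    min_mean=0.0125, max_mean=3, min_disp=0.5, scaled, top ``n_pcs`` PCs,
    10-neighbor graph); a linear SVM (C=1) with Platt-calibrated
    probabilities trained on the unperturbed cells is applied to all cells.
    Rows are renormalized to sum to 1.
    """
    unpert = guides.unperturbed_cells()
    if len(unpert) < 10:
        raise ValueError("too few unperturbed cells to define states")
    hvg = select_hvg(lognorm, method="dispersion", n_top=None,
                     min_mean=0.0125, max_mean=3.0, min_disp=0.5)
    if len(hvg) < 2:
        # degenerate panel: fall back to all non-constant genes
        var = lognorm.values.var(axis=0)
        hvg = [g for g, v in zip(lognorm.gene_ids, var) if v > 0]
    cols = [lognorm.gene_ids.index(g) for g in hvg]
    X_unpert = lognorm.values[np.ix_(unpert, cols)]
    mean = X_unpert.mean(axis=0)
    sd = X_unpert.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z_unpert = (X_unpert - mean) / sd
    k = min(n_pcs, min(Z_unpert.shape) - 1)
    emb = pca(Z_unpert, k=max(k, 1), seed=seed)
    graph = knn_graph(emb, k=min(10, len(unpert) - 1))
    part = leiden_partition(graph, leiden_resolution, seed=seed)
    labels = part.labels
    if part.n_communities < 2:
        raise ValueError("fewer than 2 cell states found")
    clf = CalibratedClassifierCV(
        LinearSVC(C=svm_C, random_state=seed), method="sigmoid", cv=3
    )
    clf.fit(emb.coords, labels)
    Z_all = (lognorm.values[:, cols] - mean) / sd
    probs = clf.predict_proba(emb.project(Z_all))
    probs = probs / probs.sum(axis=1, keepdims=True)
    return StateProbabilities(values=probs, cell_ids=list(lognorm.cell_ids))


def _design(guide_values: np.ndarray, state_values: np.ndarray) -> np.ndarray:
    return np.column_stack([guide_values, state_values])


def estimate_guide_effects(
    lognorm: LogNormMatrix,
    guides: GuideMatrix,
    states: StateProbabilities,
    l1_ratio: float = 0.5,
    alpha: float = 0.0005,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Elastic-net coefficients of every gene's expression on guide
    indicators (state probabilities included as covariates and discarded).

    Returns a guides x genes coefficient frame.  Only single-guide cells
    enter the fit.
    """
    cells = guides.single_guide_cells()
    G = guides.values[cells]
    if (G.sum(axis=0) == 0).any():
        empty = [guides.guide_ids[j] for j in np.flatnonzero(G.sum(axis=0) == 0)]
        raise ValueError(f"guides with no positive single-guide cells: {empty}")
    X = _design(G, states.values[cells])
    Y = lognorm.values[cells]
    model = ElasticNet(
        alpha=alpha, l1_ratio=l1_ratio, fit_intercept=True, max_iter=max_iter
    )
    model.fit(X, Y)
    coef = np.atleast_2d(model.coef_)  # genes x features
    n_guides = len(guides.guide_ids)
    return pd.DataFrame(
        coef[:, :n_guides].T, index=guides.guide_ids, columns=lognorm.gene_ids
    )


def permutation_significance(
    lognorm: LogNormMatrix,
    guides: GuideMatrix,
    states: StateProbabilities,
    coefs: pd.DataFrame | None = None,
    n_perm: int = 100,
    fdr_level: float = 0.05,
    seed: int = 0,
    add_one: bool = False,
) -> pd.DataFrame:
    """Sign-sided permutation test of guide coefficients with per-guide BH
    correction.

    For each guide the cell-assignment column is permuted ``n_perm`` times
    and the elastic net refit; p is the fraction of null coefficients more
    extreme than the observed one on the side of its sign (the add-one
    variant is available by flag).  Returns a long frame with columns
    guide, gene, coefficient, p_value, fdr, significant.
    """
    if n_perm < 20:
        logger.warning("n_perm=%d gives coarse p-value resolution", n_perm)
    if coefs is None:
        coefs = estimate_guide_effects(lognorm, guides, states)
    cells = guides.single_guide_cells()
    G = guides.values[cells].astype(float)
    S = states.values[cells]
    Y = lognorm.values[cells]
    rng = np.random.default_rng(seed)
    frames = []
    for gi, guide in enumerate(guides.guide_ids):
        obs = coefs.loc[guide].to_numpy()
        null = np.empty((n_perm, len(lognorm.gene_ids)))
        for b in range(n_perm):
            Gp = G.copy()
            Gp[:, gi] = G[rng.permutation(len(cells)), gi]
            model = ElasticNet(alpha=0.0005, l1_ratio=0.5, fit_intercept=True,
                               max_iter=2000)
            model.fit(_design(Gp, S), Y)
            null[b] = np.atleast_2d(model.coef_)[:, gi]
        pos = obs >= 0
        exceed = np.where(pos, (null >= obs).sum(axis=0), (null <= obs).sum(axis=0))
        if add_one:
            p = (exceed + 1) / (n_perm + 1)
        else:
            p = exceed / n_perm
        rej, fdr, _, _ = multipletests(p, alpha=fdr_level, method="fdr_bh")
        frames.append(
            pd.DataFrame(
                {
                    "guide": guide,
                    "gene": lognorm.gene_ids,
                    "coefficient": obs,
                    "p_value": p,
                    "fdr": fdr,
                    "significant": rej,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def downstream_perturbed_genes(
    effects: pd.DataFrame, guides: GuideMatrix, target: str
) -> set[str]:
    """Genes flagged significant by at least one guide targeting ``target``
    (the target itself excluded)."""
    guide_ids = [g for g, t in guides.target_of.items() if t == target]
    sub = effects[effects["guide"].isin(guide_ids) & effects["significant"]]
    return set(sub["gene"]) - {target}


def depth_roc(
    grn: EdgeList,
    source_gene: str,
    truth: set[str],
    universe: list[str],
    directed: bool = True,
) -> DepthCurve:
    """Depth-layer ROC: predicted positives at depth d are all genes within
    BFS distance <= d of the source; the curve is closed with (0,0) and
    (1,1) and integrated by the trapezoid rule.

    ``tpr_at_fpr05`` is the TPR of the deepest layer with FPR <= 0.05
    (step-function convention, 0 when no layer qualifies).
    """
    if source_gene not in universe:
        raise ValueError("source gene not in universe")
    truth = set(truth) - {source_gene}
    if not truth:
        raise ValueError("empty truth set")
    if not truth.issubset(universe):
        raise ValueError("truth must be contained in the universe")
    adj: dict[str, set[str]] = {}
    for s, t in grn.pairs():
        adj.setdefault(s, set()).add(t)
        if not directed:
            adj.setdefault(t, set()).add(s)
    negatives = set(universe) - truth - {source_gene}
    # BFS layers
    reached: set[str] = set()
    frontier = {source_gene}
    seen = {source_gene}
    points: list[tuple[int, float, float]] = []
    depth = 0
    while frontier:
        nxt: set[str] = set()
        for node in frontier:
            nxt |= adj.get(node, set())
        nxt -= seen
        if not nxt:
            break
        depth += 1
        seen |= nxt
        reached |= nxt
        tpr = len(reached & truth) / len(truth)
        fpr = len(reached - truth) / len(negatives) if negatives else 0.0
        points.append((depth, tpr, fpr))
        frontier = nxt
    xs = [0.0] + [p[2] for p in points] + [1.0]
    ys = [0.0] + [p[1] for p in points] + [1.0]
    auroc = float(np.trapezoid(ys, xs))
    tpr05 = 0.0
    for _, tpr, fpr in points:
        if fpr <= 0.05:
            tpr05 = tpr
    return DepthCurve(points=points, auroc=auroc, tpr_at_fpr05=tpr05)
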