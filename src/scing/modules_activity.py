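"""Gene-module detection on the consensus GRN, AUCell-style per-cell module
activity, and module-trait association tests.

Module activity follows the AUCell recipe: genes are ranked per cell by
expression (ties broken by a seeded random permutation) and a module's
score is the normalized area under the recovery curve of its genes within
the top fraction (default 5%) of the ranking, so scores live in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .consensus import ConsensusGRN
from .preprocessing import LogNormMatrix

logger = logging.getLogger("scing")


@dataclass
class ModulePartition:
    assignment: dict[str, int]  # gene -> module id, 0-based contiguous
    n_modules: int
    resolution: float
    quality: float = 0.0

    def module_genes(self, module: int) -> list[str]:
        return sorted(g for g, m in self.assignment.items() if m == module)


@dataclass
class ModuleActivity:
    scores: np.ndarray  # cells x modules, in [0, 1]
    cell_ids: list[str]
    n_modules: int
    top_frac: float = 0.05


def _grn_to_igraph(grn: ConsensusGRN) -> tuple[ig.Graph, list[str]]:
    genes = grn.genes()
    index = {g: i for i, g in enumerate(genes)}
    pair_w: dict[tuple[int, int], float] = {}
    for (s, t), w in grn.edges.items():
        a, b = sorted((index[s], index[t]))
        pair_w[(a, b)] = pair_w.get((a, b), 0.0) + w
    g = ig.Graph(n=len(genes), edges=list(pair_w.keys()))
    g.es["weight"] = list(pair_w.values())
    return g, genes


def partition_grn(
    grn: ConsensusGRN, resolution: float, seed: int = 0
) -> ModulePartition:
    """Leiden partition of the GRN's undirected weighted projection."""
    if len(grn) == 0:
        raise ValueError("empty GRN")
    g, genes = _grn_to_igraph(grn)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    return ModulePartition(
        assignment={g_: int(labels[i]) for i, g_ in enumerate(genes)},
        n_modules=int(labels.max()) + 1,
        resolution=resolution,
        quality=part.quality(),
    )


def scan_resolution(
    grn: ConsensusGRN,
    resolutions: list[float],
    target_module_range: tuple[int, int] = (20, 50),
    annotate=None,
    seed: int = 0,
) -> tuple[float, ModulePartition]:
    """Choose a resolution yielding a module count within the target range.

    Among in-range grid points the annotation callback's fraction-annotated
    is maximized (falling back to partition quality when no callback is
    given); when no grid point lands in range, the closest count wins with
    a warning.
    """
    if not resolutions:
        raise ValueError("empty resolution grid")
    lo, hi = target_module_range
    probes = [(r, partition_grn(grn, r, seed=seed)) for r in resolutions]
    in_range = [(r, p) for r, p in probes if lo <= p.n_modules <= hi]
    if not in_range:
        r, p = min(
            probes, key=lambda rp: (min(abs(rp[1].n_modules - lo), abs(rp[1].n_modules - hi)), rp[0])
        )
        logger.warning(
            "no resolution in module range %s; closest count %d at %g",
            target_module_range,
            p.n_modules,
            r,
        )
        return r, p
    if annotate is not None:
        scored = [(annotate(p), p.quality, -r, r, p) for r, p in in_range]
    else:
        scored = [(p.quality, 0.0, -r, r, p) for r, p in in_range]
    best = max(scored, key=lambda s: s[:3])
    return best[3], best[4]


def _top_ranked(
    lognorm: LogNormMatrix, top_frac: float, seed: int
) -> np.ndarray:
    """Indices of each cell's top-ranked genes (cells x cutoff), expression
    descending, ties broken by one seeded random gene permutation."""
    n_cells, n_genes = lognorm.values.shape
    cutoff = math.ceil(top_frac * n_genes)
    rng = np.random.default_rng(seed)
    tie_break = rng.permutation(n_genes)
    top = np.empty((n_cells, cutoff), dtype=int)
    for c in range(n_cells):
        top[c] = np.lexsort((tie_break, -lognorm.values[c]))[:cutoff]
    return top


def _score_gene_set(top: np.ndarray, member: np.ndarray, m_size: int) -> np.ndarray:
    """Normalized recovery-curve area of a gene set within the top ranks."""
    cutoff = top.shape[1]
    if m_size == 0:
        return np.zeros(top.shape[0])
    hits = np.cumsum(member[top], axis=1)
    area = hits.sum(axis=1)
    ranks = np.arange(1, cutoff + 1)
    max_area = np.minimum(ranks, m_size).sum()
    return area / max_area


def aucell_scores(
    lognorm: LogNormMatrix,
    partition: ModulePartition,
    top_frac: float = 0.05,
    seed: int = 0,
) -> ModuleActivity:
    """Per-cell module activity as the normalized recovery-curve area of
    module genes within the top ``top_frac`` of each cell's gene ranking."""
    n_genes = lognorm.n_genes
    gene_index = {g: j for j, g in enumerate(lognorm.gene_ids)}
    top = _top_ranked(lognorm, top_frac, seed)
    scores = np.zeros((lognorm.n_cells, partition.n_modules))
    for m in range(partition.n_modules):
        cols = [gene_index[g] for g in partition.module_genes(m) if g in gene_index]
        if not cols:
            logger.warning("module %d has no genes in the matrix; score 0", m)
            continue
        member = np.zeros(n_genes, dtype=bool)
        member[cols] = True
        scores[:, m] = _score_gene_set(top, member, len(cols))
    return ModuleActivity(
        scores=scores,
        cell_ids=list(lognorm.cell_ids),
        n_modules=partition.n_modules,
        top_frac=top_frac,
    )


def module_trait_association(
    activity: ModuleActivity,
    trait: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """OLS of the trait on each module's activity score (plus covariates and
    an intercept); BH adjustment across modules.

    Returns a frame with columns coefficient, p_value, fdr, significant.
    """
    trait = np.asarray(trait, dtype=float)
    if np.ptp(trait) == 0:
        raise ValueError("trait is constant")
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    else:
        cov = np.empty((len(trait), 0))
    coefs, pvals = [], []
    for m in range(activity.n_modules):
        X = np.column_stack([activity.scores[:, m], cov])
        X = sm.add_constant(X, has_constant="add")
        fit = sm.OLS(trait, X).fit()
        coefs.append(fit.params[1])
        pvals.append(fit.pvalues[1])
    rej, fdr, _, _ = multipletests(pvals, alpha=fdr_level, method="fdr_bh")
    return pd.DataFrame(
        {
            "module": np.arange(activity.n_modules),
            "coefficient": coefs,
            "p_value": pvals,
            "fdr": fdr,
            "significant": rej,
        }
    )


def module_permutation_correlation(
    lognorm: LogNormMatrix,
    partition: ModulePartition,
    trait: np.ndarray,
    n_perm: int = 1000,
    top_frac: float = 0.05,
    seed: int = 0,
    add_one: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of module activity with a trait against a null of
    same-size random gene sets.

    The two-sided permutation p-value uses the add-one estimator
    (1 + #{|r_null| >= |r|}) / (n_perm + 1) by default (``add_one=False``
    recovers the plain fraction); Bonferroni correction across modules.
    """
    trait = np.asarray(trait, dtype=float)
    if np.ptp(trait) == 0:
        raise ValueError("trait is constant")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    activity = aucell_scores(lognorm, partition, top_frac=top_frac, seed=seed)
    rng = np.random.default_rng(seed)
    n_genes = lognorm.n_genes
    gene_set = set(lognorm.gene_ids)
    top = _top_ranked(lognorm, top_frac, seed)
    rows = []
    for m in range(partition.n_modules):
        size = sum(1 for g in partition.module_genes(m) if g in gene_set)
        obs_r = pearsonr(activity.scores[:, m], trait)[0] if size else 0.0
        # null: random same-size gene sets scored the same way
        null_r = np.empty(n_perm)
        for b in range(n_perm):
            cols = rng.choice(n_genes, size=max(size, 1), replace=False)
            member = np.zeros(n_genes, dtype=bool)
            member[cols] = True
            s = _score_gene_set(top, member, len(cols))
            null_r[b] = pearsonr(s, trait)[0] if np.ptp(s) > 0 else 0.0
        extreme = int(np.sum(np.abs(null_r) >= abs(obs_r)))
        if add_one:
            p = (1 + extreme) / (n_perm + 1)
        else:
            p = extreme / n_perm
        rows.append((m, size, obs_r, p))
    df = pd.DataFrame(rows, columns=["module", "n_genes", "r", "p_value"])
    df["p_adj"] = np.minimum(1.0, df["p_value"] * partition.n_modules)
    return df
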