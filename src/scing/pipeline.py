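"""End-to-end GRN build: supercells -> candidate regulators -> bagged
subsample networks -> consensus -> direction/cycle/CMI pruning."""

from __future__ import annotations

import logging

import numpy as np

from .consensus import (
    ConsensusGRN,
    merge_networks,
    prune_triads,
    remove_cycles,
    resolve_bidirectional,
)
from .data_io import CountMatrix, RunConfig
from .grn_subsample import (
    GBRHyperparams,
    draw_subsample,
    filter_subsample_edges,
    infer_subsample_network,
)
from .preprocessing import candidate_regulators, pca, scale_features
from .supercell import SupercellMatrix, build_supercells

logger = logging.getLogger("scing")


def gene_candidate_map(
    supercells: SupercellMatrix,
    n_pcs: int = 10,
    K: int = 100,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Candidate regulators: transpose the supercell matrix, scale genes,
    embed in ``n_pcs`` PCs and take each gene's K nearest neighbors."""
    # drop genes constant across supercells (carry no signal, break scaling)
    var = supercells.values.var(axis=0)
    keep = np.flatnonzero(var > 0)
    X = scale_features(supercells.values[:, keep].T)  # genes x supercells
    gene_ids = [supercells.gene_ids[j] for j in keep]
    k = min(n_pcs, min(X.shape) - 1)
    emb = pca(X, k=max(k, 1), entity_ids=gene_ids, seed=seed)
    return candidate_regulators(emb, K=min(K, len(gene_ids) - 1))


def build_grn(
    counts: CountMatrix,
    config: RunConfig | None = None,
    hp: GBRHyperparams | None = None,
) -> tuple[ConsensusGRN, SupercellMatrix]:
    """Run the full inference pipeline on raw counts.

    Returns the pruned consensus GRN together with the supercell matrix it
    was inferred from (needed downstream for CMI re-tests and module
    activity).
    """
    config = config or RunConfig()
    hp = hp or GBRHyperparams()
    n_sc = min(config.n_supercells, counts.n_cells)
    supercells, _ = build_supercells(counts, n_supercells=n_sc, seed=config.seed)
    logger.info("built %d supercells", supercells.n_supercells)
    candidates = gene_candidate_map(
        supercells,
        n_pcs=config.n_gene_pcs,
        K=config.n_candidate_neighbors,
        seed=config.seed,
    )
    nets = []
    ss = np.random.SeedSequence(config.seed)
    for b in range(config.n_networks):
        sub_seed = int(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(1, b)).generate_state(1)[0]
            % (2**31)
        )
        rows = draw_subsample(supercells, frac=config.subsample_frac, seed=sub_seed)
        net = infer_subsample_network(
            supercells, candidates, hp, seed=sub_seed, subsample_index=b, rows=rows
        )
        if len(net):
            nets.append(filter_subsample_edges(net))
    logger.info("inferred %d subsample networks", len(nets))
    grn = merge_networks(nets, consensus_frac=config.consensus_frac)
    grn = resolve_bidirectional(grn, ratio=config.direction_ratio)
    grn = remove_cycles(grn)
    grn = prune_triads(
        grn, supercells, alpha=config.cmi_alpha, bins=config.cmi_bins
    )
    logger.info("final GRN: %d edges over %d genes", len(grn), len(grn.genes()))
    return grn, supercells
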