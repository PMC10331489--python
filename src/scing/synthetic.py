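"""Synthetic ground-truth GRNs, sparse scRNA-seq-like counts, perturbation
screens, and batch/phenotype label structure.

The generator plants a preferential-attachment DAG (edges oriented from
older to newer genes, so acyclicity holds by construction), propagates
latent log-rates along the DAG with Gaussian noise, draws Poisson counts
through a softplus link, and thins entries with independent Bernoulli
dropout.  Perturbation screens multiply the target gene's latent rate by
(1 - knockdown_frac) before propagation, so the true downstream set of a
guide is exactly the DAG descendants of its target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import CountMatrix
from .perturb_eval import GuideMatrix

logger = logging.getLogger("scing")


@dataclass
class PlantedGRN:
    """Ground-truth DAG with signed edge weights."""

    edges: list[tuple[str, str, float]]  # (regulator, target, signed weight)
    genes: list[str]  # topological order (construction order)
    n_genes: int
    m_attach: int
    seed: int
    parents: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def descendants(self, gene: str) -> set[str]:
        children: dict[str, set[str]] = {}
        for s, t, _ in self.edges:
            children.setdefault(s, set()).add(t)
        out: set[str] = set()
        frontier = [gene]
        while frontier:
            node = frontier.pop()
            for c in children.get(node, ()):  # DAG: no revisits needed but cheap
                if c not in out:
                    out.add(c)
                    frontier.append(c)
        return out

    def roots(self) -> list[str]:
        targets = {t for _, t, _ in self.edges}
        return [g for g in self.genes if g not in targets]


@dataclass
class SimulatedScreen:
    counts: CountMatrix
    guides: GuideMatrix
    truth: dict[str, set[str]]  # target gene -> DAG descendants
    knockdown_frac: float


def simulate_grn(
    n_genes: int,
    m_attach: int = 2,
    frac_negative: float = 0.3,
    seed: int = 0,
) -> PlantedGRN:
    """Preferential-attachment DAG: each new gene links to ``m_attach``
    existing genes with probability proportional to degree + 1, edges
    oriented old -> new; weights uniform in +/-[0.5, 1.5] with
    ``frac_negative`` of them negative."""
    if n_genes < m_attach + 1:
        raise ValueError("n_genes must exceed m_attach")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    degree = np.zeros(n_genes)
    edges: list[tuple[str, str, float]] = []
    parents: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    for new in range(1, n_genes):
        m = min(m_attach, new)
        probs = degree[:new] + 1.0
        probs = probs / probs.sum()
        chosen = rng.choice(new, size=m, replace=False, p=probs)
        for old in sorted(chosen):
            w = rng.uniform(0.5, 1.5)
            if rng.random() < frac_negative:
                w = -w
            edges.append((genes[old], genes[new], float(w)))
            parents[genes[new]].append((genes[old], float(w)))
            degree[old] += 1
            degree[new] += 1
    return PlantedGRN(
        edges=edges,
        genes=genes,
        n_genes=n_genes,
        m_attach=m_attach,
        seed=seed,
        parents=parents,
    )


def _rate(latent: np.ndarray) -> np.ndarray:
    """Exponential link from latent log-rate to Poisson rate, capped so deep
    DAG paths with compounding weights cannot overflow."""
    return np.exp(np.clip(latent, -30.0, np.log(1e6)))


def _simulate_latents(
    grn: PlantedGRN,
    n_cells: int,
    base_rate: float,
    noise_sd: float,
    rng: np.random.Generator,
    knockdown: dict[str, float] | None = None,
) -> np.ndarray:
    """Latent log-rates per cell, propagated in topological order.

    ``knockdown`` maps gene -> multiplier applied to that gene's latent
    before its value feeds downstream genes.
    """
    n = grn.n_genes
    base = np.log(base_rate)
    latents = np.zeros((n_cells, n))
    index = {g: j for j, g in enumerate(grn.genes)}
    for g in grn.genes:
        j = index[g]
        pars = grn.parents.get(g, [])
        if not pars:
            latents[:, j] = rng.normal(base, 1.0, size=n_cells)
        else:
            # weights act on centered parent latents, normalized so the
            # propagated variance cannot compound along deep paths: every
            # gene keeps base_rate scale, as real library-size-normalized
            # expression does
            drive = np.zeros(n_cells)
            norm = max(1.0, np.sqrt(sum(w * w for _, w in pars)))
            for p, w in pars:
                drive += w * (latents[:, index[p]] - base)
            latents[:, j] = base + drive / norm + rng.normal(
                0.0, noise_sd, size=n_cells
            )
        if knockdown and g in knockdown:
            # rate multiplied by the knockdown factor = constant latent shift
            latents[:, j] += np.log(max(knockdown[g], 1e-12))
    return latents


def _counts_from_latents(
    latents: np.ndarray, dropout: float, rng: np.random.Generator
) -> np.ndarray:
    counts = rng.poisson(_rate(latents)).astype(float)
    if dropout > 0:
        counts *= rng.random(counts.shape) >= dropout
    return counts


def simulate_expression(
    grn: PlantedGRN,
    n_cells: int,
    base_rate: float = 5.0,
    noise_sd: float = 0.3,
    dropout: float = 0.5,
    seed: int = 0,
) -> CountMatrix:
    """Sparse overdispersed counts from the planted DAG.

    Root latents ~ Normal(log base_rate, 1); child latents are the
    weight-sum of parent latents plus Normal(0, noise_sd); counts are
    Poisson(exp(latent)) thinned by independent Bernoulli dropout.
    """
    rng = np.random.default_rng(seed)
    latents = _simulate_latents(grn, n_cells, base_rate, noise_sd, rng)
    counts = _counts_from_latents(latents, dropout, rng)
    return CountMatrix(
        values=counts,
        cell_ids=[f"cell{i:05d}" for i in range(n_cells)],
        gene_ids=list(grn.genes),
    )


def simulate_perturbation_screen(
    grn: PlantedGRN,
    targets: list[str],
    cells_per_guide: int = 2000,
    n_control: int | None = None,
    knockdown_frac: float = 0.9,
    base_rate: float = 5.0,
    noise_sd: float = 0.3,
    dropout: float = 0.5,
    seed: int = 0,
) -> SimulatedScreen:
    """Pooled knockdown screen: one guide per target, ``cells_per_guide``
    perturbed cells each plus unperturbed controls.

    In perturbed cells the target's latent is multiplied by
    (1 - knockdown_frac) before feeding downstream genes, so the truth set
    for each guide is the target's DAG descendants.
    """
    unknown = [t for t in targets if t not in grn.genes]
    if unknown:
        raise ValueError(f"targets not in the GRN: {unknown}")
    rng = np.random.default_rng(seed)
    n_control = cells_per_guide if n_control is None else n_control
    blocks = []
    guide_cols = []
    for t in targets:
        latents = _simulate_latents(
            grn,
            cells_per_guide,
            base_rate,
            noise_sd,
            rng,
            knockdown={t: 1.0 - knockdown_frac},
        )
        blocks.append(_counts_from_latents(latents, dropout, rng))
    latents = _simulate_latents(grn, n_control, base_rate, noise_sd, rng)
    blocks.append(_counts_from_latents(latents, dropout, rng))
    counts = np.vstack(blocks)
    n_cells = counts.shape[0]
    guide_ids = [f"guide_{t}" for t in targets]
    gmat = np.zeros((n_cells, len(targets)), dtype=int)
    for gi in range(len(targets)):
        start = gi * cells_per_guide
        gmat[start : start + cells_per_guide, gi] = 1
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    cm = CountMatrix(values=counts, cell_ids=cell_ids, gene_ids=list(grn.genes))
    guides = GuideMatrix(
        values=gmat,
        cell_ids=cell_ids,
        guide_ids=guide_ids,
        target_of={f"guide_{t}": t for t in targets},
    )
    truth = {t: grn.descendants(t) for t in targets}
    return SimulatedScreen(
        counts=cm, guides=guides, truth=truth, knockdown_frac=knockdown_frac
    )


def simulate_batched_phenotypes(
    n_cells: int,
    n_batches: int = 2,
    n_samples: int = 4,
    n_features: int = 30,
    phenotype_effect: float = 1.0,
    batch_effect: float = 1.0,
    sample_effect: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Cell features = phenotype signal + sample offset + batch offset +
    noise, with sample/batch/phenotype labels.

    Samples are nested in batches; phenotype alternates across samples so
    it is balanced within batches.
    """
    if min(n_cells, n_batches, n_samples, n_features) < 1:
        raise ValueError("all sizes must be positive")
    rng = np.random.default_rng(seed)
    sample_of_cell = rng.integers(0, n_samples, size=n_cells)
    batch_of_sample = np.arange(n_samples) % n_batches
    pheno_of_sample = (np.arange(n_samples) // n_batches) % 2
    batch = batch_of_sample[sample_of_cell]
    pheno = pheno_of_sample[sample_of_cell]
    pheno_dirs = rng.normal(size=(2, n_features))
    batch_dirs = rng.normal(size=(n_batches, n_features))
    sample_dirs = rng.normal(size=(n_samples, n_features))
    X = (
        phenotype_effect * pheno_dirs[pheno]
        + batch_effect * batch_dirs[batch]
        + sample_effect * sample_dirs[sample_of_cell]
        + rng.normal(0.0, noise_sd, size=(n_cells, n_features))
    )
    labels = {
        "sample": sample_of_cell,
        "batch": batch,
        "phenotype": pheno,
    }
    return X, labels
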