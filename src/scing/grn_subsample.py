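"""Per-subsample GRN inference: gradient-boosting regressors per target gene
over candidate regulators, with importance-based edge weights and the
top-decile / top-3-per-target edge filter."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor

from .supercell import SupercellMatrix

logger = logging.getLogger("scing")


@dataclass
class GBRHyperparams:
    """Gradient-boosting settings used for every per-target regressor:
    500 trees of depth 3, learning rate 0.01, 90% row subsampling, sqrt
    feature subsampling, and early stopping once training loss stops
    improving over a rolling 25-tree window."""

    n_estimators: int = 500
    max_depth: int = 3
    learning_rate: float = 0.01
    subsample: float = 0.9
    max_features: str | int | float = "sqrt"
    early_stop_window: int = 25

    def __post_init__(self) -> None:
        if not (0 < self.subsample <= 1):
            raise ValueError("subsample must lie in (0, 1]")
        for name in ("n_estimators", "max_depth", "early_stop_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class SubsampleNetwork:
    """Directed edges (regulator, target, importance) from one subsample."""

    regulators: list[str]
    targets: list[str]
    importances: np.ndarray
    subsample_index: int = 0
    cells_used: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regulators)

    def edges(self) -> list[tuple[str, str, float]]:
        return list(zip(self.regulators, self.targets, self.importances))


def draw_subsample(
    supercells: SupercellMatrix, frac: float = 0.7, seed: int = 0
) -> np.ndarray:
    """floor(frac * n) distinct supercell ids, uniform without replacement."""
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    n = supercells.n_supercells
    size = math.floor(frac * n)
    if size < 2:
        raise ValueError(f"subsample of {size} supercells is too small")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n, size=size, replace=False))


def _early_stop_monitor(window: int):
    """Stop boosting when loss improvement over the last ``window`` trees is
    non-positive.

    With row subsampling the out-of-bag improvement (averaged over the
    window to damp its iteration-to-iteration noise) is monitored; without
    subsampling the training loss over the window is used.
    """

    def monitor(i: int, model: GradientBoostingRegressor, locals_) -> bool:
        if i < window:
            return False
        if hasattr(model, "oob_improvement_"):
            return float(np.mean(model.oob_improvement_[i - window + 1 : i + 1])) <= 0
        return model.train_score_[i] >= model.train_score_[i - window]

    return monitor


def fit_target_importances(
    X: np.ndarray,
    y: np.ndarray,
    hp: GBRHyperparams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Impurity-based feature importances of a GBR predicting ``y`` from ``X``.

    Importances are nonnegative and sum to 1 whenever any split occurred;
    a constant target yields the all-zero vector.
    """
    hp = hp or GBRHyperparams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 rows of candidate expression")
    if np.ptp(y) == 0:
        return np.zeros(X.shape[1])
    model = GradientBoostingRegressor(
        n_estimators=hp.n_estimators,
        max_depth=hp.max_depth,
        learning_rate=hp.learning_rate,
        subsample=hp.subsample,
        max_features=hp.max_features,
        random_state=seed,
    )
    model.fit(X, y, monitor=_early_stop_monitor(hp.early_stop_window))
    imp = model.feature_importances_
    imp = np.where(np.isfinite(imp), imp, 0.0)
    imp = np.maximum(imp, 0.0)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return imp


def infer_subsample_network(
    supercells: SupercellMatrix,
    candidates: dict[str, list[str]],
    hp: GBRHyperparams | None = None,
    seed: int = 0,
    subsample_index: int = 0,
    rows: np.ndarray | None = None,
) -> SubsampleNetwork:
    """One network from one supercell subsample.

    For each target gene with at least one candidate regulator, a GBR is
    fit on the subsample rows; every candidate with positive importance
    contributes a directed edge into the target.  Targets constant in the
    subsample are skipped.  Per-target seeds are spawned deterministically
    from ``seed``.
    """
    hp = hp or GBRHyperparams()
    values = supercells.values if rows is None else supercells.values[rows]
    gene_index = {g: j for j, g in enumerate(supercells.gene_ids)}
    regulators: list[str] = []
    targets: list[str] = []
    importances: list[float] = []
    ss = np.random.SeedSequence(seed)
    for t_idx, target in enumerate(supercells.gene_ids):
        cand = [g for g in candidates.get(target, []) if g in gene_index and g != target]
        if not cand:
            continue
        y = values[:, gene_index[target]]
        if np.ptp(y) == 0:
            continue
        X = values[:, [gene_index[g] for g in cand]]
        child_seed = int(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(t_idx,)).generate_state(1)[0]
            % (2**31)
        )
        imp = fit_target_importances(X, y, hp, seed=child_seed)
        for g, w in zip(cand, imp):
            if w > 0:
                regulators.append(g)
                targets.append(target)
                importances.append(float(w))
    return SubsampleNetwork(
        regulators=regulators,
        targets=targets,
        importances=np.asarray(importances, dtype=float),
        subsample_index=subsample_index,
        cells_used=[] if rows is None else [int(r) for r in rows],
    )


def filter_subsample_edges(
    net: SubsampleNetwork,
    top_frac: float = 0.1,
    top_per_target: int = 3,
) -> SubsampleNetwork:
    """Keep the union of the global top decile of edges by importance and the
    top 3 edges per downstream gene.

    Ties are broken by (importance descending, regulator id ascending).
    """
    m = len(net)
    if m == 0:
        raise ValueError("empty subsample network")
    order = sorted(
        range(m),
        key=lambda i: (-net.importances[i], net.regulators[i], net.targets[i]),
    )
    n_global = math.ceil(top_frac * m)
    keep = set(order[:n_global])
    per_target: dict[str, list[int]] = {}
    for i in order:
        per_target.setdefault(net.targets[i], []).append(i)
    for idxs in per_target.values():
        keep.update(idxs[:top_per_target])
    kept = sorted(keep, key=lambda i: (net.targets[i], net.regulators[i]))
    return SubsampleNetwork(
        regulators=[net.regulators[i] for i in kept],
        targets=[net.targets[i] for i in kept],
        importances=net.importances[kept],
        subsample_index=net.subsample_index,
        cells_used=net.cells_used,
    )
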