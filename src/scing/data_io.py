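"""Readers and writers for counts, edge lists, gene sets and run configuration.

On-disk conventions
-------------------
* Count matrices: 10x-style Matrix Market directories (``matrix.mtx`` +
  ``barcodes.tsv`` + ``features.tsv``/``genes.tsv``, genes x cells on disk,
  transposed to cells x genes in memory) or dense TSV (cells as rows).
* Edge lists: TSV with header ``source	target	weight[	support]``; weights
  are serialized with 17 significant digits so consensus weights round-trip
  bit-faithfully.
* Gene sets: standard GMT (name, description, genes; tab-separated).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("scing")


@dataclass
class CountMatrix:
    """Raw cell-by-gene nonnegative counts.

    ``gene_ids`` may contain duplicates straight off disk; duplicates are
    flagged here and removed during preprocessing (first occurrence kept).
    """

    values: np.ndarray  # cells x genes, dense float64
    cell_ids: list[str]
    gene_ids: list[str]
    has_duplicate_genes: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[0]} rows"
            )
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[1]} columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("negative count")
        self.has_duplicate_genes = len(set(self.gene_ids)) != len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class EdgeList:
    """Directed weighted edge set; the universal network carrier.

    ``support`` (optional) counts the subsample networks containing each edge.
    """

    source: list[str]
    target: list[str]
    weight: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=int)
        if not (len(self.source) == len(self.target) == len(self.weight)):
            raise ValueError("edge list columns must have equal length")
        if np.any(self.weight < 0):
            raise ValueError("edge weights must be nonnegative")
        pairs = list(zip(self.source, self.target))
        if len(set(pairs)) != len(pairs):
            seen: set[tuple[str, str]] = set()
            for p in pairs:
                if p in seen:
                    raise ValueError(f"duplicate edge {p[0]}->{p[1]}")
                seen.add(p)

    def __len__(self) -> int:
        return len(self.source)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.source, self.target))

    def genes(self) -> list[str]:
        return sorted(set(self.source) | set(self.target))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"source": self.source, "target": self.target, "weight": self.weight}
        )
        if self.support is not None:
            df["support"] = self.support
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EdgeList":
        support = df["support"].to_numpy() if "support" in df.columns else None
        return cls(
            source=df["source"].astype(str).tolist(),
            target=df["target"].astype(str).tolist(),
            weight=df["weight"].to_numpy(dtype=float),
            support=support,
        )

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple], with_support: bool = False
    ) -> "EdgeList":
        rows = list(edges)
        if not rows:
            return cls(
                source=[],
                target=[],
                weight=np.empty(0),
                support=np.empty(0, dtype=int) if with_support else None,
            )
        src = [str(r[0]) for r in rows]
        tgt = [str(r[1]) for r in rows]
        wts = np.array([float(r[2]) for r in rows])
        sup = (
            np.array([int(r[3]) for r in rows])
            if with_support or (len(rows[0]) > 3)
            else None
        )
        return cls(source=src, target=tgt, weight=wts, support=sup)


@dataclass
class RunConfig:
    """Pipeline defaults: 500 supercells, 100 subsample networks at 70%,
    100 candidate neighbors per gene over 10 gene PCs, 20% edge consensus,
    1.25 direction ratio, CMI pruning at alpha 0.05 with 4 bins."""

    n_supercells: int = 500
    n_networks: int = 100
    subsample_frac: float = 0.7
    n_candidate_neighbors: int = 100
    n_gene_pcs: int = 10
    consensus_frac: float = 0.2
    direction_ratio: float = 1.25
    cmi_alpha: float = 0.05
    cmi_bins: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subsample_frac", "consensus_frac", "cmi_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in (
            "n_supercells",
            "n_networks",
            "n_candidate_neighbors",
            "n_gene_pcs",
            "cmi_bins",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.direction_ratio <= 1:
            raise ValueError("direction_ratio must exceed 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_counts(path: str | Path, format: str = "mtx_dir") -> CountMatrix:
    """Load a count matrix from a 10x-style MTX directory or a dense TSV.

    MTX directories store genes x cells; the matrix is transposed so that
    cells are rows.  Duplicate gene ids are kept (and flagged) — they are
    dropped later in preprocessing.
    """
    path = Path(path)
    if format == "mtx_dir":
        if not path.is_dir():
            raise FileNotFoundError(f"{path} is not a directory")
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        if not features.exists():
            features = path / "genes.tsv"
        for f in (mtx, barcodes, features):
            if not f.exists():
                raise FileNotFoundError(f"missing {f.name} in {path}")
        mat = sp.csr_matrix(scipy.io.mmread(mtx))
        cell_ids = _read_id_column(barcodes)
        gene_ids = _read_id_column(features)
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix is {mat.shape} but found {len(gene_ids)} genes "
                f"and {len(cell_ids)} barcodes"
            )
        values = np.asarray(mat.T.todense(), dtype=float)
    elif format == "dense_tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        # header parsed by hand so duplicate gene columns are not mangled
        df = pd.read_csv(
            path, sep="\t", index_col=0, header=None, skiprows=1,
            float_precision="round_trip",
        )
        values = df.to_numpy(dtype=float)
        cell_ids = df.index.astype(str).tolist()
        gene_ids = [str(g) for g in header[1:]]
    else:
        raise ValueError(f"unknown format {format!r}")
    cm = CountMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)
    if cm.has_duplicate_genes:
        logger.warning("duplicate gene ids found in %s; first occurrence kept", path)
    return cm


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            # 10x features.tsv carries (id, symbol, type); use the first column
            ids.append(fields[0])
    return ids


def write_counts_mtx(counts: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as a 10x-style MTX directory (genes x cells)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(counts.values.T))
    (path / "barcodes.tsv").write_text("\n".join(counts.cell_ids) + "\n")
    (path / "features.tsv").write_text("\n".join(counts.gene_ids) + "\n")


def write_counts_tsv(counts: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        counts.values, index=counts.cell_ids, columns=counts.gene_ids
    ).to_csv(path, sep="\t")


def write_edge_list(net: EdgeList, path: str | Path) -> None:
    """Serialize an edge list as TSV; weights keep 17 significant digits."""
    with open(path, "w") as fh:
        cols = ["source", "target", "weight"]
        if net.support is not None:
            cols.append("support")
        fh.write("\t".join(cols) + "\n")
        for i in range(len(net)):
            row = [net.source[i], net.target[i], format(net.weight[i], ".17g")]
            if net.support is not None:
                row.append(str(int(net.support[i])))
            fh.write("\t".join(row) + "\n")


def read_edge_list(path: str | Path) -> EdgeList:
    df = pd.read_csv(
        path, sep="\t", dtype={"source": str, "target": str},
        float_precision="round_trip",
    )
    required = {"source", "target", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    if df[["source", "target"]].duplicated().any():
        dup = df[df[["source", "target"]].duplicated()].iloc[0]
        raise ValueError(f"duplicate edge {dup['source']}->{dup['target']}")
    return EdgeList.from_frame(df)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: [genes]}`` (within-set dedup,
    first occurrence order preserved)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"GMT set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gene_sets(sets: Mapping[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")
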