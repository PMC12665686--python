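"""Expression-matrix, label-hierarchy and gene-embedding I/O plus dataset splits.

Containers are deliberately light: a dense cells x genes array with id
vectors, a 4-level label table with downward propagation (deepest assigned
label fills the levels below it), and a gene -> vector embedding table.
Readers accept MatrixMarket triplets with 10x-style sidecars, dense
CSV/TSV, and H5AD containers; all readers validate non-negativity and id
uniqueness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "LabelTable",
    "GeneEmbeddingTable",
    "SplitAssignment",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "propagate_labels",
    "read_embeddings",
    "write_embeddings",
    "split_dataset",
]

N_LEVELS = 4
PARTITIONS = ("train", "val", "test")


def _check_unique(ids: Sequence[str], axis: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).duplicated()
        raise ValueError(f"duplicate {axis} ids: {sorted(set(np.array(ids)[dup]))[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Cells x genes non-negative expression values with id vectors."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if sparse.issparse(self.values):  # pragma: no cover - asarray densifies
            self.values = self.values.toarray()
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)"
            )
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative expression at (cell {i} '{self.cell_ids[i]}', "
                f"gene {j} '{self.gene_ids[j]}'): {self.values[i, j]}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            self.values[:, keep],
            list(self.cell_ids),
            [self.gene_ids[j] for j in keep],
        )

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            self.values[keep],
            [self.cell_ids[i] for i in keep],
            list(self.gene_ids),
        )


@dataclass
class LabelTable:
    """Per-cell labels over a <=4-level cell-type hierarchy.

    ``levels`` is an (n_cells, 4) object array. Every cell must carry a
    level-1 (major category) label; deeper unassigned levels are filled
    downward from the deepest assigned label, so e.g. a cell whose deepest
    label is "plasma B cells" at level 3 is also "plasma B cells" at level 4.
    """

    cell_ids: list[str]
    levels: np.ndarray
    class_set_level1: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        lv = np.asarray(self.levels, dtype=object)
        if lv.ndim != 2 or lv.shape[1] != N_LEVELS:
            raise ValueError(f"levels must be (n, {N_LEVELS}), got {lv.shape}")
        if lv.shape[0] != len(self.cell_ids):
            raise ValueError("levels row count does not match cell_ids")
        self.levels = propagate_labels(lv)
        for i in range(len(self.cell_ids)):
            if not self.levels[i, 0]:
                raise ValueError(f"cell '{self.cell_ids[i]}' has no level-1 label")
        if not self.class_set_level1:
            self.class_set_level1 = sorted({str(x) for x in self.levels[:, 0]})
        if len(self.class_set_level1) < 2:
            warnings.warn("fewer than 2 level-1 classes", stacklevel=2)

    @property
    def level1(self) -> np.ndarray:
        return self.levels[:, 0].astype(str)

    def reindex(self, cell_ids: Sequence[str]) -> "LabelTable":
        """Return a table aligned to ``cell_ids`` order."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise KeyError(f"cells without labels: {missing[:5]}")
        idx = [pos[c] for c in cell_ids]
        return LabelTable(list(cell_ids), self.levels[idx], list(self.class_set_level1))


def propagate_labels(levels: np.ndarray) -> np.ndarray:
    """Fill empty deeper levels downward from the deepest assigned label.

    Idempotent: a second application is a no-op.
    """
    out = np.asarray(levels, dtype=object).copy()
    for i in range(out.shape[0]):
        for k in range(out.shape[1]):
            v = out[i, k]
            v = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
            out[i, k] = v
        for k in range(1, out.shape[1]):
            if not out[i, k]:
                out[i, k] = out[i, k - 1]
    return out


@dataclass
class GeneEmbeddingTable:
    """Gene symbol -> d_embed vector (Gene2vec-style; default d=200)."""

    gene_ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.gene_ids):
            raise ValueError("one vector per gene id required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")

    @property
    def d_embed(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return self.vectors[[pos[g] for g in gene_ids]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


@dataclass
class SplitAssignment:
    """cell_id -> partition in {train, val, test}."""

    assignment: Mapping[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def ids(self, partition: str) -> list[str]:
        return [c for c, p in self.assignment.items() if p == partition]

    def indices(self, cell_ids: Sequence[str], partition: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(cell_ids) if self.assignment[c] == partition],
            dtype=int,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    if suffix in (".h5ad", ".h5"):
        return "h5ad"
    raise ValueError(f"cannot infer expression format from '{path.name}'")


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from MTX (+ sidecars), dense CSV/TSV or H5AD.

    The MTX file follows the 10x convention (rows = genes, columns = cells)
    with ``genes.tsv`` and ``barcodes.tsv`` sidecars in the same directory;
    it is transposed to cells x genes in memory. Dense CSV/TSV carries gene
    ids in the header and cell ids in the first column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        genes_f = path.parent / "genes.tsv"
        barcodes_f = path.parent / "barcodes.tsv"
        for side in (genes_f, barcodes_f):
            if not side.exists():
                raise FileNotFoundError(
                    f"MTX sidecar missing: expected '{side.name}' next to '{path.name}'"
                )
        mat = spio.mmread(path)
        genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str).tolist()
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
        if dense.shape != (len(genes), len(cells)):
            raise ValueError(
                f"mtx shape {dense.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} barcodes)"
            )
        return ExpressionMatrix(dense.T, cells, genes)
    if fmt == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=np.float64),
            df.index.astype(str).tolist(),
            df.columns.astype(str).tolist(),
        )
    if fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        dense = np.asarray(X.todense() if sparse.issparse(X) else X, dtype=np.float64)
        return ExpressionMatrix(
            dense, adata.obs_names.astype(str).tolist(), adata.var_names.astype(str).tolist()
        )
    raise ValueError(f"unknown expression format '{fmt}'")


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, format: str | None = None
) -> Path:
    """Write in any supported format; MTX gains genes/barcodes sidecars."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(matrix.values.T))
        pd.Series(matrix.gene_ids).to_csv(
            path.parent / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(matrix.cell_ids).to_csv(
            path.parent / "barcodes.tsv", sep="\t", header=False, index=False
        )
    elif fmt == "csv":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=matrix.gene_ids).to_csv(
            path, sep=sep
        )
    elif fmt == "h5ad":
        import anndata as ad

        adata = ad.AnnData(X=matrix.values.copy())
        adata.obs_names = matrix.cell_ids
        adata.var_names = matrix.gene_ids
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown expression format '{fmt}'")
    return path


def read_labels(path: str | Path) -> LabelTable:
    """Read a TSV label table: cell_id then up to 4 hierarchy levels."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str).fillna("")
    if df.shape[1] < 2 or df.shape[1] > 1 + N_LEVELS:
        raise ValueError(
            f"label table needs a cell id column and 1-{N_LEVELS} level columns"
        )
    cells = df.iloc[:, 0].astype(str).str.strip().tolist()
    lv = np.full((len(cells), N_LEVELS), "", dtype=object)
    for k in range(df.shape[1] - 1):
        lv[:, k] = df.iloc[:, k + 1].astype(str).str.strip().to_numpy(dtype=object)
    return LabelTable(cells, lv)


def write_labels(labels: LabelTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        labels.levels, columns=[f"level{k}" for k in range(1, N_LEVELS + 1)]
    )
    df.insert(0, "cell_id", labels.cell_ids)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_embeddings(path: str | Path) -> GeneEmbeddingTable:
    """Read a headerless TSV of gene_id followed by d_embed floats."""
    df = pd.read_csv(Path(path), sep="\t", header=None)
    return GeneEmbeddingTable(
        df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1:].to_numpy(dtype=np.float64)
    )


def write_embeddings(table: GeneEmbeddingTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(table.vectors)
    df.insert(0, "gene_id", table.gene_ids)
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.8g")
    return path


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _allocate(n: int, ratios: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to len(ratios) partitions."""
    raw = n * ratios
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def split_dataset(
    matrix: ExpressionMatrix,
    labels: LabelTable,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 2022,
    stratified: bool = True,
) -> SplitAssignment:
    """Partition cells into train/val/test at the requested ratios.

    Stratified (the default) allocates within each level-1 class by largest
    remainder, so realized per-class fractions are within one cell of the
    requested ratios. Deterministic for a fixed seed.
    """
    ratios_arr = np.asarray(ratios, dtype=float)
    if ratios_arr.shape != (3,) or np.any(ratios_arr < 0):
        raise ValueError("ratios must be three non-negative numbers")
    if not np.isclose(ratios_arr.sum(), 1.0):
        raise ValueError(f"ratios must sum to 1, got {ratios_arr.sum()}")
    aligned = labels.reindex(matrix.cell_ids)
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    if stratified:
        strata = [
            np.flatnonzero(aligned.level1 == c) for c in sorted(set(aligned.level1))
        ]
    else:
        strata = [np.arange(matrix.n_cells)]
    n_nonzero_parts = int(np.count_nonzero(ratios_arr))
    for idx in strata:
        if stratified and len(idx) < n_nonzero_parts:
            warnings.warn(
                f"stratum of size {len(idx)} smaller than number of partitions; "
                "best-effort assignment",
                stacklevel=2,
            )
        perm = rng.permutation(idx)
        counts = _allocate(len(idx), ratios_arr)
        start = 0
        for part, c in zip(PARTITIONS, counts):
            for i in perm[start : start + c]:
                assignment[matrix.cell_ids[i]] = part
            start += c
    return SplitAssignment(assignment, tuple(ratios_arr), seed)
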