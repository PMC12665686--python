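"""Gene filtering, expression binning and cell tokenization.

A cell enters the encoder as a fixed-order sequence of (gene, expression
bin) tokens over the filtered gene vocabulary. Genes are kept when they are
expressed in at least one cell *and* appear in the gene-embedding
vocabulary, which acts as a knowledge-based feature filter restricting the
model to characterized genes. Expression values are discretized into B
bins: bin 0 is reserved for exactly-zero expression, and the remaining
nonzero mass is spread over bins 1..B-1 by empirical quantiles of the
(optionally log1p-transformed) nonzero training values. Edges are frozen at
fit time and serialized with the model so inference reuses training-time
bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data import ExpressionMatrix, GeneEmbeddingTable

__all__ = [
    "BinningScheme",
    "BinnedCell",
    "filter_genes",
    "fit_bins",
    "tokenize_cell",
    "tokenize_matrix",
    "ExpressionTokenizer",
]

_TRANSFORMS = {"identity": lambda v: v, "log1p": np.log1p}


@dataclass
class BinningScheme:
    """B-bin discretization with bin 0 reserved for zero expression.

    ``edges`` are the B-1 empirical quantiles (levels k/(B-1), k=1..B-1) of
    the transformed nonzero training values; a nonzero value lands in
    1 + (number of edges strictly below it), capped at B-1, so the training
    maximum maps to the top bin.
    """

    n_bins: int
    edges: np.ndarray
    transform: str = "log1p"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform '{self.transform}'")
        self.edges = np.asarray(self.edges, dtype=np.float64)
        exp_shape = (self.n_bins - 1,)
        if self.edges.ndim == 2:
            exp_shape = (self.edges.shape[0], self.n_bins - 1)
        if self.edges.shape != exp_shape:
            raise ValueError(f"edges shape {self.edges.shape}, expected {exp_shape}")
        if np.any(np.diff(self.edges, axis=-1) < 0):
            raise ValueError("edges must be non-decreasing")

    @property
    def per_gene(self) -> bool:
        return self.edges.ndim == 2

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin ids for non-negative values; shape-preserving and monotone."""
        v = np.asarray(values, dtype=np.float64)
        if np.any(v < 0):
            raise ValueError("negative expression value")
        t = _TRANSFORMS[self.transform](v)
        if self.per_gene:
            if v.shape[-1] != self.edges.shape[0]:
                raise ValueError("row length does not match per-gene edge table")
            # each gene's value against its own edge row
            below = np.sum(t[..., :, None] > self.edges, axis=-1)
        else:
            below = np.searchsorted(self.edges, t, side="left")
        bins = np.minimum(1 + below, self.n_bins - 1)
        bins[v == 0] = 0
        return bins.astype(np.int64)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_bins": self.n_bins,
                "transform": self.transform,
                "edges": self.edges.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BinningScheme":
        d = json.loads(text)
        return cls(d["n_bins"], np.asarray(d["edges"]), d["transform"])


@dataclass
class BinnedCell:
    """One cell as aligned (gene index, bin id) token sequences."""

    gene_indices: np.ndarray
    bin_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=np.int64)
        self.bin_ids = np.asarray(self.bin_ids, dtype=np.int64)
        if self.gene_indices.shape != self.bin_ids.shape:
            raise ValueError("gene_indices and bin_ids must align")

    def __len__(self) -> int:
        return len(self.bin_ids)


def filter_genes(
    matrix: ExpressionMatrix, vocab: GeneEmbeddingTable
) -> tuple[ExpressionMatrix, dict]:
    """Keep genes expressed somewhere and present in the embedding vocabulary.

    Returns the filtered matrix (original gene order preserved) and a report
    of what was dropped and why. Idempotent.
    """
    expressed = np.asarray((matrix.values > 0).any(axis=0))
    in_vocab = np.array([g in set(vocab.gene_ids) for g in matrix.gene_ids])
    keep = expressed & in_vocab
    report = {
        "n_input": matrix.n_genes,
        "n_retained": int(keep.sum()),
        "dropped_all_zero": [g for g, e in zip(matrix.gene_ids, expressed) if not e],
        "dropped_out_of_vocab": [
            g for g, iv, e in zip(matrix.gene_ids, in_vocab, expressed) if e and not iv
        ],
    }
    if not keep.any():
        raise ValueError(
            "no genes retained after filtering; check that the embedding "
            "vocabulary matches the matrix gene identifiers"
        )
    return matrix.subset_genes(np.flatnonzero(keep)), report


def fit_bins(
    matrix: ExpressionMatrix | np.ndarray,
    n_bins: int = 7,
    transform: str = "log1p",
    per_gene: bool = False,
) -> BinningScheme:
    """Quantile bin edges from the nonzero values of a training matrix."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    t = _TRANSFORMS[transform](values.astype(np.float64))
    levels = np.arange(1, n_bins) / (n_bins - 1)
    if per_gene:
        edges = np.empty((values.shape[1], n_bins - 1))
        for j in range(values.shape[1]):
            nz = t[:, j][values[:, j] > 0]
            if nz.size == 0:
                raise ValueError(f"gene column {j} has no nonzero values to bin")
            edges[j] = np.quantile(nz, levels)
    else:
        nz = t[values > 0]
        if nz.size == 0:
            raise ValueError("all values are zero; nothing to bin")
        edges = np.quantile(nz, levels)
    return BinningScheme(n_bins, edges, transform)


def tokenize_cell(row: np.ndarray, scheme: BinningScheme) -> BinnedCell:
    """Tokenize one expression row; output order equals vocabulary order."""
    row = np.asarray(row, dtype=np.float64)
    if row.ndim != 1:
        raise ValueError("expected a single expression row")
    return BinnedCell(np.arange(row.size), scheme.assign(row))


def tokenize_matrix(matrix: ExpressionMatrix | np.ndarray, scheme: BinningScheme) -> np.ndarray:
    """(n_cells, L) bin-id array for a whole matrix."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix)
    return scheme.assign(values)


class ExpressionTokenizer(TransformerMixin, BaseEstimator):
    """Vocabulary filtering + quantile binning as an sklearn transformer.

    Fit on training cells only, so bin edges never leak information from
    evaluation data. ``transform`` returns the (n_cells, seq_len) integer
    bin-id array consumed by the encoder; gene order is frozen at fit time
    in ``gene_ids_``.

    Parameters
    ----------
    n_bins : total bin count B (bin 0 = zero expression).
    value_transform : "log1p" (default) or "identity" value transform.
    per_gene : fit a separate edge set per gene instead of one global set.
    vocab : optional GeneEmbeddingTable restricting the gene space.
    """

    def __init__(self, n_bins: int = 7, value_transform: str = "log1p",
                 per_gene: bool = False, vocab: GeneEmbeddingTable | None = None):
        self.n_bins = n_bins
        self.value_transform = value_transform
        self.per_gene = per_gene
        self.vocab = vocab

    def fit(self, X: ExpressionMatrix | np.ndarray, y=None) -> "ExpressionTokenizer":
        if isinstance(X, ExpressionMatrix):
            if self.vocab is not None:
                X, self.filter_report_ = filter_genes(X, self.vocab)
            else:
                keep = np.flatnonzero(np.asarray((X.values > 0).any(axis=0)))
                self.filter_report_ = {"n_input": X.n_genes, "n_retained": len(keep)}
                X = X.subset_genes(keep)
            self.gene_ids_ = list(X.gene_ids)
            values = X.values
        else:
            values = np.asarray(X, dtype=np.float64)
            self.gene_ids_ = [f"g{j}" for j in range(values.shape[1])]
            self.filter_report_ = {"n_input": values.shape[1], "n_retained": values.shape[1]}
        self.scheme_ = fit_bins(values, self.n_bins, self.value_transform, self.per_gene)
        self.seq_len_ = len(self.gene_ids_)
        return self

    def transform(self, X: ExpressionMatrix | np.ndarray) -> np.ndarray:
        check_is_fitted(self, "scheme_")
        if isinstance(X, ExpressionMatrix):
            pos = {g: j for j, g in enumerate(X.gene_ids)}
            missing = [g for g in self.gene_ids_ if g not in pos]
            if missing:
                raise ValueError(f"matrix lacks fitted vocabulary genes: {missing[:5]}")
            values = X.values[:, [pos[g] for g in self.gene_ids_]]
        else:
            values = np.asarray(X, dtype=np.float64)
            if values.shape[1] != self.seq_len_:
                raise ValueError(
                    f"expected {self.seq_len_} genes, got {values.shape[1]}"
                )
        return tokenize_matrix(values, self.scheme_)

    def save(self, path: str | Path) -> Path:
        check_is_fitted(self, "scheme_")
        path = Path(path)
        path.write_text(json.dumps({
            "scheme": json.loads(self.scheme_.to_json()),
            "gene_ids": self.gene_ids_,
            "params": {"n_bins": self.n_bins, "value_transform": self.value_transform,
                       "per_gene": self.per_gene},
        }))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ExpressionTokenizer":
        d = json.loads(Path(path).read_text())
        tok = cls(**d["params"])
        tok.scheme_ = BinningScheme.from_json(json.dumps(d["scheme"]))
        tok.gene_ids_ = list(d["gene_ids"])
        tok.seq_len_ = len(tok.gene_ids_)
        tok.filter_report_ = {}
        return tok
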