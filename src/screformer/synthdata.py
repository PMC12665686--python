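"""Synthetic scRNA-seq fixtures with planted cell-type structure.

Counts follow a gamma-Poisson (negative-binomial) model, the standard
overdispersion model for UMI counts: gene j has a baseline mean drawn
log-normally around ``base_mean``, multiplied by ``fold_change`` at the
marker genes of the cell's own type, with independent dropout zeroing to
mimic capture inefficiency. Labels form a 4-level hierarchy (level 1 = the
planted types, deeper levels generated sub-labels with downward
propagation), and a Gene2vec-style embedding table places each type's
marker module on a shared latent direction so that co-functional genes are
mutually similar — the property the real embeddings are used for.

The defaults (2000 cells x 300 genes, 5 types x 10 markers, fold change 6,
dropout 0.3) plant an unambiguous signal: a nearest-centroid classifier on
the true markers exceeds 90% accuracy, so end-to-end tests probe the model,
not the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, GeneEmbeddingTable, LabelTable

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "generate_embeddings"]


@dataclass
class SyntheticSpec:
    """Generative conditions for one synthetic dataset."""

    n_cells: int = 2000
    n_genes: int = 300
    n_types: int = 5
    markers_per_type: int = 10
    fold_change: float = 6.0
    base_mean: float = 1.0
    dispersion: float = 2.0
    dropout_rate: float = 0.3
    type_proportions: tuple | None = None
    d_embed: int = 200
    embed_within_sim: float = 0.8
    vocab_omit_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValueError("marker modules do not fit into the gene space")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.vocab_omit_fraction < 1:
            raise ValueError("vocab_omit_fraction must be in [0, 1)")
        if self.type_proportions is None:
            self.type_proportions = tuple([1.0 / self.n_types] * self.n_types)
        props = np.asarray(self.type_proportions, dtype=float)
        if props.shape != (self.n_types,) or not np.isclose(props.sum(), 1.0):
            raise ValueError("type_proportions must be a simplex vector over n_types")


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    labels: LabelTable
    truth: dict[str, list[str]]  # type name -> marker gene ids
    embeddings: GeneEmbeddingTable
    type_of_cell: np.ndarray = field(default=None)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"G{j:04d}" for j in range(spec.n_genes)]
    cell_ids = [f"C{i:05d}" for i in range(spec.n_cells)]
    type_names = [f"type{t}" for t in range(spec.n_types)]

    # disjoint marker modules at the front of the gene order
    truth = {
        type_names[t]: gene_ids[t * spec.markers_per_type : (t + 1) * spec.markers_per_type]
        for t in range(spec.n_types)
    }
    marker_idx = {
        t: np.arange(t * spec.markers_per_type, (t + 1) * spec.markers_per_type)
        for t in range(spec.n_types)
    }

    cell_types = rng.choice(spec.n_types, size=spec.n_cells,
                            p=np.asarray(spec.type_proportions))
    gene_base = spec.base_mean * rng.lognormal(mean=0.0, sigma=0.5, size=spec.n_genes)

    means = np.tile(gene_base, (spec.n_cells, 1))
    for t in range(spec.n_types):
        rows = cell_types == t
        means[np.ix_(rows, marker_idx[t])] *= spec.fold_change
    # gamma-Poisson: variance = mu + mu^2 / dispersion
    lam = rng.gamma(shape=spec.dispersion, scale=means / spec.dispersion)
    counts = rng.poisson(lam).astype(np.float64)
    if spec.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= spec.dropout_rate

    levels = np.empty((spec.n_cells, 4), dtype=object)
    sub2 = rng.integers(0, 2, size=spec.n_cells)
    sub3 = rng.integers(0, 2, size=spec.n_cells)
    has_l3 = rng.random(spec.n_cells) < 0.7  # some branches stop early -> propagation fills
    has_l4 = has_l3 & (rng.random(spec.n_cells) < 0.5)
    for i in range(spec.n_cells):
        t = type_names[cell_types[i]]
        levels[i, 0] = t
        levels[i, 1] = f"{t}.{sub2[i]}"
        levels[i, 2] = f"{t}.{sub2[i]}.{sub3[i]}" if has_l3[i] else ""
        levels[i, 3] = f"{t}.{sub2[i]}.{sub3[i]}.leaf" if has_l4[i] else ""

    emb_seed = int(rng.integers(2**31))
    embeddings = generate_embeddings(
        truth, gene_ids, d_embed=spec.d_embed, within_sim=spec.embed_within_sim,
        seed=emb_seed,
    )
    if spec.vocab_omit_fraction > 0:
        non_marker = [g for g in gene_ids if not any(g in m for m in truth.values())]
        n_omit = int(round(spec.vocab_omit_fraction * spec.n_genes))
        omit = set(rng.choice(non_marker, size=min(n_omit, len(non_marker)),
                              replace=False).tolist())
        keep = [j for j, g in enumerate(embeddings.gene_ids) if g not in omit]
        embeddings = GeneEmbeddingTable(
            [embeddings.gene_ids[j] for j in keep], embeddings.vectors[keep]
        )

    return SyntheticDataset(
        matrix=ExpressionMatrix(counts, cell_ids, gene_ids),
        labels=LabelTable(cell_ids, levels),
        truth=truth,
        embeddings=embeddings,
        type_of_cell=cell_types,
    )


def generate_embeddings(truth: dict[str, list[str]], gene_ids: list[str],
                        d_embed: int = 200, within_sim: float = 0.8,
                        seed: int = 0) -> GeneEmbeddingTable:
    """Unit-norm gene vectors in which marker modules share a latent direction.

    Markers of one type mix a module direction u_t with isotropic noise so
    the expected within-module cosine similarity is ``within_sim``; module
    directions are mutually orthogonal, so between-module similarity is
    near zero. Non-marker genes are isotropic.
    """
    if not 0 < within_sim < 1:
        raise ValueError("within_sim must lie strictly between 0 and 1")
    n_modules = len(truth)
    if d_embed < max(2 * n_modules, 4):
        raise ValueError(
            f"d_embed={d_embed} too small for {n_modules} orthogonal marker modules"
        )
    rng = np.random.default_rng(seed)
    # orthonormal module directions via QR
    raw = rng.standard_normal((d_embed, n_modules))
    q, _ = np.linalg.qr(raw)
    directions = {name: q[:, t] for t, name in enumerate(truth)}
    module_of = {g: name for name, genes in truth.items() for g in genes}
    a = np.sqrt(within_sim)
    b = np.sqrt(1.0 - within_sim)
    vectors = np.empty((len(gene_ids), d_embed))
    for j, g in enumerate(gene_ids):
        noise = rng.standard_normal(d_embed)
        noise /= np.linalg.norm(noise)
        if g in module_of:
            v = a * directions[module_of[g]] + b * noise
        else:
            v = noise
        vectors[j] = v / np.linalg.norm(v)
    return GeneEmbeddingTable(list(gene_ids), vectors)
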