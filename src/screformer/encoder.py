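"""The Reformer encoder: summed input embeddings, LSH attention, reversible stack.

A tokenized cell (one bin id per gene, fixed gene order) is embedded as the
sum of three terms — a per-gene identity embedding (optionally initialized
from a Gene2vec-style table), a learned embedding of the expression bin,
and the standard sinusoidal positional encoding — then passed through
``n_layers`` reversible blocks pairing a shared-QK multi-head attention
sublayer with a position-wise feed-forward sublayer. The output is one
d_model-dimensional feature vector per gene.

Attention can run in ``lsh`` mode (bucket-restricted, the default) or
``full`` mode (every pair), which supports ablation of the LSH mechanism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn.functional import (
    BucketAssignment,
    bucket_mask,
    full_attention,
    lsh_attention,
    lsh_hash,
)
from ._nn.layers import (AttentionSublayer, FeedForwardSublayer,
                         layernorm_backward, layernorm_forward)
from ._nn.reversible import (
    block_backward_recompute,
    block_backward_stored,
    block_forward,
    reversible_forward,
    reversible_inverse,
)

__all__ = [
    "EncoderConfig",
    "ReformerEncoder",
    "sinusoidal_positions",
    "embed_tokens",
    "encode",
    "full_attention",
    "lsh_hash",
    "lsh_attention",
    "BucketAssignment",
    "bucket_mask",
    "reversible_forward",
    "reversible_inverse",
]

MASK_TOKEN_OFFSET = 0  # the MASK token is bin id n_bins (one past the last bin)


@dataclass
class EncoderConfig:
    """Architecture hyperparameters.

    Defaults are sized for atlas-scale gene vocabularies (d_model 200,
    6 layers, 10 heads, 64 LSH buckets); desk-scale runs shrink these freely.
    """

    seq_len: int
    d_model: int = 200
    n_layers: int = 6
    n_heads: int = 10
    n_buckets: int = 64
    n_hash_rounds: int = 4
    n_bins: int = 7
    d_ff: int | None = None
    dropout: float = 0.1
    attention: str = "lsh"
    exclude_self: bool = False
    hash_seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.n_buckets % 2:
            raise ValueError("n_buckets must be even")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.attention not in ("lsh", "full"):
            raise ValueError("attention must be 'lsh' or 'full'")
        if self.d_ff is None:
            self.d_ff = 2 * self.d_model

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "EncoderConfig":
        return cls(**json.loads(text))


def sinusoidal_positions(seq_len: int, d_model: int) -> np.ndarray:
    """Standard sin/cos positional encoding over positions 0..seq_len-1."""
    pos = np.arange(seq_len, dtype=np.float64)[:, None]
    i = np.arange(d_model, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.empty((seq_len, d_model))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


class ReformerEncoder:
    """Trainable encoder mapping (batch, seq_len) bin ids to per-gene features.

    The bin-embedding table has ``n_bins + 1`` rows; the extra row is the
    reserved MASK token used during masked-expression pre-training. Hash
    rotations for LSH attention are drawn once per layer from
    ``config.hash_seed`` and fixed, so evaluation is deterministic.
    """

    def __init__(self, config: EncoderConfig, seed: int = 0,
                 gene_embeddings: np.ndarray | None = None):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.d_model
        if gene_embeddings is not None:
            ge = np.asarray(gene_embeddings, dtype=np.float64)
            if ge.shape != (config.seq_len, d):
                raise ValueError(
                    f"gene embedding table shape {ge.shape} does not match "
                    f"(seq_len={config.seq_len}, d_model={d})"
                )
            gene_emb = ge.copy()
        else:
            gene_emb = rng.standard_normal((config.seq_len, d)) / np.sqrt(d)
        self.gene_emb = gene_emb
        self.bin_emb = rng.standard_normal((config.n_bins + 1, d)) / np.sqrt(d)
        self.posenc = sinusoidal_positions(config.seq_len, d)
        # canonical transformer scaling: learned embeddings are multiplied by
        # sqrt(d_model) before the positional term is added, so token content
        # is not drowned by the fixed sinusoids
        self.embed_scale = float(np.sqrt(d))
        self.final_ln = {"g": np.ones(d), "b": np.zeros(d)}
        self.blocks: list[tuple[AttentionSublayer, FeedForwardSublayer]] = []
        for layer in range(config.n_layers):
            F = AttentionSublayer(
                d, config.n_heads, attention=config.attention,
                n_buckets=config.n_buckets, n_hash_rounds=config.n_hash_rounds,
                exclude_self=config.exclude_self,
                hash_seed=config.hash_seed + 7919 * layer, rng=rng,
            )
            G = FeedForwardSublayer(d, config.d_ff, rng=rng)
            self.blocks.append((F, G))

    @property
    def mask_token(self) -> int:
        return self.config.n_bins

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {"gene_emb": self.gene_emb, "bin_emb": self.bin_emb}
        if self.blocks:
            out["final_ln/g"] = self.final_ln["g"]
            out["final_ln/b"] = self.final_ln["b"]
        for i, (F, G) in enumerate(self.blocks):
            for k, v in F.params.items():
                out[f"block{i}/attn/{k}"] = v
            for k, v in G.params.items():
                out[f"block{i}/ffn/{k}"] = v
        return out

    def check_finite(self) -> None:
        for k, v in self.params.items():
            if not np.all(np.isfinite(v)):
                raise FloatingPointError(f"non-finite parameter '{k}'")

    # -- forward / backward -------------------------------------------------

    def embed(self, tokens: np.ndarray) -> np.ndarray:
        tokens = np.atleast_2d(np.asarray(tokens, dtype=np.int64))
        if tokens.shape[1] != self.config.seq_len:
            raise ValueError(
                f"sequence length {tokens.shape[1]} != configured {self.config.seq_len}"
            )
        if tokens.min() < 0 or tokens.max() > self.mask_token:
            raise IndexError("bin id out of range")
        return (
            self.embed_scale * (self.gene_emb[None, :, :] + self.bin_emb[tokens])
            + self.posenc[None, :, :]
        )

    def forward(self, tokens: np.ndarray, store_caches: bool = True):
        """Run the stack; returns (features, state) for ``backward``.

        features = (y1 + y2) / 2 of the final half-states. With
        ``store_caches=False`` only the final half-states are kept and the
        backward pass recomputes activations via the reversible inverse.
        """
        tokens = np.atleast_2d(np.asarray(tokens, dtype=np.int64))
        x = self.embed(tokens)
        x1, x2 = x, x
        caches = []
        for F, G in self.blocks:
            x1, x2, cF, cG = block_forward(x1, x2, F, G)
            if store_caches:
                caches.append((cF, cG))
        out = 0.5 * (x1 + x2)
        ln_cache = None
        if self.blocks:  # final layer norm of the pre-norm stack
            out, ln_cache = layernorm_forward(out, self.final_ln["g"], self.final_ln["b"])
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite activations in encoder output")
        state = {"tokens": tokens, "y1": x1, "y2": x2,
                 "caches": caches if store_caches else None, "ln": ln_cache}
        return out, state

    def backward(self, dout: np.ndarray, state) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt all parameters given d(features)."""
        grads: dict[str, np.ndarray] = {}
        if state["ln"] is not None:
            dout, dg, db = layernorm_backward(dout, state["ln"])
            grads["final_ln/g"] = dg
            grads["final_ln/b"] = db
        dy1 = 0.5 * dout
        dy2 = 0.5 * dout
        caches = state["caches"]
        if caches is not None:
            for i in range(len(self.blocks) - 1, -1, -1):
                F, G = self.blocks[i]
                cF, cG = caches[i]
                dy1, dy2, f_g, g_g = block_backward_stored(dy1, dy2, F, G, cF, cG)
                self._collect(grads, i, f_g, g_g)
        else:
            y1, y2 = state["y1"], state["y2"]
            for i in range(len(self.blocks) - 1, -1, -1):
                F, G = self.blocks[i]
                y1, y2, dy1, dy2, f_g, g_g = block_backward_recompute(y1, y2, dy1, dy2, F, G)
                self._collect(grads, i, f_g, g_g)
        dx = (dy1 + dy2) * self.embed_scale
        tokens = state["tokens"]
        grads["gene_emb"] = dx.sum(axis=0)
        g_bin = np.zeros_like(self.bin_emb)
        np.add.at(g_bin, tokens.ravel(), dx.reshape(-1, dx.shape[-1]))
        grads["bin_emb"] = g_bin
        return grads

    @staticmethod
    def _collect(grads, i, f_g, g_g):
        for k, v in f_g.items():
            grads[f"block{i}/attn/{k}"] = v
        for k, v in g_g.items():
            grads[f"block{i}/ffn/{k}"] = v

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {k.replace("/", "__"): v for k, v in self.params.items()}
        np.savez(path, __config__=np.frombuffer(self.config.to_json().encode(), dtype=np.uint8),
                 **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "ReformerEncoder":
        with np.load(path) as archive:
            config = EncoderConfig.from_json(bytes(archive["__config__"]).decode())
            enc = cls(config, seed=seed)
            for k, v in enc.params.items():
                v[...] = archive[k.replace("/", "__")]
        return enc


def embed_tokens(cell, encoder: ReformerEncoder) -> np.ndarray:
    """Summed gene-identity + bin + positional embedding of one cell."""
    bin_ids = getattr(cell, "bin_ids", cell)
    return encoder.embed(np.asarray(bin_ids))[0]


def encode(cell, encoder: ReformerEncoder) -> np.ndarray:
    """(seq_len, d_model) per-gene features of one tokenized cell."""
    bin_ids = getattr(cell, "bin_ids", cell)
    out, _ = encoder.forward(np.asarray(bin_ids)[None, :], store_caches=False)
    return out[0]
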