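"""Masked-expression self-supervised pre-training.

Mirrors the BERT masked-language-model recipe on expression tokens: 15% of
a cell's *expressed* (nonzero-bin) genes are selected per pass; a selected
position is replaced by the reserved MASK token with probability 0.9 and
otherwise left unchanged (no random-token branch). The encoder plus a
linear reconstruction head predict the original expression bin at each
masked position, trained with a summed cross-entropy
L = -sum_i sum_j log p_{i,j}[y_{i,j}] over cells i and their masked genes
j. Training monitors a held-out slice of the pre-training cells and stops
once the monitored loss has not improved by at least ``min_delta`` for
``patience`` consecutive epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from ._nn.functional import softmax
from ._nn.layers import Dense
from ._nn.optim import AdamW, LinearWarmupSchedule
from .encoder import EncoderConfig, ReformerEncoder

__all__ = ["MaskedCell", "MaskedBatch", "mask_cell", "mask_batch", "mlm_loss",
           "MaskedExpressionPretrainer", "pretrain"]

_CLAMP = 1e-12


@dataclass
class MaskedCell:
    """One cell after masking: model inputs plus reconstruction targets."""

    input_bins: np.ndarray
    mask_positions: np.ndarray
    targets: np.ndarray


@dataclass
class MaskedBatch:
    """Stacked masked cells; ragged mask sets kept per cell."""

    inputs: np.ndarray  # (m, L) bin ids with MASK substitutions
    mask_positions: list[np.ndarray]
    targets: list[np.ndarray]

    @property
    def m(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_masked(self) -> int:
        return int(sum(len(t) for t in self.targets))


def mask_cell(
    bin_ids: np.ndarray,
    mask_prob: float = 0.15,
    replace_prob: float = 0.9,
    seed: int | np.random.Generator = 0,
    mask_token: int | None = None,
) -> MaskedCell:
    """Mask expressed genes of one tokenized cell.

    Each nonzero-bin position is selected independently with probability
    ``mask_prob``; zero-expression positions are never candidates. Selected
    positions carry the MASK token with probability ``replace_prob`` and
    keep their original bin otherwise (they are still reconstruction
    targets). Deterministic given a seed.
    """
    if not 0 <= mask_prob <= 1 or not 0 <= replace_prob <= 1:
        raise ValueError("mask_prob and replace_prob must lie in [0, 1]")
    bin_ids = np.asarray(bin_ids, dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask_token = int(bin_ids.max()) + 1 if mask_token is None else mask_token
    nonzero = np.flatnonzero(bin_ids > 0)
    if nonzero.size == 0:
        warnings.warn("cell has no expressed genes; empty mask set", stacklevel=2)
        return MaskedCell(bin_ids.copy(), np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    selected = nonzero[rng.random(nonzero.size) < mask_prob]
    out = bin_ids.copy()
    replace = rng.random(selected.size) < replace_prob
    out[selected[replace]] = mask_token
    return MaskedCell(out, selected, bin_ids[selected])


def mask_batch(tokens: np.ndarray, mask_prob: float, replace_prob: float,
               rng: np.random.Generator, mask_token: int) -> MaskedBatch:
    cells = [
        mask_cell(row, mask_prob, replace_prob, rng, mask_token) for row in np.atleast_2d(tokens)
    ]
    return MaskedBatch(
        np.stack([c.input_bins for c in cells]),
        [c.mask_positions for c in cells],
        [c.targets for c in cells],
    )


def mlm_loss(output, batch: MaskedBatch) -> float:
    """Summed reconstruction cross-entropy -sum_{i,j} log p_{i,j}[y_{i,j}].

    ``output`` is the predicted bin distribution per masked gene: a list of
    (n_i, B) arrays aligned with ``batch.targets``, or one packed
    (total_masked, B) array. Zero probabilities at a target are clamped at
    1e-12 with a warning.
    """
    targets = np.concatenate(batch.targets) if batch.targets else np.empty(0, dtype=int)
    if isinstance(output, (list, tuple)):
        probs = np.concatenate([np.atleast_2d(p) for p in output], axis=0)
    else:
        probs = np.atleast_2d(np.asarray(output, dtype=np.float64))
    if probs.shape[0] != targets.size:
        raise ValueError("output rows do not align with batch targets")
    at_target = probs[np.arange(targets.size), targets]
    if np.any(at_target <= 0):
        warnings.warn("zero predicted probability at a target; clamped", stacklevel=2)
        at_target = np.maximum(at_target, _CLAMP)
    return float(-np.log(at_target).sum())


class MaskedExpressionPretrainer(BaseEstimator):
    """Self-supervised masked-expression pre-training of a Reformer encoder.

    Architecture defaults are sized for atlas-scale corpora (d_model 200,
    6 layers, 10 heads, 64 LSH buckets, AdamW at 1e-4 with linear schedule
    and 10% warm-up); desk-scale runs override them. ``fit`` expects
    the (n_cells, seq_len) integer bin-id array from
    :class:`~screformer.preprocess.ExpressionTokenizer`.

    Fitted attributes: ``encoder_`` (trained encoder), ``head_`` (linear
    reconstruction head), ``history_`` (per-epoch mean train/held-out loss
    per masked gene), ``best_epoch_``.
    """

    def __init__(self, d_model=200, n_layers=6, n_heads=10, n_buckets=64,
                 n_hash_rounds=4, n_bins=7, attention="lsh", d_ff=None,
                 mask_prob=0.15, replace_prob=0.9, lr=1e-4, weight_decay=0.01,
                 batch_size=64, grad_acc=1, max_epochs=50, patience=5,
                 min_delta=1e-4, holdout_frac=0.1, warmup_frac=0.1,
                 gene_embeddings=None, seed=2022, verbose=0):
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.n_buckets = n_buckets
        self.n_hash_rounds = n_hash_rounds
        self.n_bins = n_bins
        self.attention = attention
        self.d_ff = d_ff
        self.mask_prob = mask_prob
        self.replace_prob = replace_prob
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.grad_acc = grad_acc
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.holdout_frac = holdout_frac
        self.warmup_frac = warmup_frac
        self.gene_embeddings = gene_embeddings
        self.seed = seed
        self.verbose = verbose

    # -- internals ----------------------------------------------------------

    def _loss_and_grads(self, tokens, rng, train: bool):
        """One masked forward/backward over a token batch."""
        enc = self.encoder_
        batch = mask_batch(tokens, self.mask_prob, self.replace_prob, rng, enc.mask_token)
        feats, state = enc.forward(batch.inputs, store_caches=train)
        rows = np.concatenate(
            [feats[i, pos] for i, pos in enumerate(batch.mask_positions)]
            or [np.empty((0, enc.config.d_model))]
        )
        targets = (
            np.concatenate(batch.targets) if batch.targets else np.empty(0, dtype=int)
        )
        logits, head_cache = self.head_.forward(rows)
        probs = softmax(logits, axis=-1)
        n_masked = targets.size
        loss = float(-np.log(np.maximum(probs[np.arange(n_masked), targets], _CLAMP)).sum())
        if not train:
            return loss, n_masked, None
        dlogits = probs.copy()
        dlogits[np.arange(n_masked), targets] -= 1.0
        drows, head_grads = self.head_.backward(dlogits, head_cache)
        dfeats = np.zeros_like(feats)
        offset = 0
        for i, pos in enumerate(batch.mask_positions):
            dfeats[i, pos] = drows[offset : offset + len(pos)]
            offset += len(pos)
        grads = enc.backward(dfeats, state)
        for k, v in head_grads.items():
            grads[f"head/{k}"] = v
        return loss, n_masked, grads

    def _eval_loss(self, tokens, eval_seed: int) -> float:
        """Mean held-out loss per masked gene under a fixed masking draw."""
        total, count = 0.0, 0
        rng = np.random.default_rng(eval_seed)
        for start in range(0, len(tokens), self.batch_size):
            loss, n, _ = self._loss_and_grads(tokens[start : start + self.batch_size], rng, False)
            total += loss
            count += n
        return total / max(count, 1)

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, y=None):
        tokens = np.asarray(X, dtype=np.int64)
        if tokens.ndim != 2 or tokens.shape[0] < 2:
            raise ValueError("need a (n_cells >= 2, seq_len) token array")
        root = np.random.SeedSequence(self.seed)
        s_init, s_split, s_train, s_eval = [
            int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
        ]
        config = EncoderConfig(
            seq_len=tokens.shape[1], d_model=self.d_model, n_layers=self.n_layers,
            n_heads=self.n_heads, n_buckets=self.n_buckets,
            n_hash_rounds=self.n_hash_rounds, n_bins=self.n_bins, d_ff=self.d_ff,
            attention=self.attention, hash_seed=s_init,
        )
        self.encoder_ = ReformerEncoder(config, seed=s_init,
                                        gene_embeddings=self.gene_embeddings)
        self.head_ = Dense(config.d_model, config.n_bins,
                           rng=np.random.default_rng(s_init + 1))
        # held-out slice for convergence monitoring
        perm = np.random.default_rng(s_split).permutation(len(tokens))
        n_hold = max(int(round(self.holdout_frac * len(tokens))), 1)
        hold, train = tokens[perm[:n_hold]], tokens[perm[n_hold:]]
        if len(train) == 0:
            train, hold = tokens[perm], tokens[perm[:n_hold]]

        steps_per_epoch = max(int(np.ceil(len(train) / self.batch_size / self.grad_acc)), 1)
        opt = AdamW(
            self._all_params(), lr=self.lr, weight_decay=self.weight_decay,
            schedule=LinearWarmupSchedule(self.lr, steps_per_epoch * self.max_epochs,
                                          self.warmup_frac),
        )
        rng = np.random.default_rng(s_train)
        history = []
        best = np.inf
        best_params = self._snapshot()
        self.best_epoch_ = 0
        stall = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(train))
            acc: dict[str, np.ndarray] | None = None
            n_acc = 0
            total, count = 0.0, 0
            diverged = False
            for start in range(0, len(train), self.batch_size):
                tb = train[order[start : start + self.batch_size]]
                loss, n, grads = self._loss_and_grads(tb, rng, True)
                if not np.isfinite(loss):
                    warnings.warn("non-finite loss; aborting at last finite checkpoint",
                                  stacklevel=2)
                    diverged = True
                    break
                total += loss
                count += n
                if acc is None:
                    acc = grads
                else:
                    for k in acc:
                        acc[k] += grads[k]
                n_acc += 1
                if n_acc == self.grad_acc:
                    opt.step(acc)
                    acc, n_acc = None, 0
            if diverged:
                break
            if acc is not None:
                opt.step(acc)
            hold_loss = self._eval_loss(hold, s_eval)
            history.append({"epoch": epoch, "train_loss": total / max(count, 1),
                            "holdout_loss": hold_loss})
            if self.verbose:
                print(f"[pretrain] epoch {epoch}: train {history[-1]['train_loss']:.4f} "
                      f"holdout {hold_loss:.4f}")
            if hold_loss < best - self.min_delta:
                best = hold_loss
                best_params = self._snapshot()
                self.best_epoch_ = epoch
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self._restore(best_params)
        self.history_ = pd.DataFrame(history)
        self.best_holdout_loss_ = best
        return self

    def _all_params(self) -> dict[str, np.ndarray]:
        out = dict(self.encoder_.params)
        for k, v in self.head_.params.items():
            out[f"head/{k}"] = v
        return out

    def _snapshot(self):
        return {k: v.copy() for k, v in self._all_params().items()}

    def _restore(self, snapshot):
        for k, v in self._all_params().items():
            v[...] = snapshot[k]

    def score(self, X, y=None) -> float:
        """Negative mean reconstruction loss (higher is better)."""
        check_is_fitted(self, "encoder_")
        return -self._eval_loss(np.asarray(X, dtype=np.int64), self.seed)


def pretrain(tokens, seed: int = 2022, **kwargs) -> MaskedExpressionPretrainer:
    """Functional wrapper: fit a :class:`MaskedExpressionPretrainer`."""
    return MaskedExpressionPretrainer(seed=seed, **kwargs).fit(tokens)
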