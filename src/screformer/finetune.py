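"""Supervised fine-tuning: per-gene convolutional head, classifier, k-fold CV.

The encoder's per-gene features feed a kernel-size-1 one-dimensional
convolution (a shared projection applied to every gene's feature vector),
pooling over genes (concatenated mean and max by default), and a
three-layer perceptron ending in C logits —
one per first-tier cell type. The whole network, embeddings through encoder
to head, is updated during fine-tuning; the loss is the summed
cross-entropy L = -sum_i log q_i[z_i]. Early stopping follows validation
accuracy with a configurable patience and always returns the best recorded
checkpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from ._nn.functional import softmax
from ._nn.layers import Dense
from ._nn.optim import AdamW, LinearWarmupSchedule
from .encoder import EncoderConfig, ReformerEncoder
from .metrics import MetricsReport, evaluate
from .pretrain import MaskedExpressionPretrainer

__all__ = ["ClassifierHead", "classify", "cls_loss", "ReformerCellClassifier",
           "finetune", "cross_validate", "CrossValidationResult"]

_CLAMP = 1e-12


class ClassifierHead:
    """Conv(k=1) per gene -> pooling over genes -> 3-layer MLP -> C logits.

    ``pooling`` is "meanmax" (concatenated mean and max over genes, the
    default — max pooling gives sharp credit assignment for "some marker
    gene responds" detectors while the mean keeps composition information),
    "mean", or "max".
    """

    def __init__(self, d_model: int, n_classes: int, d_conv: int = 128,
                 hidden: tuple[int, int] = (512, 512), dropout: float = 0.1,
                 pooling: str = "meanmax",
                 rng: np.random.Generator | None = None):
        if pooling not in ("mean", "max", "meanmax"):
            raise ValueError("pooling must be 'mean', 'max' or 'meanmax'")
        rng = rng or np.random.default_rng(0)
        self.dropout = dropout
        self.pooling = pooling
        d_pool = d_conv * (2 if pooling == "meanmax" else 1)
        self.conv = Dense(d_model, d_conv, rng=rng, relu=True)
        self.fc1 = Dense(d_pool, hidden[0], rng=rng, relu=True)
        self.fc2 = Dense(hidden[0], hidden[1], rng=rng, relu=True)
        self.out = Dense(hidden[1], n_classes, rng=rng, relu=False)
        self._layers = {"conv": self.conv, "fc1": self.fc1, "fc2": self.fc2, "out": self.out}

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {f"{name}/{k}": v for name, layer in self._layers.items()
                for k, v in layer.params.items()}

    def _pool(self, a: np.ndarray):
        argmax = None
        if self.pooling == "mean":
            pooled = a.mean(axis=1)
        elif self.pooling == "max":
            argmax = a.argmax(axis=1)
            pooled = a.max(axis=1)
        else:
            argmax = a.argmax(axis=1)
            pooled = np.concatenate([a.mean(axis=1), a.max(axis=1)], axis=-1)
        return pooled, argmax

    def _unpool(self, dpooled: np.ndarray, a_shape, argmax):
        B, L, dc = a_shape
        da = np.zeros(a_shape)
        if self.pooling in ("mean", "meanmax"):
            d_mean = dpooled[:, :dc] if self.pooling == "meanmax" else dpooled
            da += d_mean[:, None, :] / L
        if self.pooling in ("max", "meanmax"):
            d_max = dpooled[:, dc:] if self.pooling == "meanmax" else dpooled
            rows = np.arange(B)[:, None]
            cols = np.arange(dc)[None, :]
            np.add.at(da, (rows, argmax, cols), d_max)
        return da

    def forward(self, feats: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """feats (B, L, d_model) -> logits (B, C)."""
        a, c_conv = self.conv.forward(feats)
        masks = {}
        if train and self.dropout > 0:
            masks["conv"] = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
            a = a * masks["conv"]
        pooled, argmax = self._pool(a)
        h1, c1 = self.fc1.forward(pooled)
        if train and self.dropout > 0:
            masks["fc1"] = (rng.random(h1.shape) >= self.dropout) / (1 - self.dropout)
            h1 = h1 * masks["fc1"]
        h2, c2 = self.fc2.forward(h1)
        if train and self.dropout > 0:
            masks["fc2"] = (rng.random(h2.shape) >= self.dropout) / (1 - self.dropout)
            h2 = h2 * masks["fc2"]
        logits, c3 = self.out.forward(h2)
        return logits, (a.shape, argmax, c_conv, c1, c2, c3, masks)

    def backward(self, dlogits: np.ndarray, cache):
        a_shape, argmax, c_conv, c1, c2, c3, masks = cache
        grads = {}
        dh2, g = self.out.backward(dlogits, c3)
        grads.update({f"out/{k}": v for k, v in g.items()})
        if "fc2" in masks:
            dh2 = dh2 * masks["fc2"]
        dh1, g = self.fc2.backward(dh2, c2)
        grads.update({f"fc2/{k}": v for k, v in g.items()})
        if "fc1" in masks:
            dh1 = dh1 * masks["fc1"]
        dpooled, g = self.fc1.backward(dh1, c1)
        grads.update({f"fc1/{k}": v for k, v in g.items()})
        da = self._unpool(dpooled, a_shape, argmax)
        if "conv" in masks:
            da = da * masks["conv"]
        dfeats, g = self.conv.backward(da, c_conv)
        grads.update({f"conv/{k}": v for k, v in g.items()})
        return dfeats, grads


def classify(features: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Class probabilities for per-gene features (L, d) or a batch (B, L, d)."""
    feats = np.asarray(features, dtype=np.float64)
    single = feats.ndim == 2
    if single:
        feats = feats[None]
    logits, _ = head.forward(feats, train=False)
    probs = softmax(logits, axis=-1)
    return probs[0] if single else probs


def cls_loss(probs: np.ndarray, z: np.ndarray) -> float:
    """Summed classification cross-entropy -sum_i log q_i[z_i]."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    z = np.atleast_1d(np.asarray(z, dtype=np.int64))
    if probs.shape[0] != z.size:
        raise ValueError("probabilities and labels do not align")
    at_true = probs[np.arange(z.size), z]
    if np.any(at_true <= 0):
        warnings.warn("zero predicted probability at the true class; clamped", stacklevel=2)
        at_true = np.maximum(at_true, _CLAMP)
    return float(-np.log(at_true).sum())


class ReformerCellClassifier(ClassifierMixin, BaseEstimator):
    """Reformer encoder + convolutional classification head, sklearn-style.

    ``fit`` takes the (n_cells, seq_len) bin-id array and string or integer
    first-tier labels. Pass a fitted :class:`MaskedExpressionPretrainer`
    (or a ReformerEncoder) as ``pretrained`` to start from pre-trained
    weights; otherwise the encoder is randomly initialized, optionally
    seeding gene-identity embeddings from ``gene_embeddings``
    (seq_len x d_model, rows in token order).

    Training defaults assume a large labeled dataset (batch 6,
    lr 1e-4, 60-step gradient accumulation, at most 3 epochs, patience-1
    early stopping on validation accuracy, AdamW with linear schedule and
    10% warm-up, seed 2022); small fixtures typically raise ``max_epochs``
    and drop ``grad_acc``.
    """

    def __init__(self, d_model=200, n_layers=6, n_heads=10, n_buckets=64,
                 n_hash_rounds=4, n_bins=7, attention="lsh", d_ff=None,
                 d_conv=128, hidden=(512, 512), dropout=0.1, pooling="meanmax",
                 lr=1e-4, weight_decay=0.01, batch_size=6, grad_acc=60,
                 max_epochs=3, patience=1, warmup_frac=0.1, val_frac=0.125,
                 pretrained=None, gene_embeddings=None, seed=2022, verbose=0):
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.n_buckets = n_buckets
        self.n_hash_rounds = n_hash_rounds
        self.n_bins = n_bins
        self.attention = attention
        self.d_ff = d_ff
        self.d_conv = d_conv
        self.hidden = hidden
        self.dropout = dropout
        self.pooling = pooling
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.grad_acc = grad_acc
        self.max_epochs = max_epochs
        self.patience = patience
        self.warmup_frac = warmup_frac
        self.val_frac = val_frac
        self.pretrained = pretrained
        self.gene_embeddings = gene_embeddings
        self.seed = seed
        self.verbose = verbose

    # -- construction -------------------------------------------------------

    def _build_encoder(self, seq_len: int, init_seed: int) -> ReformerEncoder:
        src = self.pretrained
        if isinstance(src, MaskedExpressionPretrainer):
            check_is_fitted(src, "encoder_")
            src = src.encoder_
        if isinstance(src, ReformerEncoder):
            if src.config.seq_len != seq_len:
                raise ValueError(
                    f"pre-trained encoder expects seq_len {src.config.seq_len}, data has {seq_len}"
                )
            enc = ReformerEncoder(src.config, seed=init_seed)
            for k, v in enc.params.items():
                v[...] = src.params[k]
            return enc
        if src is not None:
            raise TypeError("pretrained must be a MaskedExpressionPretrainer or ReformerEncoder")
        config = EncoderConfig(
            seq_len=seq_len, d_model=self.d_model, n_layers=self.n_layers,
            n_heads=self.n_heads, n_buckets=self.n_buckets,
            n_hash_rounds=self.n_hash_rounds, n_bins=self.n_bins, d_ff=self.d_ff,
            attention=self.attention, dropout=self.dropout, hash_seed=init_seed,
        )
        return ReformerEncoder(config, seed=init_seed, gene_embeddings=self.gene_embeddings)

    def _all_params(self) -> dict[str, np.ndarray]:
        out = dict(self.encoder_.params)
        for k, v in self.head_.params.items():
            out[f"head/{k}"] = v
        return out

    # -- training -----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        tokens = np.asarray(X, dtype=np.int64)
        y = np.asarray(y)
        if tokens.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        self.classes_, z = np.unique(y, return_inverse=True)
        if X_val is not None:
            val_classes = set(np.unique(y_val).tolist())
            unknown = val_classes - set(self.classes_.tolist())
            if unknown:
                raise ValueError(f"validation classes absent from training set: {sorted(unknown)}")
            z_val = np.searchsorted(self.classes_, np.asarray(y_val))
            tokens_val = np.asarray(X_val, dtype=np.int64)
        elif self.val_frac and len(tokens) >= 10 and np.min(np.bincount(z)) >= 2:
            tokens, tokens_val, z, z_val = train_test_split(
                tokens, z, test_size=self.val_frac, stratify=z, random_state=self.seed % (2**32)
            )
        else:
            tokens_val, z_val = tokens, z

        root = np.random.SeedSequence(self.seed)
        s_init, s_train = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2)]
        self.encoder_ = self._build_encoder(tokens.shape[1], s_init)
        self.head_ = ClassifierHead(
            self.encoder_.config.d_model, len(self.classes_), d_conv=self.d_conv,
            hidden=tuple(self.hidden), dropout=self.dropout, pooling=self.pooling,
            rng=np.random.default_rng(s_init + 1),
        )
        steps = max(int(np.ceil(len(tokens) / self.batch_size / self.grad_acc)), 1)
        opt = AdamW(self._all_params(), lr=self.lr, weight_decay=self.weight_decay,
                    schedule=LinearWarmupSchedule(self.lr, steps * self.max_epochs,
                                                  self.warmup_frac))
        rng = np.random.default_rng(s_train)
        history = []
        best_acc = -np.inf
        best_params = {k: v.copy() for k, v in self._all_params().items()}
        self.best_epoch_ = 0
        stall = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(tokens))
            acc_grads = None
            n_acc = 0
            total = 0.0
            for start in range(0, len(tokens), self.batch_size):
                idx = order[start : start + self.batch_size]
                feats, state = self.encoder_.forward(tokens[idx], store_caches=True)
                logits, cache = self.head_.forward(feats, train=True, rng=rng)
                probs = softmax(logits, axis=-1)
                total += float(
                    -np.log(np.maximum(probs[np.arange(len(idx)), z[idx]], _CLAMP)).sum()
                )
                dlogits = probs
                dlogits[np.arange(len(idx)), z[idx]] -= 1.0
                dfeats, head_grads = self.head_.backward(dlogits, cache)
                grads = self.encoder_.backward(dfeats, state)
                grads.update({f"head/{k}": v for k, v in head_grads.items()})
                if acc_grads is None:
                    acc_grads = grads
                else:
                    for k in acc_grads:
                        acc_grads[k] += grads[k]
                n_acc += 1
                if n_acc == self.grad_acc:
                    opt.step(acc_grads)
                    acc_grads, n_acc = None, 0
            if acc_grads is not None:
                opt.step(acc_grads)
            val_acc = float(np.mean(self._predict_indices(tokens_val) == z_val))
            history.append({"epoch": epoch, "train_loss": total / max(len(tokens), 1),
                            "val_accuracy": val_acc})
            if self.verbose:
                print(f"[finetune] epoch {epoch}: loss {history[-1]['train_loss']:.4f} "
                      f"val_acc {val_acc:.4f}")
            if val_acc > best_acc:
                best_acc = val_acc
                best_params = {k: v.copy() for k, v in self._all_params().items()}
                self.best_epoch_ = epoch
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        for k, v in self._all_params().items():
            v[...] = best_params[k]
        self.history_ = pd.DataFrame(history)
        self.best_val_accuracy_ = best_acc
        return self

    # -- inference ----------------------------------------------------------

    def _forward_logits(self, tokens: np.ndarray) -> np.ndarray:
        out = []
        bs = max(self.batch_size, 32)
        for start in range(0, len(tokens), bs):
            feats, _ = self.encoder_.forward(tokens[start : start + bs], store_caches=False)
            logits, _ = self.head_.forward(feats, train=False)
            out.append(logits)
        return np.concatenate(out, axis=0)

    def decision_function(self, X) -> np.ndarray:
        """Pre-softmax class logits (the attribution target)."""
        check_is_fitted(self, "encoder_")
        tokens = np.asarray(X, dtype=np.int64)
        if tokens.ndim != 2 or tokens.shape[1] != self.encoder_.config.seq_len:
            raise ValueError(
                f"expected (n, {self.encoder_.config.seq_len}) tokens, got {tokens.shape}"
            )
        return self._forward_logits(tokens)

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X), axis=-1)

    def _predict_indices(self, tokens: np.ndarray) -> np.ndarray:
        # np.argmax takes the lowest index on ties, the documented rule
        return np.argmax(self._forward_logits(tokens), axis=1)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "encoder_")
        tokens = np.asarray(X, dtype=np.int64)
        if tokens.shape[1] != self.encoder_.config.seq_len:
            raise ValueError("sequence length mismatch with trained vocabulary")
        return self.classes_[self._predict_indices(tokens)]


def finetune(pretrained, X, y, X_val=None, y_val=None, seed: int = 2022,
             **kwargs) -> ReformerCellClassifier:
    """Functional wrapper: fine-tune from a pre-trained encoder."""
    clf = ReformerCellClassifier(pretrained=pretrained, seed=seed, **kwargs)
    return clf.fit(X, y, X_val=X_val, y_val=y_val)


@dataclass
class CrossValidationResult:
    """Per-fold metric reports plus the mean +/- sample-SD summary."""

    reports: list[MetricsReport]
    fold_test_indices: list[np.ndarray] = field(default_factory=list)

    @property
    def accuracy(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.reports])

    @property
    def macro_f1(self) -> np.ndarray:
        return np.array([r.macro_f1 for r in self.reports])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metric": ["accuracy", "macro_f1"],
            "mean": [self.accuracy.mean(), self.macro_f1.mean()],
            "sd": [self.accuracy.std(ddof=1), self.macro_f1.std(ddof=1)],
        })


def cross_validate(estimator, X, y, k: int = 5, seed: int = 2022,
                   **fit_kwargs) -> CrossValidationResult:
    """Stratified k-fold cross-validation with mean +/- SD summary.

    Folds are disjoint and exhaustive; every fold serves as the test fold
    exactly once; the estimator is cloned per fold so folds are
    independent. Requires every class to have at least k members.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds the number of cells ({len(y)})")
    classes, z = np.unique(y, return_inverse=True)
    if np.min(np.bincount(z)) < k:
        raise ValueError("every class needs at least k members for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    reports, test_folds = [], []
    for train_idx, test_idx in skf.split(X, y):
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx], **fit_kwargs)
        proba = model.predict_proba(X[test_idx])
        order = np.searchsorted(classes, model.classes_)
        full = np.zeros((len(test_idx), len(classes)))
        full[:, order] = proba
        pred = np.argmax(full, axis=1)
        reports.append(evaluate(z[test_idx], pred, full, C=len(classes)))
        test_folds.append(test_idx)
    return CrossValidationResult(reports, test_folds)
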