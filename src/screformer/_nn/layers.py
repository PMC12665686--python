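"""Trainable layers with explicit forward/backward passes.

All arrays are float64; inputs to sublayers are (batch, seq, d_model). Each
sublayer owns a ``params`` dict and returns a gradient dict with the same
keys from ``backward``. This hand-rolled reverse mode keeps the reversible
residual stack transparent: the same sublayer code runs under both the
stored-activation and the recompute-on-backward training paths.
"""

from __future__ import annotations

import numpy as np

from .functional import assign_buckets, hash_rotations, softmax

_EPS = 1e-12


# ---------------------------------------------------------------------------
# layer norm
# ---------------------------------------------------------------------------


def layernorm_forward(x, g, b, eps: float = 1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def layernorm_backward(dy, cache):
    xhat, inv, g = cache
    axes = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=axes)
    db = dy.sum(axis=axes)
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


# ---------------------------------------------------------------------------
# sublayers
# ---------------------------------------------------------------------------


class AttentionSublayer:
    """Pre-norm multi-head shared-QK attention, optionally LSH-restricted.

    Keys are the row-normalized queries (the Reformer shared-QK regime), so
    bucket membership computed from the queries is consistent for keys. Hash
    rotations are drawn once at construction from ``hash_seed`` and kept
    fixed, making evaluation deterministic.
    """

    def __init__(self, d_model, n_heads, *, attention="lsh", n_buckets=64,
                 n_hash_rounds=4, exclude_self=False, hash_seed=0, rng=None):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.attention = attention
        self.n_buckets = n_buckets
        self.exclude_self = exclude_self
        rng = rng or np.random.default_rng(0)
        s = 1.0 / np.sqrt(d_model)
        self.params = {
            "ln_g": np.ones(d_model),
            "ln_b": np.zeros(d_model),
            "Wq": rng.standard_normal((n_heads, d_model, self.d_k)) * s,
            "Wv": rng.standard_normal((n_heads, d_model, self.d_k)) * s,
            "Wo": rng.standard_normal((n_heads, self.d_k, d_model))
            * (1.0 / np.sqrt(n_heads * self.d_k)),
            "bo": np.zeros(d_model),
        }
        self.rotations = (
            hash_rotations(self.d_k, n_buckets, n_hash_rounds, hash_seed)
            if attention == "lsh" and n_buckets > 1
            else None
        )

    def _mask(self, q):
        if self.rotations is None:
            return None
        buckets = assign_buckets(q, self.rotations)  # (rounds, B, H, L)
        mask = np.any(buckets[..., :, None] == buckets[..., None, :], axis=0)
        if self.exclude_self:
            n = mask.shape[-1]
            lone = mask.sum(axis=-1) == 1
            idx = np.arange(n)
            mask[..., idx, idx] = lone
        return mask

    def forward(self, x):
        p = self.params
        h, ln_cache = layernorm_forward(x, p["ln_g"], p["ln_b"])
        q = np.einsum("bld,hde->bhle", h, p["Wq"])
        norm = np.maximum(np.linalg.norm(q, axis=-1, keepdims=True), _EPS)
        kn = q / norm
        v = np.einsum("bld,hde->bhle", h, p["Wv"])
        scores = np.einsum("bhle,bhme->bhlm", q, kn) / np.sqrt(self.d_k)
        mask = self._mask(q)
        if mask is not None:
            scores = np.where(mask, scores, -1e30)
        att = softmax(scores, axis=-1)
        o = np.einsum("bhlm,bhme->bhle", att, v)
        out = np.einsum("bhle,hed->bld", o, p["Wo"]) + p["bo"]
        return out, (ln_cache, h, q, kn, norm, v, att, o)

    def backward(self, dout, cache):
        p = self.params
        ln_cache, h, q, kn, norm, v, att, o = cache
        grads = {
            "Wo": np.einsum("bhle,bld->hed", o, dout),
            "bo": dout.sum(axis=(0, 1)),
        }
        do = np.einsum("bld,hed->bhle", dout, p["Wo"])
        datt = np.einsum("bhle,bhme->bhlm", do, v)
        dv = np.einsum("bhlm,bhle->bhme", att, do)
        ds = att * (datt - np.sum(datt * att, axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(self.d_k)
        dq = np.einsum("bhlm,bhme->bhle", ds, kn) * scale
        dkn = np.einsum("bhlm,bhle->bhme", ds, q) * scale
        dq += (dkn - kn * np.sum(dkn * kn, axis=-1, keepdims=True)) / norm
        dh = np.einsum("bhle,hde->bld", dq, p["Wq"])
        dh += np.einsum("bhle,hde->bld", dv, p["Wv"])
        grads["Wq"] = np.einsum("bld,bhle->hde", h, dq)
        grads["Wv"] = np.einsum("bld,bhle->hde", h, dv)
        dx, grads["ln_g"], grads["ln_b"] = layernorm_backward(dh, ln_cache)
        return dx, grads


class FeedForwardSublayer:
    """Pre-norm position-wise feed-forward: LN -> dense -> ReLU -> dense."""

    def __init__(self, d_model, d_ff, rng=None):
        rng = rng or np.random.default_rng(0)
        self.params = {
            "ln_g": np.ones(d_model),
            "ln_b": np.zeros(d_model),
            "W1": rng.standard_normal((d_model, d_ff)) * np.sqrt(2.0 / d_model),
            "b1": np.zeros(d_ff),
            "W2": rng.standard_normal((d_ff, d_model)) * np.sqrt(1.0 / d_ff),
            "b2": np.zeros(d_model),
        }

    def forward(self, x):
        p = self.params
        h, ln_cache = layernorm_forward(x, p["ln_g"], p["ln_b"])
        a = h @ p["W1"] + p["b1"]
        r = np.maximum(a, 0.0)
        out = r @ p["W2"] + p["b2"]
        return out, (ln_cache, h, a, r)

    def backward(self, dout, cache):
        p = self.params
        ln_cache, h, a, r = cache
        grads = {
            "W2": np.einsum("blf,bld->fd", r, dout),
            "b2": dout.sum(axis=(0, 1)),
        }
        dr = dout @ p["W2"].T
        da = dr * (a > 0)
        grads["W1"] = np.einsum("bld,blf->df", h, da)
        grads["b1"] = da.sum(axis=(0, 1))
        dh = da @ p["W1"].T
        dx, grads["ln_g"], grads["ln_b"] = layernorm_backward(dh, ln_cache)
        return dx, grads


class Dense:
    """Affine map on the last axis, with optional ReLU."""

    def __init__(self, d_in, d_out, rng=None, relu=False):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt((2.0 if relu else 1.0) / d_in)
        self.relu = relu
        self.params = {
            "W": rng.standard_normal((d_in, d_out)) * scale,
            "b": np.zeros(d_out),
        }

    def forward(self, x):
        a = x @ self.params["W"] + self.params["b"]
        out = np.maximum(a, 0.0) if self.relu else a
        return out, (x, a)

    def backward(self, dout, cache):
        x, a = cache
        if self.relu:
            dout = dout * (a > 0)
        axes = tuple(range(x.ndim - 1))
        grads = {
            "W": np.tensordot(x, dout, axes=(axes, axes)),
            "b": dout.sum(axis=axes),
        }
        return dout @ self.params["W"].T, grads
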