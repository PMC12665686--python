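"""Attention primitives: scaled dot-product, angular LSH hashing, bucketed attention.

These are the numerical building blocks of the encoder. LSH attention here
keeps the exact restricted-softmax semantics — query *i* attends to
P_i = {j : some hash round puts q_i and k_j in the same bucket} — realised
as a dense boolean mask over the score matrix. At the sequence lengths this
package targets (a few thousand genes at most) the dense mask is exact and
cheap; the sorted-chunk kernel used to reach O(N log N) on very long
sequences is intentionally not replicated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "softmax",
    "full_attention",
    "lsh_hash",
    "BucketAssignment",
    "bucket_mask",
    "lsh_attention",
]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(x)
    return e / np.sum(e, axis=axis, keepdims=True)


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite attention inputs")


def full_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention softmax(q k^T / sqrt(d_k)) v.

    Accepts leading batch dimensions; the last two axes are (positions, d_k).
    """
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    _check_finite(q, k, v)
    d_k = q.shape[-1]
    scores = np.einsum("...id,...jd->...ij", q, k) / np.sqrt(d_k)
    return np.einsum("...ij,...jd->...id", softmax(scores, axis=-1), v)


@dataclass
class BucketAssignment:
    """Per-round bucket ids for each position.

    ``buckets`` has shape (n_rounds, n). Position *j* belongs to the
    attention set P_i of position *i* iff they share a bucket in at least
    one round. Construct directly for externally fixed assignments, or via
    :func:`lsh_hash`.
    """

    buckets: np.ndarray
    n_buckets: int

    def __post_init__(self) -> None:
        self.buckets = np.atleast_2d(np.asarray(self.buckets, dtype=np.int64))
        if np.any(self.buckets < 0) or np.any(self.buckets >= self.n_buckets):
            raise ValueError("bucket ids out of range")

    @property
    def n(self) -> int:
        return self.buckets.shape[1]

    def mask(self) -> np.ndarray:
        return bucket_mask(self.buckets)

    def attention_sets(self) -> list[np.ndarray]:
        """P_i for every position i (union over rounds)."""
        m = self.mask()
        return [np.flatnonzero(m[i]) for i in range(self.n)]


def bucket_mask(buckets: np.ndarray) -> np.ndarray:
    """(n, n) boolean union-over-rounds same-bucket mask."""
    b = np.atleast_2d(buckets)
    return np.any(b[:, :, None] == b[:, None, :], axis=0)


def lsh_hash(
    vectors: np.ndarray, n_buckets: int, n_rounds: int = 4, seed: int = 0
) -> BucketAssignment:
    """Angular LSH via random rotations.

    Each round projects onto a seeded Gaussian matrix R of shape
    (d_k, n_buckets/2) and assigns bucket = argmax over the concatenation
    [xR, -xR]; vectors pointing the same way always share a bucket (the
    hash is scale-invariant), antipodal vectors never do with n_buckets=2.
    An all-zero vector scores 0 everywhere and lands in bucket 0 by the
    argmax convention.
    """
    if n_buckets % 2 != 0:
        raise ValueError("n_buckets must be even")
    x = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    rotations = hash_rotations(x.shape[-1], n_buckets, n_rounds, seed)
    return BucketAssignment(assign_buckets(x, rotations), n_buckets)


def hash_rotations(d_k: int, n_buckets: int, n_rounds: int, seed: int) -> np.ndarray:
    """Seeded (n_rounds, d_k, n_buckets/2) rotation stack.

    Columns are drawn as stacked orthonormal blocks (QR of Gaussian
    matrices) rather than raw Gaussians: equal-norm, well-spread directions
    keep bucket occupancy near uniform for isotropic inputs.
    """
    rng = np.random.default_rng(seed)
    half = n_buckets // 2
    rounds = []
    for _ in range(n_rounds):
        cols = []
        n_have = 0
        while n_have < half:
            q, _ = np.linalg.qr(rng.standard_normal((d_k, d_k)))
            cols.append(q)
            n_have += d_k
        rounds.append(np.concatenate(cols, axis=1)[:, :half])
    return np.stack(rounds)


def assign_buckets(x: np.ndarray, rotations: np.ndarray) -> np.ndarray:
    """Bucket ids for x (..., n, d_k) under a rotation stack; (rounds, ..., n)."""
    proj = np.einsum("...nd,rdb->r...nb", x, rotations)
    both = np.concatenate([proj, -proj], axis=-1)
    return np.argmax(both, axis=-1)


def lsh_attention(
    q: np.ndarray,
    k: np.ndarray,
    v: np.ndarray,
    assignment: BucketAssignment | np.ndarray,
    exclude_self: bool = False,
) -> np.ndarray:
    """Bucket-restricted attention: row i softmaxes q_i·k_j/sqrt(d_k) over j in P_i.

    ``assignment`` is a :class:`BucketAssignment`, a raw (rounds, n) bucket
    array, or a precomputed (n, n) boolean mask. With a single bucket this
    reduces exactly to :func:`full_attention`. ``exclude_self`` removes the
    diagonal except where i is the only member of its set (the shared-QK
    convention); the output stays a convex combination of rows of v.
    """
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    _check_finite(q, k, v)
    n, d_k = q.shape[-2], q.shape[-1]
    if isinstance(assignment, BucketAssignment):
        mask = assignment.mask()
    else:
        arr = np.asarray(assignment)
        mask = arr if arr.dtype == bool else bucket_mask(arr)
    if mask.shape[-2:] != (n, n):
        raise ValueError(f"assignment covers {mask.shape[-1]} positions, inputs have {n}")
    mask = mask.copy()
    if exclude_self:
        lone = mask.sum(axis=-1) == 1  # i stays in P_i when it is the sole member
        idx = np.arange(n)
        mask[..., idx, idx] = lone
    scores = np.einsum("...id,...jd->...ij", q, k) / np.sqrt(d_k)
    scores = np.where(mask, scores, -np.inf)
    # every row has at least one admissible key (i itself), so softmax is finite
    p = softmax(scores, axis=-1)
    return np.einsum("...ij,...jd->...id", p, v)
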