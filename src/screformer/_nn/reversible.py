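"""Reversible residual coupling: y1 = x1 + F(x2), y2 = x2 + G(y1).

The inverse reads the coupling backwards, so a stack of such blocks can be
back-propagated by recomputing activations from the outputs instead of
storing them — activation memory stays constant in the number of layers.
Both backward routes (stored caches and recompute-from-outputs) are
implemented; they are algebraically identical and agree to float tolerance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "reversible_forward",
    "reversible_inverse",
    "block_forward",
    "block_backward_stored",
    "block_backward_recompute",
]


def reversible_forward(x1, x2, f, g):
    """Apply the coupling with plain callables F, G."""
    x1, x2 = np.asarray(x1, dtype=np.float64), np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError(f"half-state shapes differ: {x1.shape} vs {x2.shape}")
    y1 = x1 + f(x2)
    y2 = x2 + g(y1)
    return y1, y2


def reversible_inverse(y1, y2, f, g):
    """Recover (x1, x2) from (y1, y2) without stored activations."""
    y1, y2 = np.asarray(y1, dtype=np.float64), np.asarray(y2, dtype=np.float64)
    if y1.shape != y2.shape:
        raise ValueError(f"half-state shapes differ: {y1.shape} vs {y2.shape}")
    x2 = y2 - g(y1)
    x1 = y1 - f(x2)
    return x1, x2


# -- trainable-block variants (sublayers expose .forward/.backward) ----------


def block_forward(x1, x2, F, G):
    f_out, cF = F.forward(x2)
    y1 = x1 + f_out
    g_out, cG = G.forward(y1)
    y2 = x2 + g_out
    return y1, y2, cF, cG


def block_backward_stored(dy1, dy2, F, G, cF, cG):
    """Gradients using caches kept from the forward pass."""
    dg_in, g_grads = G.backward(dy2, cG)
    dy1_total = dy1 + dg_in
    df_in, f_grads = F.backward(dy1_total, cF)
    dx1 = dy1_total
    dx2 = dy2 + df_in
    return dx1, dx2, f_grads, g_grads


def block_backward_recompute(y1, y2, dy1, dy2, F, G):
    """Gradients recomputing activations from the block outputs.

    Returns the reconstructed inputs as well, so a stack can walk backwards
    layer by layer carrying only one pair of half-states.
    """
    g_out, cG = G.forward(y1)
    x2 = y2 - g_out
    f_out, cF = F.forward(x2)
    x1 = y1 - f_out
    dx1, dx2, f_grads, g_grads = block_backward_stored(dy1, dy2, F, G, cF, cG)
    return x1, x2, dx1, dx2, f_grads, g_grads
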