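"""Gated fusion of the structural embedding view and the raw-feature view.

Given a structural embedding ``z`` and raw features ``x``, the raw
features are projected into the same latent space, ``h = relu(W_x x +
b_x)``; a learned sigmoid gate ``g = sigmoid(W_g [z || h] + b_g)`` then
interpolates elementwise, ``f = g * z + (1 - g) * h``.  The fused vector
is a convex combination of the two views, so each coordinate of ``f``
lies between the corresponding coordinates of ``z`` and ``h``.

Two APIs: plain-numpy functions (``project_features`` / ``compute_gate``
/ ``fuse``) for inspection and testing, and the ``GatedFusion`` autodiff
module trained jointly with the GNN.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .nn import Tensor


class DimensionError(ValueError):
    pass


def project_features(x: np.ndarray, w_x: np.ndarray, b_x: np.ndarray) -> np.ndarray:
    """``relu(W_x x + b_x)`` with ``w_x`` of shape (d, p)."""
    x = np.asarray(x, dtype=float)
    w_x = np.asarray(w_x, dtype=float)
    b_x = np.asarray(b_x, dtype=float)
    if x.shape[-1] != w_x.shape[1] or w_x.shape[0] != b_x.shape[0]:
        raise DimensionError(
            f"shape mismatch: x{x.shape} w_x{w_x.shape} b_x{b_x.shape}")
    return np.maximum(x @ w_x.T + b_x, 0.0)


def compute_gate(z: np.ndarray, h: np.ndarray,
                 w_g: np.ndarray, b_g: np.ndarray) -> np.ndarray:
    """``sigmoid(W_g [z || h] + b_g)``; entries strictly in (0, 1)."""
    z = np.asarray(z, dtype=float)
    h = np.asarray(h, dtype=float)
    if z.shape != h.shape:
        raise DimensionError(f"z{z.shape} and h{h.shape} differ")
    w_g = np.asarray(w_g, dtype=float)
    if w_g.shape[1] != 2 * z.shape[-1]:
        raise DimensionError(f"w_g{w_g.shape} incompatible with d={z.shape[-1]}")
    return expit(np.concatenate([z, h], axis=-1) @ w_g.T + np.asarray(b_g, dtype=float))


def fuse(z: np.ndarray, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Elementwise interpolation ``g * z + (1 - g) * h``."""
    z, h, g = (np.asarray(a, dtype=float) for a in (z, h, g))
    if not (z.shape == h.shape == g.shape):
        raise DimensionError(f"shapes differ: z{z.shape} h{h.shape} g{g.shape}")
    return g * z + (1.0 - g) * h


class GatedFusion:
    """Learnable gated fusion module (weights stored transposed, (p, d))."""

    def __init__(self, n_features: int, dim: int, rng: np.random.Generator):
        def glorot(shape):
            lim = np.sqrt(6.0 / sum(shape))
            return rng.uniform(-lim, lim, shape)

        self.W_x = Tensor(glorot((n_features, dim)), requires_grad=True)
        self.b_x = Tensor(np.zeros(dim), requires_grad=True)
        self.W_g = Tensor(glorot((2 * dim, dim)), requires_grad=True)
        self.b_g = Tensor(np.zeros(dim), requires_grad=True)
        self.dim = dim

    def __call__(self, x: Tensor, z: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Return (fused f, gate g, projected h)."""
        if x.shape[-1] != self.W_x.shape[0]:
            raise DimensionError(
                f"x has {x.shape[-1]} features, expected {self.W_x.shape[0]}")
        h = (x @ self.W_x + self.b_x).relu()
        g = (Tensor.cat([z, h], axis=1) @ self.W_g + self.b_g).sigmoid()
        f = g * z + (1.0 - g) * h
        return f, g, h

    def parameters(self):
        return [self.W_x, self.b_x, self.W_g, self.b_g]

    def named_parameters(self):
        return [("fusion.W_x", self.W_x), ("fusion.b_x", self.b_x),
                ("fusion.W_g", self.W_g), ("fusion.b_g", self.b_g)]
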