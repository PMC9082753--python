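"""Stacked dense co-attention (DCA) fusion of sEMG and EEG features.

One DCA layer takes the sEMG-side features M (d x n_m) and the EEG-side
features E (d x n_e) and computes

    A   = E^T W M                    bilinear affinity, (n_e x n_m)
    A_M = rowsoftmax(A)              attention on sEMG positions per EEG position
    A_E = rowsoftmax(A^T)            attention on EEG positions per sEMG position
    P_M = M A_M^T                    sEMG features attended to EEG positions, (d x n_e)
    P_E = E A_E^T                    EEG features attended to sEMG positions, (d x n_m)
    M'  = ReLU(W_M [M; P_E] + b_M) + M
    E'  = ReLU(W_E [E; P_M] + b_E) + E

where [X; Y] stacks vertically to 2d rows, W is (d x d), W_M and W_E are
(d x 2d), and b_M, b_E are (d x 1).  The layer preserves both shapes, so any
number N of layers can be stacked; N = 0 is the identity.

This module provides the operation both as plain-NumPy functions (the
reference used by the tests' scalar-loop oracle) and as an autograd
``DCAStack`` for end-to-end training; the two agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor, concat


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

@dataclass
class DCAWeights:
    """Per-layer weights: list entries are dicts with keys
    ``W`` (d x d), ``W_M``, ``W_E`` (d x 2d), ``b_M``, ``b_E`` (d x 1)."""

    layers: list = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @staticmethod
    def zeros(d: int, n_layers: int) -> "DCAWeights":
        return DCAWeights([
            {"W": np.zeros((d, d)), "W_M": np.zeros((d, 2 * d)),
             "W_E": np.zeros((d, 2 * d)), "b_M": np.zeros((d, 1)),
             "b_E": np.zeros((d, 1))}
            for _ in range(n_layers)
        ])

    @staticmethod
    def random(d: int, n_layers: int, rng: np.random.Generator,
               scale: float | None = None) -> "DCAWeights":
        s = scale if scale is not None else 1.0 / np.sqrt(d)
        return DCAWeights([
            {"W": rng.normal(0, s, (d, d)),
             "W_M": rng.normal(0, s / np.sqrt(2), (d, 2 * d)),
             "W_E": rng.normal(0, s / np.sqrt(2), (d, 2 * d)),
             "b_M": np.zeros((d, 1)), "b_E": np.zeros((d, 1))}
            for _ in range(n_layers)
        ])


def _check_2d(name, arr):
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# functional (NumPy) form
# ---------------------------------------------------------------------------

def affinity(e_prev: np.ndarray, m_prev: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Bilinear affinity ``A = E^T W M`` of shape ``(n_e, n_m)``."""
    e_prev, m_prev, w = (_check_2d("E", e_prev), _check_2d("M", m_prev),
                         _check_2d("W", w))
    d = e_prev.shape[0]
    if w.shape != (d, d) or m_prev.shape[0] != d:
        raise ValueError(
            f"dimension mismatch: E {e_prev.shape}, W {w.shape}, M {m_prev.shape}")
    return e_prev.T @ w @ m_prev


def _row_softmax(a: np.ndarray) -> np.ndarray:
    shifted = a - a.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def attention_maps(a: np.ndarray) -> tuple:
    """Row-stochastic attention maps ``(A_M, A_E)`` from the affinity matrix:
    ``A_M = rowsoftmax(A)`` (n_e x n_m), ``A_E = rowsoftmax(A^T)`` (n_m x n_e)."""
    a = _check_2d("A", a)
    if not np.all(np.isfinite(a)):
        raise ValueError("affinity matrix contains non-finite entries")
    return _row_softmax(a), _row_softmax(a.T)


def attend(m_prev: np.ndarray, e_prev: np.ndarray,
           a_m: np.ndarray, a_e: np.ndarray) -> tuple:
    """Cross-attended features ``P_M = M A_M^T`` (d x n_e) and
    ``P_E = E A_E^T`` (d x n_m)."""
    m_prev, e_prev = _check_2d("M", m_prev), _check_2d("E", e_prev)
    a_m, a_e = _check_2d("A_M", a_m), _check_2d("A_E", a_e)
    if a_m.shape != (e_prev.shape[1], m_prev.shape[1]):
        raise ValueError(f"A_M shape {a_m.shape} inconsistent with "
                         f"n_e={e_prev.shape[1]}, n_m={m_prev.shape[1]}")
    if a_e.shape != (m_prev.shape[1], e_prev.shape[1]):
        raise ValueError(f"A_E shape {a_e.shape} inconsistent")
    return m_prev @ a_m.T, e_prev @ a_e.T


def dca_layer(m_prev: np.ndarray, e_prev: np.ndarray, weights: dict) -> tuple:
    """One full DCA layer; returns ``(M_i, E_i)`` with input shapes preserved."""
    a = affinity(e_prev, m_prev, weights["W"])
    a_m, a_e = attention_maps(a)
    p_m, p_e = attend(m_prev, e_prev, a_m, a_e)
    m_cat = np.vstack([m_prev, p_e])   # (2d, n_m)
    e_cat = np.vstack([e_prev, p_m])   # (2d, n_e)
    m_i = np.maximum(weights["W_M"] @ m_cat + weights["b_M"], 0.0) + m_prev
    e_i = np.maximum(weights["W_E"] @ e_cat + weights["b_E"], 0.0) + e_prev
    if m_i.shape != m_prev.shape or e_i.shape != e_prev.shape:
        raise ValueError("DCA layer must preserve shapes")
    return m_i, e_i


def stacked_dca(m0: np.ndarray, e0: np.ndarray, weights: DCAWeights) -> tuple:
    """Apply ``weights.n_layers`` DCA layers; zero layers is the identity."""
    m, e = np.asarray(m0, dtype=float), np.asarray(e0, dtype=float)
    for layer in weights.layers:
        m, e = dca_layer(m, e, layer)
    return m, e


def reshape_to_dca(features: np.ndarray, d: int) -> np.ndarray:
    """Row-major reshape of a flat feature vector (or (f, p) tensor) to
    ``(d, n)``; the feature count must be a multiple of ``d``.  Encoders whose
    feature count is not a multiple of ``d`` go through a learned linear
    projection instead (see :class:`~dcafusion.model.MovementFusionNet`)."""
    if d <= 0:
        raise ValueError("d must be positive")
    flat = np.asarray(features, dtype=float).reshape(-1)
    if flat.size % d:
        raise ValueError(
            f"feature count {flat.size} not divisible by d={d}; "
            "use a learned projection")
    return flat.reshape(d, -1)


# ---------------------------------------------------------------------------
# autograd form (batched)
# ---------------------------------------------------------------------------

class DCAStack(nn.Module):
    """N stacked DCA layers over batched states ``M (B, d, n_m)`` and
    ``E (B, d, n_e)``.  Weight layout matches :class:`DCAWeights`."""

    def __init__(self, d: int, n_layers: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if d <= 0 or n_layers < 0:
            raise ValueError("d must be positive and n_layers >= 0")
        rng = rng or np.random.default_rng(0)
        self.d, self.n_layers = d, n_layers
        init = DCAWeights.random(d, n_layers, rng)
        self.weights = [
            # order: W, W_M, W_E, b_M, b_E
            [Tensor(layer[k], requires_grad=True)
             for k in ("W", "W_M", "W_E", "b_M", "b_E")]
            for layer in init.layers
        ]
        # register parameters for discovery
        for i, layer in enumerate(self.weights):
            for name, p in zip(("W", "W_M", "W_E", "b_M", "b_E"), layer):
                setattr(self, f"layer{i}_{name}", p)

    def forward(self, m: Tensor, e: Tensor) -> tuple:
        for w, w_m, w_e, b_m, b_e in self.weights:
            a = e.transpose((0, 2, 1)) @ (w @ m)          # (B, n_e, n_m)
            a_m = nn.softmax(a, axis=2)                   # rows over n_m
            a_e = nn.softmax(a.transpose((0, 2, 1)), axis=2)
            p_m = m @ a_m.transpose((0, 2, 1))            # (B, d, n_e)
            p_e = e @ a_e.transpose((0, 2, 1))            # (B, d, n_m)
            m_new = ((w_m @ concat([m, p_e], axis=1)) + b_m).relu() + m
            e_new = ((w_e @ concat([e, p_m], axis=1)) + b_e).relu() + e
            m, e = m_new, e_new
        return m, e

    def export_weights(self) -> DCAWeights:
        return DCAWeights([
            {k: p.data.copy() for k, p in
             zip(("W", "W_M", "W_E", "b_M", "b_E"), layer)}
            for layer in self.weights
        ])
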