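"""Soft-stagewise regression (SSR) codec for the ellipse rotation angle.

The angle theta in [0, V) (V = 180 degrees by ellipse symmetry) is
expressed as a hierarchy of coarse-to-fine soft classifications.  Stage k
splits the previous stage's bin into ``s_k`` parts; with the default
stages (18, 10, 10) the bin widths are 10, 1 and 0.1 degrees.  The decoded
angle is the sum over stages of the probability-weighted bin indices times
the stage's bin width:

    theta = sum_k sum_i p_i^(k) * (i + eta_i^(k)) * V / prod_{j<=k} s_j*

where ``s_j* = s_j (1 + Delta_j)`` lets the network scale each stage's
span (a per-image "dynamic range") and ``eta_i^(k)`` shifts individual
bins.  Delta and eta live in (-1, 1) -- the network head squashes them
with tanh -- so bins cannot invert their order.

:func:`decode_angle` is written against a minimal array protocol
(arithmetic operators plus ``sum(axis=...)``) so the same arithmetic
serves plain numpy at inference time and autodiff tensors during
training, where gradients must flow through the decode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SSRConfig", "SSRPrediction", "decode_angle", "ssr_decode", "ssr_encode_reference"]


@dataclass(frozen=True)
class SSRConfig:
    """Stage bin counts and total angular range."""

    stages: tuple[int, ...] = (18, 10, 10)
    v_range: float = 180.0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.stages):
            raise ValueError("every stage needs at least 2 bins")
        if self.v_range <= 0:
            raise ValueError("angle range must be positive")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def total_bins(self) -> int:
        return int(sum(self.stages))

    def bin_width(self, k: int) -> float:
        """Nominal (Delta = 0) width of stage k's bins, degrees."""
        w = self.v_range
        for j in range(k + 1):
            w /= self.stages[j]
        return w


@dataclass
class SSRPrediction:
    """Per-stage bin probabilities, per-stage scale modifiers, per-bin shifts."""

    probs: list[np.ndarray]
    delta: np.ndarray = None  # shape (K,)
    eta: list[np.ndarray] = None

    def __post_init__(self) -> None:
        self.probs = [np.asarray(p, dtype=float) for p in self.probs]
        k = len(self.probs)
        if self.delta is None:
            self.delta = np.zeros(k)
        self.delta = np.asarray(self.delta, dtype=float).reshape(k)
        if self.eta is None:
            self.eta = [np.zeros_like(p) for p in self.probs]
        self.eta = [np.asarray(e, dtype=float) for e in self.eta]
        for p in self.probs:
            if abs(float(p.sum()) - 1.0) > 1e-6:
                raise ValueError("each stage's probabilities must sum to 1")


def decode_angle(probs: Sequence, etas: Sequence, deltas: Sequence, cfg: SSRConfig):
    """Decode SSR head outputs to an (unwrapped) angle.

    Parameters
    ----------
    probs, etas
        One array per stage, trailing axis of length ``s_k``; leading axes
        (if any) are batch axes.  Numpy arrays or autodiff tensors.
    deltas
        One scalar (or batch-shaped array) per stage.
    """
    if len(probs) != cfg.n_stages:
        raise ValueError(f"expected {cfg.n_stages} stages, got {len(probs)}")
    theta = 0.0
    denom = 1.0
    for k in range(cfg.n_stages):
        s_k = cfg.stages[k]
        p, e = probs[k], etas[k]
        if p.shape != e.shape or p.shape[-1] != s_k:
            raise ValueError(f"stage {k}: shape mismatch (want trailing axis {s_k})")
        denom = denom * (s_k * (1.0 + deltas[k]))
        width = cfg.v_range / denom
        ibar = e + np.arange(s_k, dtype=float)
        theta = theta + (p * ibar).sum(axis=-1) * width
    return theta


def ssr_decode(pred: SSRPrediction, cfg: SSRConfig | None = None) -> float:
    """Decode a single prediction to an angle wrapped into [0, V)."""
    cfg = cfg or SSRConfig()
    theta = float(decode_angle(pred.probs, pred.eta, pred.delta, cfg))
    return theta % cfg.v_range


def ssr_encode_reference(theta: float, cfg: SSRConfig | None = None) -> SSRPrediction:
    """Greedy coarse-to-fine one-hot encoding of an angle (test-only inverse).

    Assigns each stage the largest bin not exceeding the residual angle;
    Delta and eta are zero.  The round-trip error is below the finest bin
    width (0.1 degrees at the default stages).
    """
    cfg = cfg or SSRConfig()
    if not (0.0 <= theta < cfg.v_range):
        raise ValueError(f"angle must lie in [0, {cfg.v_range}), got {theta}")
    probs = []
    residual = float(theta)
    for k, s_k in enumerate(cfg.stages):
        width = cfg.bin_width(k)
        idx = min(int(residual / width), s_k - 1)
        residual -= idx * width
        onehot = np.zeros(s_k)
        onehot[idx] = 1.0
        probs.append(onehot)
    return SSRPrediction(probs=probs)
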