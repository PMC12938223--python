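"""Cross-entropy, mean-squared position loss, and the hard-gated objective.

The composite fine-tuning objective is

    L = L_CE + omega * 1[L_CE < loss_min] * L_pos

where the indicator is evaluated on the batch cross-entropy value itself:
the separability term only switches on once the classifier is already fitting
the batch.  Target positions enter ``L_pos`` as constants — they carry no
gradient, so the position term simply pulls features toward fixed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

__all__ = ["GateConfig", "LossBreakdown", "ce_loss", "ce_loss_grad",
           "position_loss", "position_loss_grad", "gated_total_loss"]


@dataclass(frozen=True)
class GateConfig:
    """Weight ``omega`` and gating threshold ``loss_min`` of the position term.

    ``loss_min = 0`` is legal and, because the gate opens strictly below the
    threshold, disables the position term entirely (CE-only training).
    """

    omega: float = 1.0
    loss_min: float = 0.2

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.loss_min < 0:
            raise ValueError("loss_min must be >= 0")


@dataclass(frozen=True)
class LossBreakdown:
    ce: float
    lpos: float
    gate_open: bool
    total: float


def _check_labels(y: np.ndarray, K: int) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        raise ValueError("labels must be integers")
    if np.any(y < 1) or np.any(y > K):
        raise ValueError(f"labels must lie in {{1..{K}}}")
    return y - 1


def ce_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy (natural log) of labels ``y`` in ``{1..K}``."""
    logits = np.asarray(logits, dtype=float)
    if logits.ndim != 2 or logits.shape[1] < 2:
        raise ValueError("logits must be N x K with K >= 2")
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits contain non-finite entries")
    idx = _check_labels(y, logits.shape[1])
    logp = log_softmax(logits, axis=1)
    return float(-logp[np.arange(len(idx)), idx].mean())


def ce_loss_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy value and its gradient with respect to the logits."""
    logits = np.asarray(logits, dtype=float)
    idx = _check_labels(y, logits.shape[1])
    N = logits.shape[0]
    logp = log_softmax(logits, axis=1)
    loss = float(-logp[np.arange(N), idx].mean())
    grad = softmax(logits, axis=1)
    grad[np.arange(N), idx] -= 1.0
    return loss, grad / N


def position_loss(Z: np.ndarray, t: np.ndarray) -> float:
    """Mean squared deviation of features from their target positions."""
    Z = np.asarray(Z, dtype=float)
    t = np.asarray(t, dtype=float)
    if Z.shape != t.shape:
        raise ValueError(f"shape mismatch: {Z.shape} vs {t.shape}")
    return float(np.mean((Z - t) ** 2))


def position_loss_grad(Z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Position-loss value and gradient w.r.t. ``Z`` (targets are constants)."""
    Z = np.asarray(Z, dtype=float)
    t = np.asarray(t, dtype=float)
    if Z.shape != t.shape:
        raise ValueError(f"shape mismatch: {Z.shape} vs {t.shape}")
    diff = Z - t
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def gated_total_loss(ce: float, lpos: float, cfg: GateConfig) -> LossBreakdown:
    """Compose the hard-gated objective from precomputed loss values.

    The gate opens strictly below ``loss_min`` (a batch sitting exactly at the
    threshold keeps the gate closed) and is evaluated on the detached CE
    value, so the indicator itself contributes no gradient.
    """
    if not (np.isfinite(ce) and np.isfinite(lpos)) or ce < 0 or lpos < 0:
        raise ValueError("ce and lpos must be finite and >= 0")
    gate_open = ce < cfg.loss_min
    total = ce + cfg.omega * lpos if gate_open else ce
    return LossBreakdown(ce=ce, lpos=lpos, gate_open=gate_open, total=total)
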