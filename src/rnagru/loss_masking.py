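"""Flag-masked, class-weighted cross-entropy for variable-length sequences.

Two mechanisms, composable per sequence of true length n padded to N:

* **Flag mask** — ``flag[i] = 1`` for i ≤ n, 0 beyond, so that padded
  positions contribute exactly nothing to the loss::

      cross_loss = Σ_i flag[i] · ℓ_i / Σ_i flag[i]

* **Dynamic class weights** — with u the number of unpaired bases in the
  sequence, unpaired bases get weight 1 and paired bases weight u, which
  upweights the minority "paired" classes (the paired:unpaired ratio in
  curated RNA data is about 2:3)::

      cross_loss = Σ_i flag[i]·weight[i]·ℓ_i / Σ_i flag[i]·weight[i]

  The degenerate all-paired sequence (u = 0) would zero every weight, so
  paired weights are floored at 1.

ℓ_i is the per-base cross-entropy −Σ_c y_[i,c] log y[i,c] with predicted
probabilities clamped at 1e−12 before the log.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

__all__ = [
    "PROB_CLAMP",
    "make_flag",
    "make_weight",
    "per_base_loss",
    "sequence_cross_entropy",
    "weighted_cross_entropy",
    "batch_loss",
    "batch_loss_logit_grad",
]

PROB_CLAMP = 1e-12


def make_flag(n: int, N: int) -> np.ndarray:
    """Binary mask: ones for the n real positions, zeros for padding."""
    if not 1 <= n <= N:
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    flag = np.zeros(N)
    flag[:n] = 1.0
    return flag


def make_weight(labels: np.ndarray, n: int) -> np.ndarray:
    """Per-base loss weights from one-hot labels of shape (N, C).

    Unpaired bases (class 0) get 1; paired bases get the number of unpaired
    bases in the sequence, floored at 1. Padded positions get 0 (they are
    inert under the flag mask regardless).
    """
    N = labels.shape[0]
    if not 1 <= n <= N:
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    unpaired = labels[:n, 0] > 0.5
    u = max(int(unpaired.sum()), 1)
    weight = np.zeros(N)
    weight[:n] = np.where(unpaired, 1.0, float(u))
    return weight


def per_base_loss(pred: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ℓ_i = −Σ_c y_[i,c] log y[i,c] along the last axis, clamped."""
    logp = np.log(np.clip(pred, PROB_CLAMP, None))
    return -(labels * logp).sum(axis=-1)


def _masked_mean(losses: np.ndarray, fw: np.ndarray) -> float:
    # Sum only the selected positions: appending padded (fw = 0) positions
    # then leaves the floating-point summation order untouched, so padding
    # changes the loss by exactly 0, not merely by round-off.
    idx = fw > 0
    denom = fw[idx].sum()
    if not idx.any() or denom <= 0:
        raise ValueError("flag/weight mask selects no positions: loss undefined")
    return float((fw[idx] * losses[idx]).sum() / denom)


def sequence_cross_entropy(
    pred: np.ndarray, labels: np.ndarray, flag: np.ndarray
) -> float:
    """Flag-masked mean cross-entropy for one sequence (pred: (N, C))."""
    return _masked_mean(per_base_loss(pred, labels), np.asarray(flag, dtype=float))


def weighted_cross_entropy(
    pred: np.ndarray, labels: np.ndarray, flag: np.ndarray, weight: np.ndarray
) -> float:
    """Flag- and weight-masked mean cross-entropy for one sequence."""
    return _masked_mean(per_base_loss(pred, labels), flag * weight)


def batch_loss(
    preds: np.ndarray,
    labels: np.ndarray,
    flags: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Mean over the batch of per-sequence weighted cross-entropies.

    Shapes: preds/labels (B, N, C); flags/weights (B, N).
    """
    if preds.shape[0] == 0:
        raise ValueError("empty batch")
    fw = flags * weights
    losses = per_base_loss(preds, labels)
    per_seq = [_masked_mean(losses[b], fw[b]) for b in range(preds.shape[0])]
    return float(np.mean(per_seq))


def batch_loss_logit_grad(
    probs: np.ndarray,
    labels: np.ndarray,
    flags: np.ndarray,
    weights: np.ndarray,
) -> Tuple[float, np.ndarray]:
    """Batch loss and its gradient w.r.t. the pre-softmax logits.

    For softmax probabilities y and one-hot labels y_, the per-position
    gradient is c_i (y − y_) with c_i = flag·weight / (Σ flag·weight · B).
    """
    B = probs.shape[0]
    fw = flags * weights
    denom = fw.sum(axis=1, keepdims=True)
    if np.any(denom <= 0):
        raise ValueError("a sequence has zero flag·weight mass")
    loss = batch_loss(probs, labels, flags, weights)
    coef = (fw / denom)[:, :, None] / B
    # d(−Σ_c y_[c] log y[c])/dlogits = (Σ_c y_[c])·y − y_ ; the mass term
    # matters for all-zero padding rows, whose loss (and gradient) is 0.
    mass = labels.sum(axis=-1, keepdims=True)
    grad = coef * (mass * probs - labels)
    return loss, grad
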