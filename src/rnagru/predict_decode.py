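"""From per-base class probabilities to a valid pairing map.

The network emits, for every base i, a distribution over "unpaired" and
"paired with base k". Rows need not agree with each other, so a decoding
policy resolves them into a symmetric structure:

* ``mutual_argmax`` (default) — keep pair (i, j) only when i's most probable
  partner is j *and* j's most probable partner is i; everything else is
  unpaired. Closest to scoring the raw per-base classifications.
* ``greedy_probability`` — rank candidate pairs by min(y[i→j], y[j→i]) and
  accept greedily while both bases are free; optionally restricted to
  canonical pairs {AU, UA, GC, CG, GU, UG}.

Neither policy imposes nestedness, so decoded structures may contain
pseudoknots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import PairingMap, RnaSequence, ValidationError
from .model_core import NetworkParams, network_forward
from .pair_probabilities import (
    DEFAULT_MODEL,
    PairEnergyModel,
    PairProbabilityMatrix,
)
from . import features as feat

__all__ = ["DecodingPolicy", "predict", "decode"]

_CANONICAL = {
    frozenset("AU"), frozenset("GC"), frozenset("GU"),
}


@dataclass(frozen=True)
class DecodingPolicy:
    mode: str = "mutual_argmax"
    canonical_only: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("mutual_argmax", "greedy_probability"):
            raise ValidationError(f"unknown decoding mode {self.mode!r}")


def predict(
    params: NetworkParams,
    seq: RnaSequence,
    P: Optional[PairProbabilityMatrix] = None,
    model: PairEnergyModel = DEFAULT_MODEL,
) -> np.ndarray:
    """Class probabilities for one sequence, shape (n, N+1).

    If no external pair-probability matrix is supplied, the internal
    partition function is used. Deterministic (dropout inactive).
    """
    n = len(seq)
    if n > params.N:
        raise ValidationError(
            f"sequence length {n} exceeds the model's padded length N={params.N}"
        )
    X = feat.build_features(seq, P, params.N, model)[None, :, :]
    probs = network_forward(X, params, training=False)
    return probs[0, :n, :]


def decode(
    pred: np.ndarray,
    n: int,
    policy: DecodingPolicy = DecodingPolicy(),
    seq: Optional[RnaSequence] = None,
) -> PairingMap:
    """Resolve an (n, C) probability matrix into a valid PairingMap."""
    if pred.shape[0] < n:
        raise ValidationError(f"prediction has {pred.shape[0]} rows for n={n}")
    partner = np.zeros(n, dtype=np.int64)
    if policy.mode == "mutual_argmax":
        # restrict to realizable classes: 0 (unpaired) or a partner <= n, not self
        scores = pred[:n, : n + 1].copy()
        for i in range(n):
            scores[i, i + 1] = -np.inf
        best = np.argmax(scores, axis=1)
        for i in range(n):
            j = best[i]
            if j > 0 and best[j - 1] == i + 1:
                partner[i] = j
    else:  # greedy_probability
        if policy.canonical_only and seq is None:
            raise ValidationError("canonical_only decoding requires the sequence")
        candidates = []
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                if policy.canonical_only:
                    pair = frozenset((seq.residues[i - 1], seq.residues[j - 1]))
                    if pair not in _CANONICAL:
                        continue
                score = min(pred[i - 1, j], pred[j - 1, i])
                if score > 0.0:
                    candidates.append((score, i, j))
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        free = np.ones(n + 1, dtype=bool)
        for score, i, j in candidates:
            if free[i] and free[j]:
                partner[i - 1] = j
                partner[j - 1] = i
                free[i] = free[j] = False
    return PairingMap(partner)
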