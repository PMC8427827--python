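"""Input tensors and label matrices for the per-base partner classifier.

Each base of a sequence of length n ≤ N (N = maximum length in the dataset,
which is also the recursion depth of the GRU) gets an (N + 5)-dimensional
feature vector:

* the base's row of the pair-probability matrix, zero-padded to length N,
* the within-sequence frequency of the base's own type (1 scalar),
* a one-hot encoding of the base identity (4 entries; A→0001, G→0010,
  C→0100, U→1000 read left-to-right, anything else all zeros).

The target for base j is one of N + 1 classes: class 0 means unpaired and
class k (1 ≤ k ≤ N) means "paired with base k". Rows beyond n are all-zero
padding, kept inert by the flag mask in the loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .io_formats import PairingMap, RnaSequence, StructureRecord, ValidationError
from .pair_probabilities import (
    DEFAULT_MODEL,
    PairEnergyModel,
    PairProbabilityMatrix,
    partition_function,
)

__all__ = [
    "ONE_HOT",
    "one_hot_base",
    "base_frequency",
    "build_features",
    "build_labels",
    "decode_labels",
    "FeatureBatch",
    "featurize",
    "batch",
    "DEFAULT_BATCH_SIZE",
]

DEFAULT_BATCH_SIZE = 200

# the four-digit codes read most-significant-first into vector slots 1..4
ONE_HOT: Dict[str, Tuple[int, int, int, int]] = {
    "A": (0, 0, 0, 1),
    "G": (0, 0, 1, 0),
    "C": (0, 1, 0, 0),
    "U": (1, 0, 0, 0),
}


def one_hot_base(residue: str) -> np.ndarray:
    return np.array(ONE_HOT.get(residue, (0, 0, 0, 0)), dtype=np.float64)


def base_frequency(seq: RnaSequence, i: int) -> float:
    """Relative frequency of the type of base i (1-based) within its sequence."""
    if not 1 <= i <= len(seq):
        raise ValueError(f"position {i} outside sequence of length {len(seq)}")
    target = seq.residues[i - 1]
    return seq.residues.count(target) / len(seq)


def _pair_matrix(
    item: Union[RnaSequence, StructureRecord],
    P: Optional[PairProbabilityMatrix],
    model: PairEnergyModel,
) -> Tuple[RnaSequence, np.ndarray]:
    seq = item.sequence if isinstance(item, StructureRecord) else item
    if P is None:
        P = partition_function(seq, model)
    if P.n != len(seq):
        raise ValidationError(
            f"pair-probability matrix is {P.n}x{P.n} but sequence has length {len(seq)}"
        )
    return seq, P.values


def build_features(
    item: Union[RnaSequence, StructureRecord],
    P: Optional[PairProbabilityMatrix],
    N: int,
    model: PairEnergyModel = DEFAULT_MODEL,
) -> np.ndarray:
    """Per-sequence feature slab of shape (N, N + 5).

    If ``P`` is None the pair-probability matrix is computed internally.
    """
    seq, pv = _pair_matrix(item, P, model)
    n = len(seq)
    if n > N:
        raise ValidationError(
            f"sequence length {n} exceeds the padded length N={N}; "
            "raise N to at least the longest sequence"
        )
    X = np.zeros((N, N + 5))
    counts = {b: seq.residues.count(b) for b in set(seq.residues)}
    for j in range(n):
        X[j, :n] = pv[j]
        X[j, N] = counts[seq.residues[j]] / n
        X[j, N + 1 :] = one_hot_base(seq.residues[j])
    return X


def build_labels(structure: PairingMap, N: int) -> np.ndarray:
    """One-hot label matrix of shape (N, N + 1); rows beyond n are all-zero."""
    n = len(structure)
    if n > N:
        raise ValidationError(f"structure length {n} exceeds N={N}")
    Y = np.zeros((N, N + 1))
    Y[np.arange(n), structure.partner] = 1.0
    return Y


def decode_labels(labels: np.ndarray, n: int) -> PairingMap:
    """Invert :func:`build_labels` for the first n rows."""
    return PairingMap(np.argmax(labels[:n], axis=1))


@dataclass
class FeatureBatch:
    """A batch of feature slabs, label matrices and true lengths."""

    X: np.ndarray  # (B, N, N+5)
    Y: np.ndarray  # (B, N, N+1)
    lengths: np.ndarray  # (B,)

    def __len__(self) -> int:
        return self.X.shape[0]


def featurize(
    records: Sequence[StructureRecord],
    N: int,
    model: PairEnergyModel = DEFAULT_MODEL,
    matrices: Optional[Sequence[PairProbabilityMatrix]] = None,
) -> FeatureBatch:
    """Build the stacked feature/label arrays for a whole dataset."""
    if not records:
        raise ValidationError("no records to featurize")
    X = np.stack(
        [
            build_features(rec, matrices[k] if matrices else None, N, model)
            for k, rec in enumerate(records)
        ]
    )
    Y = np.stack([build_labels(rec.structure, N) for rec in records])
    lengths = np.array([len(rec.sequence) for rec in records])
    return FeatureBatch(X, Y, lengths)


def batch(
    records: Sequence[StructureRecord],
    N: int,
    batch_size: int = DEFAULT_BATCH_SIZE,
    seed: Optional[int] = None,
    model: PairEnergyModel = DEFAULT_MODEL,
) -> List[FeatureBatch]:
    """Split a dataset into mini-batches (last partial batch kept).

    With a seed, record order is shuffled reproducibly before slicing.
    """
    if not records:
        raise ValidationError("cannot batch an empty record list")
    if batch_size < 1:
        raise ValidationError("batch_size must be positive")
    full = featurize(records, N, model)
    order = np.arange(len(records))
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    out = []
    for start in range(0, len(records), batch_size):
        idx = order[start : start + batch_size]
        out.append(FeatureBatch(full.X[idx], full.Y[idx], full.lengths[idx]))
    return out
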