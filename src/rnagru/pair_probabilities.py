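"""Base-pair probabilities from a McCaskill-style partition function.

The classifier's dominant input feature is the n×n matrix of equilibrium
base-pair probabilities. Here it is computed with inside/outside dynamic
programming over all *nested* secondary structures under a simple additive
pair-energy model (default: GC = −3, AU = −2, GU = −1 in units of kT, with a
minimum hairpin loop of 3 unpaired bases). This is deliberately not the
nearest-neighbour (Turner) model: the downstream network only needs an
informative pairing signal, and the simple model is exactly verifiable
against exhaustive enumeration. Users with a thermodynamic folding tool can
supply its probability matrix through :func:`load_external_matrix` instead.

Pseudoknots are excluded from the ensemble (the standard McCaskill
restriction); pseudoknot prediction is the classifier's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Tuple

import numpy as np

from .io_formats import RnaSequence, ValidationError

__all__ = [
    "PairEnergyModel",
    "DEFAULT_MODEL",
    "PairProbabilityMatrix",
    "partition_function",
    "enumerate_pair_probabilities",
    "load_external_matrix",
]

_TOL = 1e-6


def _default_energies() -> Dict[frozenset, float]:
    return {
        frozenset("GC"): -3.0,
        frozenset("AU"): -2.0,
        frozenset("GU"): -1.0,
    }


@dataclass(frozen=True)
class PairEnergyModel:
    """Additive pair energies in kT; pairs absent from the map are forbidden.

    ``min_loop`` is the minimum number of unpaired bases a hairpin must
    enclose, i.e. (i, j) may pair only when j − i > min_loop.
    """

    pair_energy: Dict[frozenset, float] = field(default_factory=_default_energies)
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValidationError("min_loop must be >= 0")
        for key, e in self.pair_energy.items():
            if not math.isfinite(e):
                raise ValidationError(f"non-finite energy for pair {set(key)}")

    def weight(self, a: str, b: str) -> float:
        """Boltzmann weight exp(−E) of pairing residues a and b (0 if forbidden)."""
        e = self.pair_energy.get(frozenset((a, b)))
        return 0.0 if e is None else math.exp(-e)

    def scaled(self, factor: float) -> "PairEnergyModel":
        """Model with all energies multiplied by ``factor`` (temperature sweep)."""
        return PairEnergyModel(
            {k: v * factor for k, v in self.pair_energy.items()}, self.min_loop
        )


DEFAULT_MODEL = PairEnergyModel()


class PairProbabilityMatrix:
    """Symmetric n×n matrix of pair probabilities; each row sums to ≤ 1."""

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray) -> None:
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValidationError("pair-probability matrix must be square")
        if np.max(np.abs(arr - arr.T), initial=0.0) > _TOL:
            raise ValidationError("pair-probability matrix must be symmetric")
        if np.max(np.abs(np.diag(arr)), initial=0.0) > _TOL:
            raise ValidationError("pair-probability matrix must have a zero diagonal")
        if arr.min(initial=0.0) < -_TOL or arr.max(initial=0.0) > 1 + _TOL:
            raise ValidationError("pair probabilities must lie in [0, 1]")
        rowsum = arr.sum(axis=1)
        if rowsum.size and rowsum.max() > 1 + _TOL:
            raise ValidationError(
                f"row sum {rowsum.max():.6f} exceeds 1: a base pairs with at most one partner"
            )
        arr = np.clip(arr, 0.0, 1.0)
        np.fill_diagonal(arr, 0.0)
        self.values = arr
        self.values.setflags(write=False)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _weight_matrix(seq: RnaSequence, model: PairEnergyModel) -> np.ndarray:
    n = len(seq)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + model.min_loop + 1, n):
            w[i, j] = w[j, i] = model.weight(seq.residues[i], seq.residues[j])
    return w


def partition_function(
    seq: RnaSequence, model: PairEnergyModel = DEFAULT_MODEL
) -> PairProbabilityMatrix:
    """Pair probabilities over the Boltzmann ensemble of nested structures.

    Inside recursion (0-based, spans grown outward; Q ≡ 1 on empty intervals)::

        Q(i, j) = Q(i, j−1) + Σ_k Q(i, k−1) · w(k, j) · Q(k+1, j−1)

    Outside quantities ``Qout(i, j)`` sum the weights of everything outside a
    pair (i, j), decomposed by the pair that directly encloses it, and

        P(i, j) = w(i, j) · Q(i+1, j−1) · Qout(i, j) / Q(0, n−1).

    Per-nucleotide rescaling keeps intermediates inside double range for very
    long sequences; probabilities are invariant to the scale.
    """
    n = len(seq)
    w = _weight_matrix(seq, model)
    if not np.any(w):
        return PairProbabilityMatrix(np.zeros((n, n)))

    # Per-nucleotide scale: only engage when the unscaled recursion could
    # overflow (roughly wmax**(n/2) > 1e150, leaving double-precision headroom).
    wmax = w.max()
    scale = 1.0
    if wmax > 1.0 and (n / 2) * math.log(wmax) > 150 * math.log(10):
        scale = wmax ** 0.5
    ws = w / scale**2
    inv_s = 1.0 / scale

    # Q[i][j] = inside partition function on i..j, scaled by s^-(j-i+1);
    # empty intervals (j < i) contribute exactly 1 via q().
    Q = np.zeros((n + 1, n + 1))

    def q(i: int, j: int) -> float:
        if j < i:
            return 1.0
        return Q[i][j]

    ml = model.min_loop
    for i in range(n):
        Q[i][i] = inv_s
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            total = Q[i][j - 1] * inv_s if j - 1 >= i else inv_s
            kmax = j - ml  # exclusive upper bound for the paired index k
            if kmax > i:
                # a[k] = Q(i, k-1), b[k] = Q(k+1, j-1) for k in [i, kmax)
                m = kmax - i
                a = np.empty(m)
                a[0] = 1.0
                a[1:] = Q[i, i : kmax - 1]
                b = Q[i + 1 : kmax + 1, j - 1]
                if ml == 0:  # k = j-1 has an empty enclosed interval
                    b = b.copy()
                    b[-1] = 1.0
                total += float(a @ (ws[i:kmax, j] * b))
            Q[i][j] = total

    Qtot = q(0, n - 1)

    # Outside pass: process pairable (i, j) in decreasing span order.
    # Qout(i,j) = Q(0,i-1)·Q(j+1,n-1)
    #           + Σ_{k<i, l>j} w(k,l)·Qout(k,l)·Q(k+1,i-1)·Q(j+1,l-1)
    M = np.zeros((n, n))  # ws[k,l] * Qout[k,l], filled as spans shrink
    P = np.zeros((n, n))
    # prefix[i] = Q(0, i-1), suffix[j] = Q(j+1, n-1)
    prefix = np.array([q(0, i - 1) for i in range(n)])
    suffix = np.array([q(j + 1, n - 1) for j in range(n)])
    for span in range(n - 1, model.min_loop, -1):
        for i in range(n - span):
            j = i + span
            if ws[i, j] == 0.0:
                continue
            qout = prefix[i] * suffix[j]
            if i > 0 and j < n - 1:
                # enclosing pairs (k, l), k < i, l > j: those have a strictly
                # larger span, so M[k, l] is already filled.
                # a[k] = Q(k+1, i-1), b[l] = Q(j+1, l-1); empty intervals = 1.
                a = np.empty(i)
                a[: i - 1] = Q[1:i, i - 1]
                a[i - 1] = 1.0
                b = np.empty(n - 1 - j)
                b[0] = 1.0
                b[1:] = Q[j + 1, j + 1 : n - 1]
                qout += a @ M[0:i, j + 1 : n] @ b
            M[i, j] = ws[i, j] * qout
            P[i, j] = P[j, i] = ws[i, j] * q(i + 1, j - 1) * qout / Qtot

    P = np.clip(P, 0.0, 1.0)
    return PairProbabilityMatrix(P)


def _enumerate_structures(
    w: np.ndarray, min_loop: int, i: int, j: int
) -> Iterator[Tuple[Tuple[int, int], ...]]:
    """Yield every nested structure on [i, j] exactly once (0-based pairs)."""
    if i > j:
        yield ()
        return
    # base i unpaired
    for rest in _enumerate_structures(w, min_loop, i + 1, j):
        yield rest
    # base i paired with k
    for k in range(i + min_loop + 1, j + 1):
        if w[i, k] > 0.0:
            for inner in _enumerate_structures(w, min_loop, i + 1, k - 1):
                for outer in _enumerate_structures(w, min_loop, k + 1, j):
                    yield ((i, k),) + inner + outer


def enumerate_pair_probabilities(
    seq: RnaSequence, model: PairEnergyModel = DEFAULT_MODEL
) -> PairProbabilityMatrix:
    """Brute-force pair probabilities by explicit enumeration (n ≤ 16).

    Test oracle only: sums Boltzmann weights over every nested structure.
    """
    n = len(seq)
    if n > 16:
        raise ValueError("enumeration oracle refuses n > 16 (combinatorial blow-up)")
    w = _weight_matrix(seq, model)
    Z = 0.0
    acc = np.zeros((n, n))
    for structure in _enumerate_structures(w, model.min_loop, 0, n - 1):
        weight = 1.0
        for i, j in structure:
            weight *= w[i, j]
        Z += weight
        for i, j in structure:
            acc[i, j] += weight
            acc[j, i] += weight
    return PairProbabilityMatrix(acc / Z if Z > 0 else acc)


def load_external_matrix(path: str | Path, n: int) -> PairProbabilityMatrix:
    """Load a pair-probability matrix computed by an external folding tool.

    Accepts either a whitespace-delimited full n×n matrix or triplet lines
    ``i j p`` with 1-based indices (remaining entries zero). The result is
    symmetrized and validated.
    """
    rows: List[List[str]] = []
    for line in Path(path).read_text().splitlines():
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            rows.append(stripped.split())

    def is_triplet(fields: List[str]) -> bool:
        if len(fields) != 3:
            return False
        try:
            i, j = int(fields[0]), int(fields[1])
            float(fields[2])
        except ValueError:
            return False
        return 1 <= i <= n and 1 <= j <= n

    if len(rows) == n and all(len(r) == n for r in rows):
        try:
            mat = np.array([[float(x) for x in r] for r in rows])
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric matrix entry: {exc}") from exc
        mat = 0.5 * (mat + mat.T)
    elif all(is_triplet(r) for r in rows):
        mat = np.zeros((n, n))
        for fields in rows:
            i, j, p = int(fields[0]), int(fields[1]), float(fields[2])
            if i == j:
                raise ValidationError(f"{path}: self-pair probability for base {i}")
            mat[i - 1, j - 1] = mat[j - 1, i - 1] = p
    else:
        shape = f"{len(rows)} rows" if rows else "no rows"
        raise ValidationError(
            f"{path}: expected an {n}x{n} matrix or 'i j p' triplets, got {shape}"
        )
    return PairProbabilityMatrix(mat)
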