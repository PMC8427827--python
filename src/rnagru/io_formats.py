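"""Reading and writing RNA sequences and secondary structures.

Supported interchange formats, all plain text:

* CT (the RNAstructure-ecosystem connectivity table),
* BPSEQ (three-column index / base / partner),
* dot-bracket with up to four bracket layers ``() [] {} <>`` so that
  pseudoknotted (crossing) pairs can be expressed,
* FASTA for bare sequences.

Everything converts to and from :class:`PairingMap`, a 1-based partner-index
array (0 = unpaired) that is agnostic to nestedness and therefore represents
pseudoknots natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO

__all__ = [
    "ParseError",
    "ValidationError",
    "RnaSequence",
    "PairingMap",
    "StructureRecord",
    "read_ct",
    "write_ct",
    "read_bpseq",
    "write_bpseq",
    "read_dot_bracket",
    "write_dot_bracket",
    "read_fasta",
    "has_pseudoknot",
    "BRACKET_LAYERS",
]


class ParseError(ValueError):
    """A file does not conform to the expected on-disk syntax."""


class ValidationError(ValueError):
    """Syntactically valid input that violates a structural invariant."""


def _normalize_residues(residues: str) -> str:
    return residues.upper().replace("T", "U")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA primary structure: an identifier and a residue string.

    Residues are stored uppercase with T normalized to U; characters outside
    {A, C, G, U} are preserved and treated as an "other" class downstream.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalize_residues(self.residues))
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n(self) -> int:
        return len(self.residues)


class PairingMap:
    """Per-base partner indices (1-based; 0 = unpaired) for one structure.

    Enforces symmetry (``partner[partner[i]] == i``), no self-pairing and
    in-range indices at construction time.
    """

    __slots__ = ("partner",)

    def __init__(self, partner: Sequence[int]) -> None:
        arr = np.asarray(partner, dtype=np.int64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValidationError("partner array must be one-dimensional and non-empty")
        n = arr.size
        if arr.min() < 0 or arr.max() > n:
            raise ValidationError(f"partner indices must lie in [0, {n}]")
        for i in range(n):
            j = arr[i]
            if j == 0:
                continue
            if j == i + 1:
                raise ValidationError(f"base {i + 1} pairs with itself")
            if arr[j - 1] != i + 1:
                raise ValidationError(
                    f"asymmetric pairing: base {i + 1} says {j}, base {j} says {arr[j - 1]}"
                )
        self.partner = arr
        self.partner.setflags(write=False)

    def __len__(self) -> int:
        return self.partner.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairingMap):
            return NotImplemented
        return np.array_equal(self.partner, other.partner)

    def __hash__(self) -> int:
        return hash(self.partner.tobytes())

    def __repr__(self) -> str:  # pragma: no cover
        return f"PairingMap({self.partner.tolist()})"

    def pairs(self) -> List[Tuple[int, int]]:
        """All pairs (i, j) with i < j, 1-based, sorted by i."""
        return [
            (i + 1, int(j))
            for i, j in enumerate(self.partner)
            if j > i + 1
        ]

    @classmethod
    def unpaired(cls, n: int) -> "PairingMap":
        return cls(np.zeros(n, dtype=np.int64))


@dataclass(frozen=True)
class StructureRecord:
    """A sequence together with its known secondary structure."""

    sequence: RnaSequence
    structure: PairingMap

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValidationError(
                f"record {self.sequence.id!r}: sequence length {len(self.sequence)} "
                f"!= structure length {len(self.structure)}"
            )


def has_pseudoknot(structure: PairingMap) -> bool:
    """True iff two pairs (i, j) and (m, n) cross, i.e. i < m < j < n."""
    pairs = structure.pairs()
    for a in range(len(pairs)):
        i, j = pairs[a]
        for b in range(a + 1, len(pairs)):
            m, n = pairs[b]
            # pairs() sorts by opening index, so i < m always holds here
            if m < j < n:
                return True
    return False


# ---------------------------------------------------------------------------
# CT


def read_ct(path: str | Path) -> List[StructureRecord]:
    """Read one or more structures from a CT (connectivity table) file.

    Header line: ``<length> <title>``; per-base lines carry six columns
    (index, base, previous, next, partner, natural index). Multiple
    concatenated entries yield multiple records.
    """
    lines = Path(path).read_text().splitlines()
    records: List[StructureRecord] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        header = lines[pos].split()
        try:
            n = int(header[0])
        except (IndexError, ValueError):
            raise ParseError(f"{path}:{pos + 1}: expected CT header '<length> <title>'")
        title = " ".join(header[1:]) if len(header) > 1 else f"ct_{len(records)}"
        if n < 1:
            raise ParseError(f"{path}:{pos + 1}: non-positive length {n}")
        residues = []
        partner = np.zeros(n, dtype=np.int64)
        for k in range(n):
            lineno = pos + 2 + k
            if lineno - 1 >= len(lines):
                raise ParseError(f"{path}:{lineno}: truncated CT entry (expected {n} bases)")
            fields = lines[lineno - 1].split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 CT columns, got {len(fields)}")
            try:
                idx, base, pair = int(fields[0]), fields[1], int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed CT line")
            if idx != k + 1:
                raise ParseError(f"{path}:{lineno}: base index {idx}, expected {k + 1}")
            residues.append(base)
            partner[k] = pair
        try:
            pm = PairingMap(partner)
        except ValidationError as exc:
            raise ValidationError(f"{path}: entry {title!r}: {exc}") from exc
        records.append(StructureRecord(RnaSequence(title, "".join(residues)), pm))
        pos += 1 + n
    return records


def write_ct(records: Iterable[StructureRecord], path: str | Path) -> None:
    out = []
    for rec in records:
        n = len(rec.sequence)
        out.append(f"{n} {rec.sequence.id}")
        for i in range(n):
            nxt = i + 2 if i + 1 < n else 0
            out.append(
                f"{i + 1} {rec.sequence.residues[i]} {i} {nxt} "
                f"{rec.structure.partner[i]} {i + 1}"
            )
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# BPSEQ


def read_bpseq(path: str | Path) -> List[StructureRecord]:
    """Read BPSEQ: blank-line-separated blocks of ``index base partner``."""
    text = Path(path).read_text()
    records: List[StructureRecord] = []
    block: List[Tuple[int, str, str, int]] = []  # (lineno, base, raw, partner)

    def flush(block):
        if not block:
            return
        residues = []
        partner = np.zeros(len(block), dtype=np.int64)
        for k, (lineno, idx, base, pair) in enumerate(block):
            if idx != k + 1:
                raise ParseError(f"{path}:{lineno}: non-contiguous index {idx}, expected {k + 1}")
            if pair > len(block):
                raise ValidationError(f"{path}:{lineno}: partner {pair} exceeds length {len(block)}")
            residues.append(base)
            partner[k] = pair
        pm = PairingMap(partner)  # may raise ValidationError (asymmetry etc.)
        records.append(
            StructureRecord(RnaSequence(f"bpseq_{len(records)}", "".join(residues)), pm)
        )

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            flush(block)
            block = []
            continue
        fields = stripped.split()
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 BPSEQ columns, got {len(fields)}")
        try:
            idx, pair = int(fields[0]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed BPSEQ line")
        block.append((lineno, idx, fields[1], pair))
    flush(block)
    return records


def write_bpseq(records: Iterable[StructureRecord], path: str | Path) -> None:
    chunks = []
    for rec in records:
        lines = [
            f"{i + 1} {rec.sequence.residues[i]} {rec.structure.partner[i]}"
            for i in range(len(rec.sequence))
        ]
        chunks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(chunks) + "\n")


# ---------------------------------------------------------------------------
# Dot-bracket

BRACKET_LAYERS = ["()", "[]", "{}", "<>"]
_OPEN = {pair[0]: layer for layer, pair in enumerate(BRACKET_LAYERS)}
_CLOSE = {pair[1]: layer for layer, pair in enumerate(BRACKET_LAYERS)}


def read_dot_bracket(path: str | Path) -> List[StructureRecord]:
    """Read dot-bracket records: optional ``>id`` line, sequence, structure.

    Crossing pairs must use distinct bracket layers (up to four supported).
    """
    lines = [ln.rstrip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    records: List[StructureRecord] = []
    pos = 0
    while pos < len(lines):
        if lines[pos].startswith(">"):
            rid = lines[pos][1:].strip() or f"db_{len(records)}"
            pos += 1
        else:
            rid = f"db_{len(records)}"
        if pos + 1 >= len(lines):
            raise ParseError(f"{path}: record {rid!r}: missing sequence/structure line")
        seq_line, struct_line = lines[pos], lines[pos + 1]
        pos += 2
        if len(seq_line) != len(struct_line):
            raise ValidationError(
                f"{path}: record {rid!r}: sequence length {len(seq_line)} != "
                f"structure length {len(struct_line)}"
            )
        partner = np.zeros(len(struct_line), dtype=np.int64)
        stacks: List[List[int]] = [[] for _ in BRACKET_LAYERS]
        for i, ch in enumerate(struct_line):
            if ch == ".":
                continue
            if ch in _OPEN:
                stacks[_OPEN[ch]].append(i)
            elif ch in _CLOSE:
                stack = stacks[_CLOSE[ch]]
                if not stack:
                    raise ParseError(
                        f"{path}: record {rid!r}: unbalanced {ch!r} at position {i + 1}"
                    )
                j = stack.pop()
                partner[i] = j + 1
                partner[j] = i + 1
            else:
                raise ParseError(
                    f"{path}: record {rid!r}: invalid structure character {ch!r}"
                )
        leftovers = [s for s in stacks if s]
        if leftovers:
            raise ParseError(f"{path}: record {rid!r}: unbalanced open brackets")
        records.append(StructureRecord(RnaSequence(rid, seq_line), PairingMap(partner)))
    return records


def brackets_for(structure: PairingMap) -> str:
    """Render a structure as multi-layer dot-bracket notation.

    Pairs are assigned greedily (by opening position) to the first bracket
    layer in which they cross no already-placed pair. Structures needing more
    than four layers are rejected.
    """
    chars = ["."] * len(structure)
    layers: List[List[Tuple[int, int]]] = [[] for _ in BRACKET_LAYERS]
    for i, j in structure.pairs():
        placed = False
        for layer, placed_pairs in enumerate(layers):
            if not any(m < i < n < j or i < m < j < n for m, n in placed_pairs):
                placed_pairs.append((i, j))
                chars[i - 1] = BRACKET_LAYERS[layer][0]
                chars[j - 1] = BRACKET_LAYERS[layer][1]
                placed = True
                break
        if not placed:
            raise ValidationError(
                f"structure needs more than {len(BRACKET_LAYERS)} bracket layers"
            )
    return "".join(chars)


def write_dot_bracket(records: Iterable[StructureRecord], path: str | Path) -> None:
    out = []
    for rec in records:
        out.append(f">{rec.sequence.id}")
        out.append(rec.sequence.residues)
        out.append(brackets_for(rec.structure))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> List[RnaSequence]:
    """Read RNA sequences from FASTA, normalizing T→U and lowercase→upper."""
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq)
        if not residues:
            raise ValidationError(f"{path}: record {rec.id!r} has an empty sequence")
        seqs.append(RnaSequence(rec.id, residues))
    return seqs
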