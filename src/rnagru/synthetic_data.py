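"""Structure-first synthetic RNA data with controllable statistics.

Records are generated structure-first: a pairing map is sampled to hit a
target paired-base fraction (default 0.4, i.e. the 2:3 paired:unpaired
ratio typical of curated RNA structure collections), then a sequence is
filled in complementary at paired positions. This guarantees a learnable
sequence→structure signal; realism of specific RNA families is explicitly
not the goal.

Nested helices (2–4 pairs) are placed by recursive interval splitting; with
probability ``pk_prob`` one extra helix is inserted so that it crosses an
existing one (pairs (i, j), (m, n) with i < m < j < n), producing a genuine
pseudoknot expressible with two bracket layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .io_formats import (
    PairingMap,
    RnaSequence,
    StructureRecord,
    ValidationError,
    has_pseudoknot,
    write_bpseq,
    write_ct,
    write_dot_bracket,
)

__all__ = ["SyntheticConfig", "generate_structure", "generate_sequence",
           "generate_dataset", "write_dataset"]

MIN_LOOP = 3  # minimum unpaired hairpin span, matching the energy model

_WC = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
_GU = [("G", "U"), ("U", "G")]


@dataclass(frozen=True)
class SyntheticConfig:
    count: int = 50
    length_min: int = 20
    length_max: int = 60
    paired_fraction: float = 0.4
    pk_prob: float = 0.3
    gu_freq: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValidationError("paired_fraction must lie in [0, 1]")
        if self.length_min < 5:
            raise ValidationError("length_min must be >= 5")
        if self.length_max < self.length_min:
            raise ValidationError("length_max must be >= length_min")
        if self.count < 1:
            raise ValidationError("count must be positive")


def _place_helices(length: int, target_paired: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy nested helix placement; returns a partner array (may undershoot)."""
    partner = np.zeros(length, dtype=np.int64)
    intervals = [(0, length - 1)]  # inclusive, 0-based
    placed = 0
    while placed < target_paired - 1 and intervals:
        # only intervals wide enough for at least one pair with slack to
        # place it (width >= min_loop + 3 guarantees a non-empty (i, j) draw)
        viable = [iv for iv in intervals if iv[1] - iv[0] >= MIN_LOOP + 2]
        if not viable:
            break
        a, b = viable[rng.integers(len(viable))]
        intervals.remove((a, b))
        width = b - a + 1
        h_fit = (width - MIN_LOOP - 1) // 2
        h_need = max(1, (target_paired - placed) // 2)
        h = max(int(min(rng.integers(2, 5), h_fit, h_need)), 1)
        # choose outer pair (i, j) leaving room for the stem
        span_min = 2 * h + MIN_LOOP  # j - i >= 2(h-1) + min_loop + 1
        i = int(rng.integers(a, b - span_min + 1))
        j = int(rng.integers(i + span_min, b + 1))
        for t in range(h):
            partner[i + t] = j - t + 1
            partner[j - t] = i + t + 1
        placed += 2 * h
        if i - 1 - a >= 0:
            intervals.append((a, i - 1))
        if (j - h) - (i + h) >= 0:
            intervals.append((i + h, j - h))
        if b - (j + 1) >= 0:
            intervals.append((j + 1, b))
    return partner


def _unpaired_runs(partner: np.ndarray, lo: int, hi: int) -> List[tuple]:
    """Maximal runs of unpaired positions within [lo, hi] (0-based, inclusive)."""
    runs, start = [], None
    for k in range(lo, hi + 1):
        if partner[k] == 0:
            if start is None:
                start = k
        elif start is not None:
            runs.append((start, k - 1))
            start = None
    if start is not None:
        runs.append((start, hi))
    return runs


def _insert_crossing_helix(
    partner: np.ndarray, h: int, rng: np.random.Generator
) -> bool:
    """Insert an h-pair helix crossing an existing pair; True on success."""
    n = partner.size
    pairs = [(i, int(partner[i]) - 1) for i in range(n) if partner[i] > i + 1]
    rng.shuffle(pairs)
    for i, j in pairs:
        inner = [r for r in _unpaired_runs(partner, i + 1, j - 1) if r[1] - r[0] + 1 >= h]
        outer = (
            [r for r in _unpaired_runs(partner, j + 1, n - 1) if r[1] - r[0] + 1 >= h]
            if j + 1 <= n - 1
            else []
        )
        if not inner or not outer:
            continue
        ra = inner[rng.integers(len(inner))]
        rb = outer[rng.integers(len(outer))]
        m = int(rng.integers(ra[0], ra[1] - h + 2))
        q = int(rng.integers(rb[0] + h - 1, rb[1] + 1))
        ok = all(q - t - (m + t) > MIN_LOOP for t in range(h))
        if not ok:
            continue
        for t in range(h):
            partner[m + t] = q - t + 1
            partner[q - t] = m + t + 1
        return True
    return False


def generate_structure(
    length: int,
    paired_fraction: float,
    pk_prob: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    max_attempts: int = 60,
) -> PairingMap:
    """Sample a pairing map whose paired-base count is round(length·fraction) ± 2.

    With probability ``pk_prob`` the emitted structure contains a pseudoknot
    (an extra helix of 2–4 pairs crossing a nested one).
    """
    rng = rng or np.random.default_rng()
    target = int(round(length * paired_fraction))
    if target > 2 * ((length - MIN_LOOP) // 2):
        raise ValidationError(
            f"paired fraction {paired_fraction} infeasible at length {length}"
        )
    want_pk = bool(rng.random() < pk_prob)
    for _ in range(max_attempts):
        pk_h = int(rng.integers(2, 5)) if want_pk else 0
        nested_target = max(target - 2 * pk_h, 0)
        partner = _place_helices(length, nested_target, rng)
        if want_pk:
            if not _insert_crossing_helix(partner, pk_h, rng):
                continue
        if abs(int((partner > 0).sum()) - target) <= 2:
            pm = PairingMap(partner)
            if want_pk and not has_pseudoknot(pm):
                continue
            return pm
    raise ValidationError(
        f"could not realize paired fraction {paired_fraction} "
        f"(pk={want_pk}) at length {length}"
    )


def generate_sequence(
    structure: PairingMap,
    gu_freq: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    id: str = "synthetic",
) -> RnaSequence:
    """Fill a structure with a complementary sequence.

    Paired positions get a Watson–Crick pair with probability 1 − gu_freq and
    a GU wobble otherwise; unpaired positions are uniform over {A, C, G, U}.
    """
    rng = rng or np.random.default_rng()
    n = len(structure)
    residues = [""] * n
    for i in range(n):
        j = int(structure.partner[i])
        if j == 0:
            residues[i] = "ACGU"[rng.integers(4)]
        elif j > i + 1:
            pool = _GU if rng.random() < gu_freq else _WC
            a, b = pool[rng.integers(len(pool))]
            residues[i], residues[j - 1] = a, b
    return RnaSequence(id, "".join(residues))


def generate_dataset(config: SyntheticConfig) -> List[StructureRecord]:
    """Deterministic (seeded) list of synthetic structure records."""
    rng = np.random.default_rng(config.seed)
    records = []
    for k in range(config.count):
        length = int(rng.integers(config.length_min, config.length_max + 1))
        structure = generate_structure(
            length, config.paired_fraction, config.pk_prob, rng
        )
        seq = generate_sequence(
            structure, config.gu_freq, rng, id=f"syn_{k:04d}"
        )
        records.append(StructureRecord(seq, structure))
    return records


def write_dataset(
    records: List[StructureRecord],
    outdir: str | Path,
    config: Optional[SyntheticConfig] = None,
    fmt: str = "ct",
) -> Path:
    """Write one structure file per record plus a TSV manifest.

    Returns the manifest path. ``fmt`` is one of ct, bpseq, dbn.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    writers = {"ct": write_ct, "bpseq": write_bpseq, "dbn": write_dot_bracket}
    if fmt not in writers:
        raise ValidationError(f"unknown format {fmt!r}; choose from {sorted(writers)}")
    rows = []
    for rec in records:
        path = outdir / f"{rec.sequence.id}.{fmt}"
        writers[fmt]([rec], path)
        n = len(rec.sequence)
        paired = int((rec.structure.partner > 0).sum())
        rows.append(
            {
                "id": rec.sequence.id,
                "length": n,
                "paired_bases": paired,
                "paired_fraction": paired / n,
                "pseudoknot": has_pseudoknot(rec.structure),
                "file": path.name,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if config is not None:
        (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")
    return manifest
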