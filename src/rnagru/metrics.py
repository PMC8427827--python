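"""Per-base evaluation: sensitivity, PPV, accuracy and Matthews correlation.

Each base of each sequence falls into exactly one confusion cell:

* TP — truly paired and predicted with the correct partner,
* TN — truly unpaired and predicted unpaired,
* FP — predicted paired when unpaired in truth *or* paired to the wrong
  partner (wrong-partner bases count FP only, keeping the four cells a
  partition of the n bases),
* FN — predicted unpaired but truly paired.

SEN = TP/(TP+FN), PPV = TP/(TP+FP), ACC = (TP+TN)/total and
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with any ratio whose
denominator is zero defined as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

from .io_formats import PairingMap, ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "DatasetReport",
    "confusion",
    "compute_metrics",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    sen: float
    ppv: float
    acc: float
    mcc: float

    def to_dict(self) -> Dict[str, float]:
        c = self.counts
        return {
            "TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn,
            "SEN": self.sen, "PPV": self.ppv, "ACC": self.acc, "MCC": self.mcc,
        }


def confusion(pred: PairingMap, truth: PairingMap) -> ConfusionCounts:
    """Per-base confusion counts between a predicted and a true structure."""
    if len(pred) != len(truth):
        raise ValidationError(
            f"length mismatch: prediction {len(pred)} vs truth {len(truth)}"
        )
    tp = tn = fp = fn = 0
    for p, t in zip(pred.partner, truth.partner):
        if t > 0:
            if p == t:
                tp += 1
            elif p == 0:
                fn += 1
            else:
                fp += 1  # wrong partner: a predicted pairing that doesn't exist
        else:
            if p == 0:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    if c.total == 0:
        raise ValidationError("cannot compute metrics on zero evaluated bases")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return MetricsReport(
        counts=c,
        sen=_ratio(c.tp, c.tp + c.fn),
        ppv=_ratio(c.tp, c.tp + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
        mcc=_ratio(c.tp * c.tn - c.fp * c.fn, mcc_den),
    )


@dataclass(frozen=True)
class DatasetReport:
    """Pooled (summed counts) and macro (mean per-sequence) dataset metrics."""

    pooled: MetricsReport
    macro: Dict[str, float]
    per_sequence: List[MetricsReport]

    def to_dict(self) -> Dict[str, object]:
        return {
            "pooled": self.pooled.to_dict(),
            "macro": dict(self.macro),
            "per_sequence": [r.to_dict() for r in self.per_sequence],
        }


def evaluate_dataset(
    preds: Sequence[PairingMap], truths: Sequence[PairingMap]
) -> DatasetReport:
    if len(preds) != len(truths):
        raise ValidationError(
            f"{len(preds)} predictions vs {len(truths)} reference structures"
        )
    if not preds:
        raise ValidationError("nothing to evaluate")
    reports = [compute_metrics(confusion(p, t)) for p, t in zip(preds, truths)]
    pooled_counts = ConfusionCounts()
    for r in reports:
        pooled_counts = pooled_counts + r.counts
    macro = {
        key: sum(getattr(r, key.lower()) for r in reports) / len(reports)
        for key in ("SEN", "PPV", "ACC", "MCC")
    }
    return DatasetReport(compute_metrics(pooled_counts), macro, reports)
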