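"""Mini-batch training of the bidirectional GRU partner classifier.

The loop follows the dynamically weighted scheme: features, labels, flags
and per-base weights are built once up front; each iteration draws a
mini-batch, computes the flag-masked (and, in ``vldb`` mode, class-weighted)
cross-entropy, backpropagates and updates the parameters. Three weight modes
reproduce the ablation between the padded baseline, the flag-masked model
and the fully weighted model:

* ``plain``  — no masking: padding positions are labelled "unpaired" and
  scored like real bases (the crude length-supplement baseline),
* ``flag``   — flag mask only (padding inert, all real bases weight 1),
* ``vldb``   — flag mask plus dynamic class weights (the full model).

Defaults follow the reference configuration: hidden width 50, fully
connected width 150, learning rate 0.1 (plain SGD), 2000 iterations, batch
size 200, dropout 0.5. "Iterations" counts parameter updates, not epochs.
The recursion depth N defaults to the longest training sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureBatch, featurize
from .io_formats import StructureRecord, ValidationError
from .loss_masking import batch_loss_logit_grad, make_flag, make_weight
from .metrics import evaluate_dataset
from .model_core import (
    NetworkParams,
    _params_from_dict,
    init_params,
    network_backward,
    network_forward,
    network_forward_cached,
)
from .pair_probabilities import DEFAULT_MODEL, PairEnergyModel
from .predict_decode import DecodingPolicy, decode

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "train",
    "split",
    "save_checkpoint",
    "load_checkpoint",
    "WEIGHT_MODES",
]

CHECKPOINT_VERSION = 1
WEIGHT_MODES = ("vldb", "flag", "plain")
_MODE_ALIASES = {"weighted": "vldb", "flag_only": "flag", "vldb": "vldb",
                 "flag": "flag", "plain": "plain"}


@dataclass(frozen=True)
class TrainingConfig:
    hidden: int = 50
    fc_width: int = 150
    learning_rate: float = 0.1
    max_iterations: int = 2000
    batch_size: int = 200
    dropout: float = 0.5
    seed: int = 0
    optimizer: str = "sgd"
    weight_mode: str = "vldb"
    momentum: float = 0.9  # used only by optimizer="momentum"
    eval_every: int = 100
    N: Optional[int] = None  # padded length; default: longest training sequence

    def __post_init__(self) -> None:
        if min(self.hidden, self.fc_width, self.batch_size) < 1:
            raise ValidationError("widths and batch size must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be positive")
        if self.max_iterations < 0:
            raise ValidationError("max_iterations must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must lie in [0, 1)")
        if self.optimizer not in ("sgd", "momentum"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")
        if self.weight_mode not in _MODE_ALIASES:
            raise ValidationError(
                f"weight_mode must be one of {sorted(_MODE_ALIASES)}"
            )
        object.__setattr__(self, "weight_mode", _MODE_ALIASES[self.weight_mode])


@dataclass
class TrainingTrace:
    losses: List[float] = field(default_factory=list)
    eval_iterations: List[int] = field(default_factory=list)
    eval_metrics: List[Dict[str, float]] = field(default_factory=list)
    best_iteration: int = 0
    best_mcc: float = -np.inf

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"iteration": range(1, len(self.losses) + 1),
                             "loss": self.losses})


def split(
    records: Sequence[StructureRecord], fraction: float, seed: int
) -> Tuple[List[StructureRecord], List[StructureRecord]]:
    """Deterministic shuffle-split; ``fraction`` is the training share."""
    if not 0.0 < fraction < 1.0:
        raise ValidationError("split fraction must lie strictly in (0, 1)")
    order = np.arange(len(records))
    np.random.default_rng(seed).shuffle(order)
    cut = int(round(fraction * len(records)))
    return [records[i] for i in order[:cut]], [records[i] for i in order[cut:]]


def _masks_for_mode(
    data: FeatureBatch, mode: str
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(labels, flags, weights) arrays for the requested weight mode."""
    B, N, _ = data.Y.shape
    labels = data.Y.copy()
    flags = np.ones((B, N))
    weights = np.ones((B, N))
    if mode == "plain":
        # padding scored as "unpaired", as if the sequence had been extended
        for b, n in enumerate(data.lengths):
            labels[b, n:, 0] = 1.0
        return labels, flags, weights
    for b, n in enumerate(data.lengths):
        flags[b] = make_flag(int(n), N)
        if mode == "vldb":
            weights[b] = make_weight(labels[b], int(n))
        else:
            weights[b] = flags[b]
    return labels, flags, weights


def _evaluate(params: NetworkParams, data: FeatureBatch) -> Dict[str, float]:
    probs = network_forward(data.X, params, training=False)
    preds, truths = [], []
    policy = DecodingPolicy("mutual_argmax")
    from .features import decode_labels

    for b, n in enumerate(data.lengths):
        n = int(n)
        preds.append(decode(probs[b, :n], n, policy))
        truths.append(decode_labels(data.Y[b], n))
    report = evaluate_dataset(preds, truths)
    return report.pooled.to_dict()


def train(
    records: Sequence[StructureRecord],
    config: TrainingConfig = TrainingConfig(),
    val_records: Optional[Sequence[StructureRecord]] = None,
    model: PairEnergyModel = DEFAULT_MODEL,
) -> Tuple[NetworkParams, TrainingTrace]:
    """Train on ``records``; model selection by pooled MCC on the validation
    set (the training set itself when none is given).

    Deterministic for a fixed config and seed. Raises on divergence (NaN or
    infinite loss).
    """
    if not records:
        raise ValidationError("no training records")
    N = config.N or max(len(r.sequence) for r in records)
    data = featurize(records, N, model)
    val_data = featurize(val_records, N, model) if val_records else data
    labels, flags, weights = _masks_for_mode(data, config.weight_mode)

    rng = np.random.default_rng(config.seed)
    params = init_params(N, config.hidden, config.fc_width, config.dropout, rng)
    trace = TrainingTrace()
    best = params.copy()
    if config.max_iterations == 0:
        return params, trace

    velocity: Dict[str, np.ndarray] = {
        name: np.zeros_like(arr) for name, arr in params.arrays()
    }
    B_total = len(records)
    batch_size = min(config.batch_size, B_total)
    order = rng.permutation(B_total)
    cursor = 0

    for it in range(1, config.max_iterations + 1):
        if cursor + batch_size > B_total:
            order = rng.permutation(B_total)
            cursor = 0
        idx = order[cursor : cursor + batch_size]
        cursor += batch_size

        probs, cache = network_forward_cached(
            data.X[idx], params, training=True, rng=rng
        )
        loss, dlogits = batch_loss_logit_grad(
            probs, labels[idx], flags[idx], weights[idx]
        )
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at iteration {it}: loss={loss!r}; "
                "try a smaller learning rate"
            )
        trace.losses.append(loss)
        grads = network_backward(params, cache, dlogits)
        for name, arr in params.arrays():
            g = grads[name]
            if config.optimizer == "momentum":
                velocity[name] = config.momentum * velocity[name] - config.learning_rate * g
                arr += velocity[name]
            else:
                arr -= config.learning_rate * g

        if it % config.eval_every == 0 or it == config.max_iterations:
            m = _evaluate(params, val_data)
            trace.eval_iterations.append(it)
            trace.eval_metrics.append(m)
            if m["MCC"] > trace.best_mcc:
                trace.best_mcc = m["MCC"]
                trace.best_iteration = it
                best = params.copy()

    return best, trace


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(
    path: str | Path, params: NetworkParams, config: Optional[TrainingConfig] = None
) -> None:
    """Single-archive checkpoint: every array plus the model metadata."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "N": params.N,
        "hidden": params.hidden,
        "fc_width": params.fc_width,
        "dropout": params.dropout,
        "feature_version": params.feature_version,
        "config": asdict(config) if config else None,
    }
    arrays = dict(params.arrays())
    with open(path, "wb") as fh:  # exact path, no implicit .npz suffix
        np.savez(
            fh,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )


def load_checkpoint(path: str | Path) -> Tuple[NetworkParams, Optional[dict]]:
    with np.load(path) as archive:
        if "__meta__" not in archive:
            raise ValidationError(f"{path}: not an rnagru checkpoint")
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValidationError(
                f"{path}: checkpoint version {meta.get('version')} "
                f"not supported (expected {CHECKPOINT_VERSION})"
            )
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    params = _params_from_dict(
        arrays, meta["N"], meta["dropout"], meta.get("feature_version", "1")
    )
    return params, meta.get("config")
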