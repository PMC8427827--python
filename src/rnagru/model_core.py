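"""The bidirectional GRU network, in NumPy with hand-derived gradients.

Architecture (per position): input projection (N+5 → H) → forward and
backward GRU chains whose hidden states are **summed** elementwise (the
combined width stays H, not 2H) → two fully connected ReLU layers of width
F → dropout → linear output → softmax over N+1 partner classes.

GRU cell, with σ the logistic function and ⊙ elementwise product::

    r_t = σ(W_xr x_t + W_hr h_{t−1} + b_r)          (reset gate)
    z_t = σ(W_xz x_t + W_hz h_{t−1} + b_z)          (update gate)
    h̃_t = tanh(W_xh x_t + W_hh (r_t ⊙ h_{t−1}) + b_h)
    h_t = z_t ⊙ h_{t−1} + (1 − z_t) ⊙ h̃_t

Note the update-gate convention: z gates the *old* state. Padded timesteps
(j > n) are processed like any others; only the loss masks them out.

All gradients are implemented by hand (no autodiff framework is used) and
are validated against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, Iterator, Optional, Tuple

import numpy as np

__all__ = [
    "GruParams",
    "NetworkParams",
    "init_params",
    "gru_step",
    "gru_chain",
    "bidirectional_forward",
    "network_forward",
    "network_forward_cached",
    "network_backward",
    "softmax",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class GruParams:
    """Weights of one GRU direction; input dim D, hidden dim H."""

    W_xr: np.ndarray
    W_hr: np.ndarray
    b_r: np.ndarray
    W_xz: np.ndarray
    W_hz: np.ndarray
    b_z: np.ndarray
    W_xh: np.ndarray
    W_hh: np.ndarray
    b_h: np.ndarray

    def __post_init__(self) -> None:
        D, H = self.W_xr.shape
        expected = {
            "W_xr": (D, H), "W_hr": (H, H), "b_r": (H,),
            "W_xz": (D, H), "W_hz": (H, H), "b_z": (H,),
            "W_xh": (D, H), "W_hh": (H, H), "b_h": (H,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"GruParams.{name}: expected shape {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"GruParams.{name}: non-finite values")

    @property
    def hidden(self) -> int:
        return self.W_hr.shape[0]

    def arrays(self) -> Iterator[Tuple[str, np.ndarray]]:
        for f in dc_fields(self):
            yield f.name, getattr(self, f.name)


@dataclass
class NetworkParams:
    """Full parameter set plus the metadata needed to reuse a checkpoint."""

    proj_W: np.ndarray  # (N+5, H)
    proj_b: np.ndarray
    forward: GruParams
    backward: GruParams
    fc1_W: np.ndarray  # (H, F)
    fc1_b: np.ndarray
    fc2_W: np.ndarray  # (F, F)
    fc2_b: np.ndarray
    out_W: np.ndarray  # (F, N+1)
    out_b: np.ndarray
    N: int = 0
    dropout: float = 0.5
    feature_version: str = "1"

    @property
    def hidden(self) -> int:
        return self.forward.hidden

    @property
    def fc_width(self) -> int:
        return self.fc1_W.shape[1]

    @property
    def n_classes(self) -> int:
        return self.out_W.shape[1]

    def arrays(self) -> Iterator[Tuple[str, np.ndarray]]:
        """Flat (name, array) view over every trainable array."""
        for name in ("proj_W", "proj_b", "fc1_W", "fc1_b", "fc2_W", "fc2_b", "out_W", "out_b"):
            yield name, getattr(self, name)
        for prefix, gru in (("fw", self.forward), ("bw", self.backward)):
            for name, arr in gru.arrays():
                yield f"{prefix}.{name}", arr

    def copy(self) -> "NetworkParams":
        arrs = {name: arr.copy() for name, arr in self.arrays()}
        return _params_from_dict(arrs, self.N, self.dropout, self.feature_version)


def _gru_from_dict(d: Dict[str, np.ndarray], prefix: str) -> GruParams:
    return GruParams(**{f.name: d[f"{prefix}.{f.name}"] for f in dc_fields(GruParams)})


def _params_from_dict(
    d: Dict[str, np.ndarray], N: int, dropout: float, feature_version: str = "1"
) -> NetworkParams:
    return NetworkParams(
        proj_W=d["proj_W"], proj_b=d["proj_b"],
        forward=_gru_from_dict(d, "fw"), backward=_gru_from_dict(d, "bw"),
        fc1_W=d["fc1_W"], fc1_b=d["fc1_b"],
        fc2_W=d["fc2_W"], fc2_b=d["fc2_b"],
        out_W=d["out_W"], out_b=d["out_b"],
        N=N, dropout=dropout, feature_version=feature_version,
    )


def init_params(
    N: int,
    hidden: int = 50,
    fc_width: int = 150,
    dropout: float = 0.5,
    rng: Optional[np.random.Generator] = None,
) -> NetworkParams:
    """Uniform(−0.1, 0.1) initialization of every array, seedable via rng."""
    rng = rng or np.random.default_rng()
    D, H, F, C = N + 5, hidden, fc_width, N + 1

    def u(*shape):
        return rng.uniform(-0.1, 0.1, size=shape)

    def gru():
        return GruParams(
            W_xr=u(H, H), W_hr=u(H, H), b_r=u(H),
            W_xz=u(H, H), W_hz=u(H, H), b_z=u(H),
            W_xh=u(H, H), W_hh=u(H, H), b_h=u(H),
        )

    return NetworkParams(
        proj_W=u(D, H), proj_b=u(H),
        forward=gru(), backward=gru(),
        fc1_W=u(H, F), fc1_b=u(F),
        fc2_W=u(F, F), fc2_b=u(F),
        out_W=u(F, C), out_b=u(C),
        N=N, dropout=dropout,
    )


# ---------------------------------------------------------------------------
# Forward passes


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, p: GruParams) -> np.ndarray:
    """One GRU update; x_t is (..., D), h_prev is (..., H)."""
    if x_t.shape[-1] != p.W_xr.shape[0] or h_prev.shape[-1] != p.hidden:
        raise ValueError(
            f"gru_step shape mismatch: x {x_t.shape}, h {h_prev.shape}, "
            f"W_xr {p.W_xr.shape}"
        )
    r = sigmoid(x_t @ p.W_xr + h_prev @ p.W_hr + p.b_r)
    z = sigmoid(x_t @ p.W_xz + h_prev @ p.W_hz + p.b_z)
    h_cand = np.tanh(x_t @ p.W_xh + (r * h_prev) @ p.W_hh + p.b_h)
    return z * h_prev + (1.0 - z) * h_cand


def _gru_step_cached(x_t, h_prev, p):
    r = sigmoid(x_t @ p.W_xr + h_prev @ p.W_hr + p.b_r)
    z = sigmoid(x_t @ p.W_xz + h_prev @ p.W_hz + p.b_z)
    h_cand = np.tanh(x_t @ p.W_xh + (r * h_prev) @ p.W_hh + p.b_h)
    h = z * h_prev + (1.0 - z) * h_cand
    return h, (x_t, h_prev, r, z, h_cand)


def gru_chain(inputs: np.ndarray, p: GruParams, reverse: bool = False):
    """Run one GRU direction over (B, T, D) inputs from a zero initial state.

    Returns the (B, T, H) hidden states (in input order) and step caches.
    """
    B, T, _ = inputs.shape
    h = np.zeros((B, p.hidden))
    states = np.empty((B, T, p.hidden))
    caches = [None] * T
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        h, cache = _gru_step_cached(inputs[:, t, :], h, p)
        states[:, t, :] = h
        caches[t] = cache
    return states, caches


def bidirectional_forward(
    inputs: np.ndarray,
    forward: GruParams,
    backward: GruParams,
    lengths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Sum of the forward and backward GRU chains, shape (B, T, H).

    The combined per-position state is the elementwise sum (not a
    concatenation), so the output width equals the hidden width H. All T
    timesteps, padding included, are processed; ``lengths`` is accepted for
    interface symmetry but masking happens in the loss.
    """
    fwd, _ = gru_chain(inputs, forward, reverse=False)
    bwd, _ = gru_chain(inputs, backward, reverse=True)
    return fwd + bwd


def network_forward(
    X: np.ndarray,
    params: NetworkParams,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Class probabilities of shape (B, N, N+1); rows are simplices."""
    probs, _ = network_forward_cached(X, params, training=training, rng=rng)
    return probs


def network_forward_cached(
    X: np.ndarray,
    params: NetworkParams,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
):
    """Forward pass retaining every intermediate needed for backprop."""
    proj = X @ params.proj_W + params.proj_b
    fwd, fwd_caches = gru_chain(proj, params.forward, reverse=False)
    bwd, bwd_caches = gru_chain(proj, params.backward, reverse=True)
    h = fwd + bwd
    a1 = h @ params.fc1_W + params.fc1_b
    f1 = np.maximum(a1, 0.0)
    a2 = f1 @ params.fc2_W + params.fc2_b
    f2 = np.maximum(a2, 0.0)
    if training and params.dropout > 0.0:
        rng = rng or np.random.default_rng()
        keep = 1.0 - params.dropout
        mask = (rng.random(f2.shape) < keep) / keep
    else:
        mask = None
    d2 = f2 if mask is None else f2 * mask
    logits = d2 @ params.out_W + params.out_b
    probs = softmax(logits)
    cache = {
        "X": X, "proj": proj,
        "fwd_caches": fwd_caches, "bwd_caches": bwd_caches,
        "a1": a1, "f1": f1, "a2": a2, "f2": f2,
        "mask": mask, "d2": d2, "h": h,
    }
    return probs, cache


# ---------------------------------------------------------------------------
# Backward pass


def _gru_backward(dstates, caches, p: GruParams, reverse: bool):
    """Backprop through one GRU chain.

    dstates: (B, T, H) gradient w.r.t. each emitted hidden state.
    Returns (d_inputs, grads dict keyed like GruParams fields).
    """
    B, T, H = dstates.shape
    grads = {name: np.zeros_like(arr) for name, arr in p.arrays()}
    d_inputs = np.zeros((B, T, p.W_xr.shape[0]))
    dh_next = np.zeros((B, H))  # gradient flowing into h_t from step t+1 (chain order)
    order = range(T) if reverse else range(T - 1, -1, -1)
    for t in order:
        x_t, h_prev, r, z, h_cand = caches[t]
        dh = dstates[:, t, :] + dh_next
        # h = z*h_prev + (1-z)*h_cand
        dz_pre = dh * (h_prev - h_cand) * z * (1.0 - z)
        dcand_pre = dh * (1.0 - z) * (1.0 - h_cand**2)
        dh_prev = dh * z
        # candidate branch
        grads["W_xh"] += x_t.T @ dcand_pre
        grads["W_hh"] += (r * h_prev).T @ dcand_pre
        grads["b_h"] += dcand_pre.sum(axis=0)
        d_rh = dcand_pre @ p.W_hh.T
        dr_pre = d_rh * h_prev * r * (1.0 - r)
        dh_prev += d_rh * r
        dx = dcand_pre @ p.W_xh.T
        # reset gate
        grads["W_xr"] += x_t.T @ dr_pre
        grads["W_hr"] += h_prev.T @ dr_pre
        grads["b_r"] += dr_pre.sum(axis=0)
        dx += dr_pre @ p.W_xr.T
        dh_prev += dr_pre @ p.W_hr.T
        # update gate
        grads["W_xz"] += x_t.T @ dz_pre
        grads["W_hz"] += h_prev.T @ dz_pre
        grads["b_z"] += dz_pre.sum(axis=0)
        dx += dz_pre @ p.W_xz.T
        dh_prev += dz_pre @ p.W_hz.T
        d_inputs[:, t, :] = dx
        dh_next = dh_prev
    return d_inputs, grads


def network_backward(
    params: NetworkParams, cache: dict, dlogits: np.ndarray
) -> Dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every parameter array.

    ``dlogits`` is the loss gradient at the pre-softmax output, shape
    (B, N, C). Returns a dict keyed like :meth:`NetworkParams.arrays`.
    """
    grads: Dict[str, np.ndarray] = {}
    B, T, C = dlogits.shape
    d2 = cache["d2"]
    grads["out_W"] = d2.reshape(-1, d2.shape[-1]).T @ dlogits.reshape(-1, C)
    grads["out_b"] = dlogits.sum(axis=(0, 1))
    dd2 = dlogits @ params.out_W.T
    if cache["mask"] is not None:
        dd2 = dd2 * cache["mask"]
    da2 = dd2 * (cache["a2"] > 0.0)
    f1 = cache["f1"]
    grads["fc2_W"] = f1.reshape(-1, f1.shape[-1]).T @ da2.reshape(-1, da2.shape[-1])
    grads["fc2_b"] = da2.sum(axis=(0, 1))
    df1 = da2 @ params.fc2_W.T
    da1 = df1 * (cache["a1"] > 0.0)
    h = cache["h"]
    grads["fc1_W"] = h.reshape(-1, h.shape[-1]).T @ da1.reshape(-1, da1.shape[-1])
    grads["fc1_b"] = da1.sum(axis=(0, 1))
    dh = da1 @ params.fc1_W.T  # flows equally into both chains (h = fwd + bwd)
    dproj_f, fw_grads = _gru_backward(dh, cache["fwd_caches"], params.forward, reverse=False)
    dproj_b, bw_grads = _gru_backward(dh, cache["bwd_caches"], params.backward, reverse=True)
    for name, g in fw_grads.items():
        grads[f"fw.{name}"] = g
    for name, g in bw_grads.items():
        grads[f"bw.{name}"] = g
    dproj = dproj_f + dproj_b
    X = cache["X"]
    grads["proj_W"] = X.reshape(-1, X.shape[-1]).T @ dproj.reshape(-1, dproj.shape[-1])
    grads["proj_b"] = dproj.sum(axis=(0, 1))
    return grads
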