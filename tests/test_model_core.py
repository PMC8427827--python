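"""GRU cell, bidirectional combination and full forward pass."""

import numpy as np
import pytest

from rnagru.model_core import (
    GruParams,
    bidirectional_forward,
    gru_step,
    init_params,
    network_forward,
    network_forward_cached,
    softmax,
)


def make_gru(D, H, rng=None, zero=False):
    if zero:
        u = lambda *s: np.zeros(s)
    else:
        u = lambda *s: rng.uniform(-0.5, 0.5, size=s)
    return GruParams(
        W_xr=u(D, H), W_hr=u(H, H), b_r=u(H),
        W_xz=u(D, H), W_hz=u(H, H), b_z=u(H),
        W_xh=u(D, H), W_hh=u(H, H), b_h=u(H),
    )


def reference_gru_step(x, h_prev, p):
    """Scalar-by-scalar evaluation of the cell equations."""
    D, H = p.W_xr.shape
    h = np.zeros(H)
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    for k in range(H):
        ar = p.b_r[k] + sum(p.W_xr[d, k] * x[d] for d in range(D)) \
            + sum(p.W_hr[m, k] * h_prev[m] for m in range(H))
        az = p.b_z[k] + sum(p.W_xz[d, k] * x[d] for d in range(D)) \
            + sum(p.W_hz[m, k] * h_prev[m] for m in range(H))
        r_row = [sig(p.b_r[m] + sum(p.W_xr[d, m] * x[d] for d in range(D))
                     + sum(p.W_hr[q, m] * h_prev[q] for q in range(H)))
                 for m in range(H)]
        ah = p.b_h[k] + sum(p.W_xh[d, k] * x[d] for d in range(D)) \
            + sum(p.W_hh[m, k] * r_row[m] * h_prev[m] for m in range(H))
        z = sig(az)
        h[k] = z * h_prev[k] + (1.0 - z) * np.tanh(ah)
    return h


class TestGruStep:
    def test_zero_parameters_closed_form(self, rng):
        p = make_gru(3, 4, zero=True)
        v = rng.normal(size=4)
        h = gru_step(rng.normal(size=3), v, p)
        # r = z = sigmoid(0) = 1/2, candidate = tanh(0) = 0, so h = v/2
        assert np.allclose(h, 0.5 * v, atol=1e-15)

    def test_update_gate_saturation_carries_state(self, rng):
        p = make_gru(3, 4, rng)
        p.b_z[:] = 50.0  # z -> 1: the old state passes through unchanged
        v = rng.normal(size=4)
        h = gru_step(rng.normal(size=3), v, p)
        assert np.allclose(h, v, atol=1e-12)

    def test_matches_elementwise_reference(self, rng):
        worst = 0.0
        for _ in range(100):
            D, H = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            p = make_gru(D, H, rng)
            x, h_prev = rng.normal(size=D), rng.normal(size=H)
            got = gru_step(x, h_prev, p)
            ref = reference_gru_step(x, h_prev, p)
            worst = max(worst, float(np.abs(got - ref).max()))
        assert worst <= 1e-10

    def test_shape_mismatch_rejected(self, rng):
        p = make_gru(3, 4, rng)
        with pytest.raises(ValueError, match="mismatch"):
            gru_step(np.zeros(5), np.zeros(4), p)

    def test_bounded_state(self, rng):
        # h_t is a convex combination of h_prev and a tanh value
        p = make_gru(4, 6, rng)
        h = np.zeros(6)
        for _ in range(50):
            h = gru_step(rng.normal(size=4), h, p)
            assert np.all(np.abs(h) <= 1.0 + 1e-12)


class TestBidirectional:
    def test_sum_not_concatenation(self, rng):
        D, H, T = 5, 4, 6
        fw, bw = make_gru(D, H, rng), make_gru(D, H, rng)
        out = bidirectional_forward(rng.normal(size=(2, T, D)), fw, bw)
        assert out.shape == (2, T, H)  # width H, not 2H

    def test_single_timestep_is_sum_of_two_steps(self, rng):
        D, H = 5, 4
        fw, bw = make_gru(D, H, rng), make_gru(D, H, rng)
        x = rng.normal(size=(1, 1, D))
        out = bidirectional_forward(x, fw, bw)
        expected = gru_step(x[0, 0], np.zeros(H), fw) + gru_step(x[0, 0], np.zeros(H), bw)
        assert np.allclose(out[0, 0], expected)

    def test_reversal_symmetry(self, rng):
        """Reversing the inputs and swapping directions reverses the output."""
        D, H, T = 4, 3, 7
        fw, bw = make_gru(D, H, rng), make_gru(D, H, rng)
        x = rng.normal(size=(1, T, D))
        out = bidirectional_forward(x, fw, bw)
        flipped = bidirectional_forward(x[:, ::-1, :], bw, fw)
        assert np.allclose(out, flipped[:, ::-1, :], atol=1e-12)

    def test_zero_parameters_decay_chains(self):
        # both chains halve a zero initial state: all states stay exactly zero,
        # and the candidate tanh(0)=0 contributes nothing
        fw, bw = make_gru(2, 3, zero=True), make_gru(2, 3, zero=True)
        out = bidirectional_forward(np.ones((1, 5, 2)), fw, bw)
        assert np.allclose(out, 0.0)


class TestNetworkForward:
    def test_softmax_rows_are_simplices(self, rng):
        params = init_params(N=7, hidden=5, fc_width=6, rng=rng)
        X = rng.normal(size=(3, 7, 12))
        probs = network_forward(X, params)
        assert probs.shape == (3, 7, 8)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert probs.min() >= 0

    def test_inference_deterministic(self, rng):
        params = init_params(N=6, hidden=4, fc_width=5, rng=rng)
        X = rng.normal(size=(2, 6, 11))
        a = network_forward(X, params, training=False)
        b = network_forward(X, params, training=False)
        assert np.array_equal(a, b)

    def test_dropout_zero_training_equals_inference(self, rng):
        params = init_params(N=6, hidden=4, fc_width=5, dropout=0.0, rng=rng)
        X = rng.normal(size=(2, 6, 11))
        a = network_forward(X, params, training=True, rng=np.random.default_rng(0))
        b = network_forward(X, params, training=False)
        assert np.allclose(a, b)

    def test_dropout_active_only_in_training(self, rng):
        params = init_params(N=6, hidden=4, fc_width=5, dropout=0.5, rng=rng)
        X = rng.normal(size=(2, 6, 11))
        _, cache_train = network_forward_cached(
            X, params, training=True, rng=np.random.default_rng(0)
        )
        _, cache_infer = network_forward_cached(X, params, training=False)
        assert cache_train["mask"] is not None
        assert cache_infer["mask"] is None


def test_softmax_numerical_stability():
    out = softmax(np.array([1000.0, 1000.0, -1000.0]))
    assert np.allclose(out[:2], 0.5)
    assert np.isfinite(out).all()
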