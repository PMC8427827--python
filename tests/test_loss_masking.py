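"""Flag-masked and class-weighted cross-entropy mechanics."""

import math

import numpy as np
import pytest

from rnagru.loss_masking import (
    batch_loss,
    batch_loss_logit_grad,
    make_flag,
    make_weight,
    per_base_loss,
    sequence_cross_entropy,
    weighted_cross_entropy,
)
from rnagru.model_core import softmax


def random_instance(rng, B=3, N=8, C=5):
    """Random simplex predictions, one-hot labels and masks."""
    logits = rng.normal(size=(B, N, C))
    preds = softmax(logits)
    labels = np.zeros((B, N, C))
    lengths = rng.integers(1, N + 1, size=B)
    flags = np.zeros((B, N))
    weights = np.zeros((B, N))
    for b, n in enumerate(lengths):
        classes = rng.integers(0, C, size=n)
        labels[b, np.arange(n), classes] = 1.0
        flags[b] = make_flag(int(n), N)
        weights[b] = make_weight(labels[b], int(n))
    return logits, preds, labels, flags, weights, lengths


class TestFlag:
    def test_ones_then_zeros(self):
        assert make_flag(3, 5).tolist() == [1, 1, 1, 0, 0]

    def test_full_length(self):
        assert make_flag(5, 5).tolist() == [1] * 5

    def test_single_position(self):
        assert make_flag(1, 4).tolist() == [1, 0, 0, 0]

    def test_n_greater_than_N_rejected(self):
        with pytest.raises(ValueError):
            make_flag(6, 5)


class TestWeight:
    def test_unpaired_count_upweights_paired(self):
        # partners (0, 4, 0, 2): two unpaired bases, so paired bases weigh 2
        labels = np.zeros((4, 5))
        for i, c in enumerate([0, 4, 0, 2]):
            labels[i, c] = 1.0
        assert make_weight(labels, 4).tolist() == [1, 2, 1, 2]

    def test_all_unpaired(self):
        labels = np.zeros((3, 4))
        labels[:, 0] = 1.0
        assert make_weight(labels, 3).tolist() == [1, 1, 1]

    def test_all_paired_floored_at_one(self):
        labels = np.zeros((4, 5))
        for i, c in enumerate([2, 1, 4, 3]):
            labels[i, c] = 1.0
        assert make_weight(labels, 4).tolist() == [1, 1, 1, 1]

    def test_padding_weights_zero(self):
        labels = np.zeros((5, 6))
        labels[:3, 0] = 1.0
        assert make_weight(labels, 3).tolist()[3:] == [0, 0]


class TestSequenceCrossEntropy:
    def test_uniform_predictions_log4(self):
        # n=2, N=3, uniform over 4 classes: (ln4 + ln4)/2 = ln4
        preds = np.full((3, 4), 0.25)
        labels = np.zeros((3, 4))
        labels[0, 0] = labels[1, 0] = 1.0
        flag = make_flag(2, 3)
        assert sequence_cross_entropy(preds, labels, flag) == pytest.approx(math.log(4))

    def test_perfect_predictions_near_zero(self):
        labels = np.zeros((2, 3))
        labels[0, 1] = labels[1, 0] = 1.0
        loss = sequence_cross_entropy(labels.copy(), labels, make_flag(2, 2))
        assert 0 <= loss <= 1e-11

    def test_padding_garbage_is_inert(self, rng):
        n, N, C = 4, 4, 5
        preds = softmax(rng.normal(size=(n, C)))
        labels = np.zeros((n, C))
        labels[np.arange(n), rng.integers(0, C, n)] = 1.0
        base = sequence_cross_entropy(preds, labels, make_flag(n, N))
        for extra in (1, 3, 10):
            preds_pad = np.vstack([preds, rng.normal(size=(extra, C))])
            labels_pad = np.vstack([labels, np.zeros((extra, C))])
            padded = sequence_cross_entropy(preds_pad, labels_pad, make_flag(n, N + extra))
            assert padded == base  # exact, not approximate


class TestWeightedCrossEntropy:
    def test_unit_weights_reduce_to_flag_form(self, rng):
        _, preds, labels, flags, _, lengths = random_instance(rng, B=1)
        b0 = sequence_cross_entropy(preds[0], labels[0], flags[0])
        w = flags[0].copy()
        assert weighted_cross_entropy(preds[0], labels[0], flags[0], w) == pytest.approx(
            b0, abs=1e-15
        )

    def test_direct_weighted_mean(self):
        # per-base losses a,b,c,d with weights 1,2,1,2 -> (a+2b+c+2d)/6
        preds = np.array([[0.5, 0.5], [0.8, 0.2], [0.3, 0.7], [0.9, 0.1]])
        labels = np.eye(2)[[0, 0, 1, 1]].astype(float)
        losses = per_base_loss(preds, labels)
        flag = np.ones(4)
        weight = np.array([1.0, 2.0, 1.0, 2.0])
        expected = (losses[0] + 2 * losses[1] + losses[2] + 2 * losses[3]) / 6
        assert weighted_cross_entropy(preds, labels, flag, weight) == pytest.approx(expected)

    def test_weight_rescaling_invariance(self, rng):
        _, preds, labels, flags, weights, _ = random_instance(rng, B=1)
        a = weighted_cross_entropy(preds[0], labels[0], flags[0], weights[0])
        b = weighted_cross_entropy(preds[0], labels[0], flags[0], 7.3 * weights[0])
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_denominator_rejected(self):
        preds = np.full((2, 3), 1 / 3)
        with pytest.raises(ValueError):
            weighted_cross_entropy(preds, np.zeros((2, 3)), np.zeros(2), np.zeros(2))


class TestBatchLoss:
    def test_identical_sequences_equal_single(self, rng):
        _, preds, labels, flags, weights, _ = random_instance(rng, B=1)
        single = weighted_cross_entropy(preds[0], labels[0], flags[0], weights[0])
        stacked = batch_loss(
            np.repeat(preds, 4, 0), np.repeat(labels, 4, 0),
            np.repeat(flags, 4, 0), np.repeat(weights, 4, 0),
        )
        assert stacked == pytest.approx(single, rel=1e-14)

    def test_two_sequences_average(self, rng):
        _, preds, labels, flags, weights, _ = random_instance(rng, B=2)
        a = weighted_cross_entropy(preds[0], labels[0], flags[0], weights[0])
        b = weighted_cross_entropy(preds[1], labels[1], flags[1], weights[1])
        assert batch_loss(preds, labels, flags, weights) == pytest.approx((a + b) / 2)

    def test_matches_scalar_loop_oracle(self, rng):
        """Vectorized batch loss equals an explicit scalar triple loop."""
        worst = 0.0
        for _ in range(100):
            B, N, C = int(rng.integers(1, 5)), int(rng.integers(2, 7)), int(rng.integers(2, 6))
            _, preds, labels, flags, weights, _ = random_instance(rng, B, N, C)
            total = 0.0
            for b in range(B):
                num = den = 0.0
                for i in range(N):
                    li = 0.0
                    for c in range(C):
                        li -= labels[b, i, c] * math.log(max(preds[b, i, c], 1e-12))
                    num += flags[b, i] * weights[b, i] * li
                    den += flags[b, i] * weights[b, i]
                total += num / den
            expected = total / B
            worst = max(worst, abs(batch_loss(preds, labels, flags, weights) - expected))
        assert worst <= 1e-8

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            batch_loss(np.zeros((0, 3, 2)), np.zeros((0, 3, 2)),
                       np.zeros((0, 3)), np.zeros((0, 3)))


class TestGradient:
    def test_finite_difference_check(self, rng):
        """Analytic logit gradient vs central differences (rel err <= 1e-4)."""
        logits, _, labels, flags, weights, _ = random_instance(rng, B=2, N=5, C=4)
        _, grad = batch_loss_logit_grad(softmax(logits), labels, flags, weights)
        eps = 1e-6
        for _ in range(60):
            b = rng.integers(logits.shape[0])
            i = rng.integers(logits.shape[1])
            c = rng.integers(logits.shape[2])
            bumped = logits.copy()
            bumped[b, i, c] += eps
            up = batch_loss(softmax(bumped), labels, flags, weights)
            bumped[b, i, c] -= 2 * eps
            down = batch_loss(softmax(bumped), labels, flags, weights)
            fd = (up - down) / (2 * eps)
            denom = max(abs(fd), abs(grad[b, i, c]), 1e-6)
            assert abs(fd - grad[b, i, c]) / denom <= 1e-4
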