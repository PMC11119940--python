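"""Loss functions: the α weight law, focal degeneracies, gradients, and the
minority-recall mechanism on an imbalanced toy problem."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pestnet.experiments import linear_imbalance_experiment
from pestnet.losses import (balanced_focal_loss, class_weights, cross_entropy,
                            focal_loss)
from pestnet.nn import Tensor, log_softmax


def manual_cross_entropy(logits, labels):
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return -logp[np.arange(len(labels)), labels].mean()


# -- α weight law -------------------------------------------------------------

@pytest.mark.parametrize("counts,expected", [
    ([90, 10], [0.91, 0.99]),
    ([50, 50], [0.95, 0.95]),
    ([100], [0.9]),                 # f = 1 boundary
    ([0, 10], [1.0, 0.9]),          # absent class gets exactly 1
])
def test_class_weight_examples(counts, expected):
    assert np.allclose(class_weights(counts), expected, atol=1e-12)


@given(st.lists(st.integers(0, 10_000), min_size=2, max_size=50))
def test_class_weight_law_and_antimonotonicity(counts):
    if sum(counts) == 0:
        counts[0] = 1
    counts = np.array(counts)
    alpha = class_weights(counts)
    n = counts.sum()
    assert np.allclose(alpha, 1.0 - counts / n / 10.0, atol=1e-12)
    # strictly rarer class => strictly larger weight
    for i in range(len(counts)):
        for j in range(len(counts)):
            if counts[i] < counts[j]:
                assert alpha[i] > alpha[j]


def test_empty_histogram_rejected():
    with pytest.raises(ValueError):
        class_weights([0, 0, 0])


# -- focal loss ---------------------------------------------------------------

def test_gamma_zero_equals_cross_entropy(rng):
    logits = rng.normal(size=(16, 7)) * 3
    labels = rng.integers(0, 7, size=16)
    fl = focal_loss(Tensor(logits), labels, gamma=0.0).item()
    assert abs(fl - manual_cross_entropy(logits, labels)) < 1e-7
    assert abs(cross_entropy(Tensor(logits), labels).item() - fl) < 1e-12


def test_perfect_prediction_gives_zero_loss():
    probs = np.eye(3)[[0, 1, 2, 1]]
    for gamma in (0.0, 1.0, 2.0):
        # exact one-hot rows: p_t = 1, log(1) = 0, modulation 0
        assert focal_loss(probs, [0, 1, 2, 1], gamma=gamma,
                          from_logits=False).item() == 0.0


def test_single_sample_half_confidence():
    probs = np.array([[0.5, 0.5]])
    loss = focal_loss(probs, [0], gamma=2.0, from_logits=False).item()
    assert abs(loss - 0.25 * np.log(2.0)) < 1e-12


def test_focusing_suppresses_confident_samples():
    """(1 − p_t)^γ is non-increasing in γ and the loss non-increasing in p_t."""
    for p_t in (0.6, 0.9, 0.99):
        probs = np.array([[p_t, 1 - p_t]])
        losses = [focal_loss(probs, [0], gamma=g, from_logits=False).item()
                  for g in (0.0, 1.0, 2.0, 5.0)]
        assert all(a >= b for a, b in zip(losses, losses[1:]))
    by_pt = [focal_loss(np.array([[q, 1 - q]]), [0], gamma=2.0,
                        from_logits=False).item() for q in (0.3, 0.6, 0.9)]
    assert all(a > b for a, b in zip(by_pt, by_pt[1:]))


def test_negative_gamma_rejected(rng):
    with pytest.raises(ValueError):
        focal_loss(rng.normal(size=(2, 3)), [0, 1], gamma=-1.0)


def test_invalid_probability_rows_rejected():
    with pytest.raises(ValueError):
        focal_loss(np.array([[0.7, 0.7]]), [0], from_logits=False)


def test_gradient_matches_finite_difference(rng):
    logits = rng.normal(size=(4, 3))
    labels = np.array([0, 2, 1, 2])
    alpha = class_weights([5, 3, 2])
    t = Tensor(logits.copy(), requires_grad=True)
    focal_loss(t, labels, gamma=2.0, alpha=alpha).backward()
    eps = 1e-6
    for i in [(0, 0), (1, 2), (3, 1)]:
        up = logits.copy(); up[i] += eps
        dn = logits.copy(); dn[i] -= eps
        num = (focal_loss(Tensor(up), labels, gamma=2.0, alpha=alpha).item()
               - focal_loss(Tensor(dn), labels, gamma=2.0, alpha=alpha).item()
               ) / (2 * eps)
        assert abs(t.grad[i] - num) / max(abs(num), 1e-8) < 1e-4


# -- balanced focal loss ------------------------------------------------------

def test_uniform_histogram_is_pure_rescaling(rng):
    logits = rng.normal(size=(8, 4))
    labels = rng.integers(0, 4, size=8)
    c = 4
    bfl = balanced_focal_loss(Tensor(logits), labels, [25] * c, gamma=2.0).item()
    fl = focal_loss(Tensor(logits), labels, gamma=2.0).item()
    assert abs(bfl - (1 - 1 / (10 * c)) * fl) < 1e-12


def test_rare_class_sample_weighted_higher():
    probs = np.array([[0.5, 0.5]])
    rare = balanced_focal_loss(probs, [1], [99, 1], gamma=0.0,
                               from_logits=False).item()
    common = balanced_focal_loss(probs, [0], [99, 1], gamma=0.0,
                                 from_logits=False).item()
    base = -np.log(0.5)
    assert abs(rare - 0.999 * base) < 1e-12
    assert abs(common - 0.901 * base) < 1e-12
    assert rare > common


def test_gamma_zero_uniform_histogram_scales_cross_entropy(rng):
    logits = rng.normal(size=(6, 3))
    labels = rng.integers(0, 3, size=6)
    bfl = balanced_focal_loss(Tensor(logits), labels, [7, 7, 7], gamma=0.0).item()
    cel = cross_entropy(Tensor(logits), labels).item()
    assert abs(bfl - (1 - 1 / 30) * cel) < 1e-12


def test_label_outside_histogram_rejected(rng):
    with pytest.raises(ValueError):
        balanced_focal_loss(rng.normal(size=(1, 5)), [4], [10, 10])


def test_bfl_nonnegative_and_zero_iff_perfect(rng):
    logits = rng.normal(size=(10, 4))
    labels = rng.integers(0, 4, size=10)
    assert balanced_focal_loss(Tensor(logits), labels, [5, 5, 5, 5]).item() > 0
    perfect = np.eye(4)[labels]
    assert balanced_focal_loss(perfect, labels, [5, 5, 5, 5],
                               from_logits=False).item() == 0.0


# -- imbalance mechanism ------------------------------------------------------

def test_bfl_raises_minority_recall_over_cel():
    """On a 20:1 two-class Gaussian problem, a linear model trained with the
    balanced focal loss recalls the minority class at least as well as one
    trained with cross-entropy (mean over 10 paired seeds)."""
    bfl, cel = [], []
    for s in range(10):
        seed = 1000 * s
        bfl.append(linear_imbalance_experiment("bfl", seed)["minority_recall"])
        cel.append(linear_imbalance_experiment("cel", seed)["minority_recall"])
    assert np.mean(bfl) >= np.mean(cel)
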