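"""Classification losses: cross-entropy, focal loss, balanced focal loss.

Focal loss down-weights well-classified samples through the modulation
factor (1 - p_t)^γ, where p_t is the probability the model assigns to the
true class and γ >= 0 is the focusing parameter.  The balanced variant (BFL)
additionally weights each class by

    α_i = 1 - f_i / 10,      f_i = n_i / N,

derived from the training-set label histogram, so rarer classes (small f_i)
receive a strictly larger weight.  Note the α range is (0.9, 1.0]: the
scheme nudges, rather than inverts, the class distribution.

All losses accept either logits (default) or ready-made probability rows and
return a scalar ``Tensor`` (mean over the batch) through which gradients
flow to the model.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, log_softmax

__all__ = ["class_weights", "cross_entropy", "focal_loss", "balanced_focal_loss"]

_P_FLOOR = 1e-12  # floor on p_t before the log


def class_weights(counts) -> np.ndarray:
    """Per-class α weights from a label histogram: α_i = 1 − (n_i/N)/10.

    ``counts`` is the integer vector of per-class sample counts; N is its
    sum.  Classes absent from the histogram (n_i = 0) get exactly α = 1;
    a class holding every sample gets α = 0.9.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or np.any(counts < 0):
        raise ValueError("counts must be a nonnegative 1-D vector")
    total = counts.sum()
    if total < 1:
        raise ValueError("histogram must contain at least one sample")
    freq = counts / total
    return 1.0 - freq / 10.0


def _true_class_terms(preds, labels, from_logits):
    """Return (log p_t, p_t) tensors for the true class of each sample."""
    preds = Tensor.as_tensor(preds)
    labels = np.asarray(labels)
    if preds.ndim != 2:
        raise ValueError("predictions must be a [batch, classes] matrix")
    b, c = preds.shape
    if labels.shape != (b,):
        raise ValueError("labels must be a vector matching the batch size")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    rows = np.arange(b)
    if from_logits:
        logp = log_softmax(preds, axis=1)
        logp_t = logp[rows, labels]
        p_t = logp_t.exp()
    else:
        row_sums = preds.data.sum(axis=1)
        if np.abs(row_sums - 1.0).max() > 1e-5:
            raise ValueError("probability rows must sum to 1")
        p_t = preds[rows, labels].clip(lo=_P_FLOOR)
        logp_t = p_t.log()
    return logp_t, p_t, labels


def focal_loss(preds, labels, gamma: float = 2.0, alpha=None,
               from_logits: bool = True) -> Tensor:
    """Mean focal loss  −α_y (1 − p_t)^γ log p_t  over a batch.

    ``alpha`` is an optional per-class weight vector (e.g. from
    :func:`class_weights`); when None the α term is omitted.  γ = 0 with no
    α recovers plain cross-entropy.
    """
    if gamma < 0:
        raise ValueError("focusing parameter gamma must be >= 0")
    logp_t, p_t, labels = _true_class_terms(preds, labels, from_logits)
    loss = -logp_t
    if gamma > 0:
        loss = loss * (1.0 - p_t).clip(lo=0.0) ** float(gamma)
    if alpha is not None:
        alpha = np.asarray(alpha, dtype=np.float64)
        if labels.max() >= alpha.shape[0]:
            raise ValueError("class index outside the weight vector")
        loss = loss * Tensor(alpha[labels])
    return loss.mean()


def cross_entropy(preds, labels, from_logits: bool = True) -> Tensor:
    """Mean categorical cross-entropy (focal loss with γ = 0, no α)."""
    return focal_loss(preds, labels, gamma=0.0, alpha=None, from_logits=from_logits)


def balanced_focal_loss(preds, labels, counts, gamma: float = 2.0,
                        from_logits: bool = True) -> Tensor:
    """Focal loss with histogram-derived α weights (α_i = 1 − f_i/10).

    ``counts`` is the class histogram the weights are computed from —
    normally the whole training set's label counts (a per-batch histogram is
    possible but mostly yields α = 1 for absent classes, which neutralises
    the balancing at realistic batch sizes).
    """
    labels = np.asarray(labels)
    alpha = class_weights(counts)
    if labels.size and labels.max() >= alpha.shape[0]:
        raise ValueError("batch contains a class index outside the histogram")
    return focal_loss(preds, labels, gamma=gamma, alpha=alpha,
                      from_logits=from_logits)
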