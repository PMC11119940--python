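"""Small self-contained experiments probing the loss-imbalance mechanism.

The class-balanced focal loss claims to raise minority-class recall under a
skewed label distribution.  The probe here isolates that mechanism from the
image pipeline: a linear softmax model on 2-D Gaussian class-conditional
features with a 20:1 class imbalance, trained once per loss under identical
seed, data and optimisation budget, comparing minority-class recall.
"""

from __future__ import annotations

import numpy as np

from .losses import balanced_focal_loss, cross_entropy, focal_loss
from .metrics import compute_metrics, confusion
from .nn import Adam, Linear, softmax

__all__ = ["linear_imbalance_experiment", "minority_recall_comparison"]


def _gaussian_imbalanced(rng, n_major=200, n_minor=10, separation=2.0):
    x0 = rng.normal(0.0, 1.0, (n_major, 2))
    mu = separation / np.sqrt(2.0)
    x1 = rng.normal(0.0, 1.0, (n_minor, 2)) + mu
    x = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(n_major, dtype=int), np.ones(n_minor, dtype=int)])
    return x, y


def linear_imbalance_experiment(loss_name: str, seed: int, n_major: int = 200,
                                n_minor: int = 10, steps: int = 200,
                                lr: float = 0.05, gamma: float = 2.0) -> dict:
    """Train a linear classifier on the imbalanced Gaussian problem.

    Returns the test metric report fields plus per-class recall; the test
    set is balanced-by-construction large (1000 per class) so recall
    estimates are stable.
    """
    rng = np.random.default_rng(seed)
    x, y = _gaussian_imbalanced(rng, n_major, n_minor)
    counts = np.bincount(y, minlength=2)
    model = Linear(2, 2, rng=np.random.default_rng(seed + 1))

    opt = Adam(model.parameters(), lr=lr)
    for _ in range(steps):
        logits = model(_tensorize(x))
        if loss_name == "cel":
            loss = cross_entropy(logits, y)
        elif loss_name == "fl":
            loss = focal_loss(logits, y, gamma=gamma)
        elif loss_name == "bfl":
            loss = balanced_focal_loss(logits, y, counts, gamma=gamma)
        else:
            raise ValueError(f"unknown loss {loss_name!r}")
        opt.zero_grad()
        loss.backward()
        opt.step()

    xt, yt = _gaussian_imbalanced(rng, 1000, 1000)
    probs = softmax(model(_tensorize(xt)), axis=1).data
    pred = probs.argmax(axis=1)
    report = compute_metrics(confusion(pred, yt, 2))
    rec = report.per_class["recall"]
    return {"acc": report.acc, "minority_recall": float(rec[1]),
            "majority_recall": float(rec[0])}


def _tensorize(x):
    from .nn import Tensor
    return Tensor(x)


def minority_recall_comparison(n_seeds: int = 10, base_seed: int = 0,
                               **kwargs) -> dict:
    """Mean minority-class recall of BFL vs CEL over ``n_seeds`` paired runs."""
    bfl, cel = [], []
    for s in range(n_seeds):
        seed = base_seed + 1000 * s
        bfl.append(linear_imbalance_experiment("bfl", seed, **kwargs)["minority_recall"])
        cel.append(linear_imbalance_experiment("cel", seed, **kwargs)["minority_recall"])
    return {"bfl_mean_minority_recall": float(np.mean(bfl)),
            "cel_mean_minority_recall": float(np.mean(cel)),
            "per_seed_bfl": bfl, "per_seed_cel": cel}
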