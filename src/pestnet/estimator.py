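"""scikit-learn-style estimator wrapping the full pipeline.

``PestImageClassifier`` exposes the network + training protocol through the
familiar fit/predict surface so it composes with sklearn model selection and
pipelines.  ``X`` is an array of RGB images ``[n_samples, H, W, 3]`` (uint8
or floats in [0, 1]); ``y`` is a vector of class labels.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import DatasetManifest
from .network import NetworkConfig
from .train import TrainConfig, evaluate, predict_proba, train

__all__ = ["PestImageClassifier"]


class PestImageClassifier(ClassifierMixin, BaseEstimator):
    """Image classifier with relation-aware attention, multi-scale fusion
    and generalized-mean pooling, trained with a class-balanced focal loss.

    Parameters
    ----------
    backbone : {'tiny', 'resnet50'}
        Feature extractor; 'tiny' mirrors the residual geometry at CPU scale.
    input_size : int
        Side of the square crop the network consumes.
    rga_stages : tuple of int
        Backbone stages followed by a relation-aware attention block.
    use_msff : bool
        Fuse stages L2/L3/L4 adaptively (otherwise the head sees L4 only).
    pooling : {'gem', 'gap', 'gmp'}
        Generalized-mean (learnable exponent), global average, or global max.
    loss : {'bfl', 'fl', 'cel'}
        Balanced focal (histogram-derived α), focal, or cross-entropy.
    gamma : float
        Focusing parameter of the focal losses.
    lr, lr_decay, batch_size, max_epochs
        Adam learning rate, per-epoch exponential decay, batch size, epochs.
    validation_fraction : float
        Held-out fraction used for best-epoch selection (0 disables it).
    random_state : int
        Seed for initialisation, shuffling and crop offsets.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique labels seen in fit.
    model_ : PestNet
        The trained network.
    history_ : RunLog
        Per-epoch loss / learning-rate / validation records.
    """

    def __init__(self, backbone="tiny", input_size=64, rga_stages=(2, 3),
                 use_msff=True, pooling="gem", loss="bfl", gamma=2.0,
                 lr=1e-4, lr_decay=0.96, batch_size=32, max_epochs=10,
                 validation_fraction=0.0, random_state=0):
        self.backbone = backbone
        self.input_size = input_size
        self.rga_stages = rga_stages
        self.use_msff = use_msff
        self.pooling = pooling
        self.loss = loss
        self.gamma = gamma
        self.lr = lr
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _manifest(self, X, y=None) -> DatasetManifest:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be [n_samples, H, W, 3] RGB images")
        labels = (np.zeros(len(X), dtype=int) if y is None
                  else np.searchsorted(self.classes_, y))
        return DatasetManifest([(img, int(lab)) for img, lab in zip(X, labels)])

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        net_cfg = NetworkConfig(
            num_classes=len(self.classes_), backbone=self.backbone,
            input_size=self.input_size, rga_stages=tuple(self.rga_stages),
            use_msff=self.use_msff, pooling=self.pooling,
        )
        cfg = TrainConfig(
            lr=self.lr, lr_decay=self.lr_decay, batch_size=self.batch_size,
            max_epochs=self.max_epochs, crop_size=self.input_size,
            seed=self.random_state, loss_name=self.loss, gamma=self.gamma,
            model=net_cfg,
        )
        manifest = self._manifest(X, y)
        val = None
        if self.validation_fraction > 0:
            rng = np.random.default_rng(self.random_state)
            n_val = max(1, int(round(self.validation_fraction * len(manifest))))
            order = rng.permutation(len(manifest))
            val = manifest.subset(order[:n_val])
            manifest = manifest.subset(order[n_val:])
        self.model_, self.history_ = train(cfg, manifest, val)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return predict_proba(self.model_, self._manifest(X),
                             batch_size=self.batch_size,
                             crop_size=self.input_size)

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def evaluate_report(self, X, y):
        """Full imbalance-aware metric report (Acc/MPre/MRec/MF1/GM)."""
        check_is_fitted(self, "model_")
        return evaluate(self.model_, self._manifest(X, y),
                        batch_size=self.batch_size, crop_size=self.input_size)
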