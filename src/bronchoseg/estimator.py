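"""scikit-learn-style estimator wrapping the multi-task network.

:class:`LesionNet` exposes the joint segmentation + malignancy model with
the familiar ``fit`` / ``predict`` / ``predict_proba`` / ``score`` surface
and ``get_params`` / ``set_params`` for model selection.  Because the
supervision is structured (a pixel mask *and* an image label per frame),
``fit`` takes ``y`` as a ``(masks, labels)`` pair — a dict with keys
``"masks"`` / ``"labels"`` is also accepted.  ``predict`` returns the
malignancy labels; pixel masks come from :meth:`predict_mask`.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator

from .decoder import DecoderConfig
from .encoder import EncoderConfig
from .losses import LossWeights
from .model import ModelConfig
from .train import TrainConfig, evaluate, train
from .synthetic import ImageSample

__all__ = ["LesionNet"]


def _unpack_y(y):
    if isinstance(y, dict):
        return np.asarray(y["masks"]), np.asarray(y["labels"])
    masks, labels = y
    return np.asarray(masks), np.asarray(labels)


class LesionNet(BaseEstimator):
    """Joint bronchoscopic lesion segmenter and malignancy classifier.

    Parameters mirror the model and optimization configuration; all are
    plain values so the estimator clones cleanly.  Fitted state lives in
    trailing-underscore attributes (``model_``, ``history_``, ``classes_``).
    """

    def __init__(self, base_channels: int = 16, adapter_compression: int = 4,
                 mask_ratio: float = 0.25, adapters_enabled: bool = True,
                 n_tokens: int = 1, threshold: float = 0.5,
                 learning_rate: float = 2e-4, max_epochs: int = 100,
                 max_steps: int | None = None, patience: int = 10,
                 lambda_bce: float = 1.0, lambda_iou: float = 2.0,
                 lambda_seg: float = 1.0, lambda_cls: float = 1.8,
                 augment_prob: float = 0.0, validation_fraction: float = 0.0,
                 seed: int = 0):
        self.base_channels = base_channels
        self.adapter_compression = adapter_compression
        self.mask_ratio = mask_ratio
        self.adapters_enabled = adapters_enabled
        self.n_tokens = n_tokens
        self.threshold = threshold
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.max_steps = max_steps
        self.patience = patience
        self.lambda_bce = lambda_bce
        self.lambda_iou = lambda_iou
        self.lambda_seg = lambda_seg
        self.lambda_cls = lambda_cls
        self.augment_prob = augment_prob
        self.validation_fraction = validation_fraction
        self.seed = seed

    # ----------------------------------------------------------- internals
    def _model_config(self, image_size) -> ModelConfig:
        return ModelConfig(
            image_size=tuple(image_size),
            encoder=EncoderConfig(base_channels=self.base_channels),
            adapter_compression=self.adapter_compression,
            adapters_enabled=self.adapters_enabled,
            mask_ratio=self.mask_ratio,
            decoder=DecoderConfig(n_tokens=self.n_tokens,
                                  threshold=self.threshold),
            seed=self.seed)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            max_steps=self.max_steps, patience=self.patience,
            loss_weights=LossWeights(bce=self.lambda_bce, iou=self.lambda_iou,
                                     seg=self.lambda_seg, cls=self.lambda_cls),
            augment_prob=self.augment_prob, seed=self.seed)

    @staticmethod
    def _to_samples(X, masks, labels):
        return [ImageSample(image=np.asarray(img, dtype=np.float64),
                            mask=np.asarray(msk).astype(np.uint8),
                            label=int(lab), sample_id=f"fit_{i:05d}", seed=0)
                for i, (img, msk, lab) in enumerate(zip(X, masks, labels))]

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    # ------------------------------------------------------------- sklearn
    def fit(self, X, y):
        """X: (n, H, W, 3) images in [0,1]; y: (masks (n,H,W), labels (n,))."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be an (n, H, W, 3) image stack")
        masks, labels = _unpack_y(y)
        if len(X) != len(masks) or len(X) != len(labels):
            raise ValueError("X, masks and labels must have equal length")
        samples = self._to_samples(X, masks, labels)
        val = None
        if self.validation_fraction > 0:
            from .synthetic import split_dataset
            tr_frac = 1.0 - self.validation_fraction
            try:
                samples, val, _ = split_dataset(
                    samples, (tr_frac, self.validation_fraction, 0.0),
                    seed=self.seed)
            except ValueError:  # single-class y: unstratifiable, hold out tail
                n_val = max(1, int(round(self.validation_fraction * len(samples))))
                samples, val = samples[:-n_val], samples[-n_val:]
        result = train(self._model_config(X.shape[1:3]), samples, val,
                       self._train_config())
        self.model_ = result.model
        self.history_ = result.history
        self.n_steps_ = result.steps
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return np.array([self.model_.predict(img).predicted_label for img in X])

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        p1 = np.array([self.model_.predict(img).class_prob for img in X])
        return np.stack([1.0 - p1, p1], axis=1)

    def predict_mask(self, X) -> np.ndarray:
        """Binary lesion masks (n, H, W)."""
        self._check_fitted()
        return np.stack([self.model_.predict(img).binary_mask for img in X])

    def score(self, X, y) -> float:
        """Mean Dice (class-averaged, per-image) of predicted masks."""
        from .metrics import segmentation_metrics
        self._check_fitted()
        masks, _ = _unpack_y(y)
        return segmentation_metrics(list(self.predict_mask(X)),
                                    [np.asarray(m) for m in masks])["mDice"]

    def evaluate(self, samples) -> dict:
        self._check_fitted()
        return evaluate(self.model_, samples)
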