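"""Scikit-learn-style estimator wrapping the full detector.

``RotatedEllipseDetector`` exposes the train/predict cycle through the
familiar ``fit`` / ``predict`` interface so the detector composes with
sklearn model selection: ``X`` is an ``(n, H, W)`` stack of grayscale
images (uint8 or floats in [0, 1]), ``y`` a sequence of
:class:`~fetalhc.encoding.Annotation`.  Fitted state lives in
trailing-underscore attributes (``model_``, ``history_``,
``n_parameters_``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .encoding import Annotation
from .inference import DEFAULT_SCORE_THRESHOLD, ScoredEllipse, decode_detections
from .geometry import head_circumference
from .losses import LossConfig
from .network import EllipseNet, ModelConfig
from .phantom import PhantomSample
from .ssr import SSRConfig
from .train import TrainConfig, train_model

__all__ = ["RotatedEllipseDetector"]


class RotatedEllipseDetector(BaseEstimator):
    """One-stage anchor-free rotated-ellipse detector for fetal HC.

    Parameters mirror the model, loss and optimizer configurations; see
    :class:`~fetalhc.network.ModelConfig`, :class:`~fetalhc.losses.LossConfig`
    and :class:`~fetalhc.train.TrainConfig` for semantics.
    """

    def __init__(self, input_size=(96, 96), base_channels=24, use_mhsa=True,
                 use_deformable=False, dropout=0.1, stages=(18, 10, 10),
                 use_ssr=True, use_kld=True, include_axes_in_total=True,
                 circular_angle=True, epochs=10, batch_size=4, optimizer="adam",
                 lr=None, momentum=0.9, weight_decay=1e-4,
                 score_threshold=DEFAULT_SCORE_THRESHOLD, max_peaks=1, seed=0):
        self.input_size = input_size
        self.base_channels = base_channels
        self.use_mhsa = use_mhsa
        self.use_deformable = use_deformable
        self.dropout = dropout
        self.stages = stages
        self.use_ssr = use_ssr
        self.use_kld = use_kld
        self.include_axes_in_total = include_axes_in_total
        self.circular_angle = circular_angle
        self.epochs = epochs
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.score_threshold = score_threshold
        self.max_peaks = max_peaks
        self.seed = seed

    # -- configuration assembly -----------------------------------------
    def _configs(self):
        model_cfg = ModelConfig(input_size=tuple(self.input_size),
                                base_channels=self.base_channels,
                                use_mhsa=self.use_mhsa,
                                use_deformable=self.use_deformable,
                                dropout=self.dropout, seed=self.seed)
        ssr_cfg = SSRConfig(stages=tuple(self.stages))
        loss_cfg = LossConfig(use_ssr=self.use_ssr, use_kld=self.use_kld,
                              include_axes_in_total=self.include_axes_in_total,
                              circular_angle=self.circular_angle)
        train_cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                                optimizer=self.optimizer, lr=self.lr,
                                momentum=self.momentum,
                                weight_decay=self.weight_decay, seed=self.seed)
        return model_cfg, ssr_cfg, loss_cfg, train_cfg

    @staticmethod
    def _as_samples(X, y) -> list[PhantomSample]:
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError(f"X must be (n, H, W), got shape {X.shape}")
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        imgs = X if X.dtype == np.uint8 else np.clip(X * 255.0, 0, 255).astype(np.uint8)
        samples = []
        for i, (img, ann) in enumerate(zip(imgs, y)):
            if not isinstance(ann, Annotation):
                raise TypeError("y must contain Annotation objects")
            samples.append(PhantomSample(image=img, annotation=ann, seed=i))
        return samples

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y):
        """Train the detector on images ``X`` with annotations ``y``."""
        model_cfg, ssr_cfg, loss_cfg, train_cfg = self._configs()
        samples = self._as_samples(X, y)
        self.model_ = EllipseNet(model_cfg, ssr_cfg)
        self.n_parameters_ = self.model_.count_parameters()
        self.history_ = train_model(self.model_, samples, train_cfg, loss_cfg)
        return self

    def predict(self, X, pixel_sizes_mm=None) -> list[ScoredEllipse | None]:
        """Best detection per image (None where nothing clears the threshold).

        With ``pixel_sizes_mm`` given (scalar or per-image), detections
        carry head circumference in mm.
        """
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the estimator (or load a checkpoint) before predicting")
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        imgs = X.astype(np.float32)
        if imgs.max() > 1.5:
            imgs = imgs / 255.0
        if pixel_sizes_mm is not None:
            pixel_sizes_mm = np.broadcast_to(np.asarray(pixel_sizes_mm, dtype=float), (len(X),))
        self.model_.eval()
        results: list[ScoredEllipse | None] = []
        # batch in chunks to bound memory
        chunk = 16
        for start in range(0, len(imgs), chunk):
            out = self.model_.forward(imgs[start : start + chunk, None])
            for j in range(out.heatmap.shape[0]):
                dets = decode_detections(out, self.model_.ssr_cfg,
                                         stride=self.model_.cfg.stride,
                                         threshold=self.score_threshold,
                                         max_peaks=self.max_peaks, image_index=j)
                if not dets:
                    results.append(None)
                    continue
                best = dets[0]
                if pixel_sizes_mm is not None:
                    px = float(pixel_sizes_mm[start + j])
                    e = best.ellipse
                    best = ScoredEllipse(ellipse=e, score=best.score,
                                         hc_mm=head_circumference(e.a * px, e.b * px))
                results.append(best)
        return results

    def score(self, X, y) -> float:
        """Detection rate: fraction of positive images with a detection."""
        preds = self.predict(X)
        pos = [(p, ann) for p, ann in zip(preds, y) if not ann.is_negative]
        if not pos:
            return 0.0
        return float(np.mean([p is not None for p, _ in pos]))
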