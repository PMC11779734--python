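"""Scikit-learn-style estimator facades over the library layer.

``DfmaSegmenter`` wraps network construction + training (``fit``) and mask
prediction (``predict``); ``SeedlingMeasurer`` wraps coin calibration
(``fit``) and per-seedling length extraction (``transform``).  Both follow
the sklearn conventions (``get_params``/``set_params``, fitted attributes
with a trailing underscore), so they compose with sklearn model-selection
tooling where that is meaningful.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io_datasets import DEFAULT_SCHEME, ImageSample
from .measure import calibrate, detect_coin, measure_seedlings
from .network import DfmaNet, ModelConfig, predict_mask
from .train import AugmentConfig, TrainConfig, confusion, miou, train


class DfmaSegmenter(BaseEstimator):
    """Four-class seedling segmentation (background / shoot / root / seed).

    Parameters
    ----------
    width_mult : float
        Channel-width multiplier; 1.0 is the full architecture, smaller
        values give CPU-friendly variants.
    max_epochs, patience, lr_init, lr_end, batch_size, optimizer : training
        schedule knobs (cosine decay, early stopping on validation loss).
    val_fraction : float
        Fraction of ``fit`` samples held out for early stopping when no
        explicit validation set is passed.
    augment : bool
        Online train-time augmentation (flips/rotations/HSV jitter).
    seed : int
        Seeds weight initialization, shuffling, and augmentation draws.
    """

    def __init__(self, width_mult: float = 0.25, max_epochs: int = 30,
                 patience: int = 10, lr_init: float = 0.005, lr_end: float = 1e-4,
                 batch_size: int = 8, optimizer: str = "sgd",
                 val_fraction: float = 0.2, augment: bool = False, seed: int = 0):
        self.width_mult = width_mult
        self.max_epochs = max_epochs
        self.patience = patience
        self.lr_init = lr_init
        self.lr_end = lr_end
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.val_fraction = val_fraction
        self.augment = augment
        self.seed = seed

    def _samples(self, X, y):
        if y is None:
            raise ValueError("fit requires label masks")
        return [ImageSample(image=np.asarray(img), mask=np.asarray(m), id=str(i))
                for i, (img, m) in enumerate(zip(X, y))]

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on lists of HxWx3 images and HxW label masks."""
        samples = self._samples(X, y)
        if X_val is not None:
            tr, va = samples, self._samples(X_val, y_val)
        else:
            n_val = max(1, int(round(self.val_fraction * len(samples))))
            if len(samples) - n_val < 1:
                raise ValueError("too few samples to hold out a validation set")
            va, tr = samples[:n_val], samples[n_val:]
        cfg = (ModelConfig() if self.width_mult >= 1.0
               else ModelConfig.reduced(self.width_mult))
        self.model_ = DfmaNet(cfg, rng=np.random.default_rng(self.seed))
        tc = TrainConfig(lr_init=self.lr_init, lr_end=self.lr_end,
                         batch_size=self.batch_size, max_epochs=self.max_epochs,
                         patience=self.patience, optimizer=self.optimizer,
                         seed=self.seed)
        aug = AugmentConfig(enable_scale=False, enable_crop=False) if self.augment else None
        self.history_ = train(self.model_, tr, va, tc, aug)
        self.classes_ = np.arange(cfg.num_classes)
        return self

    def predict(self, X):
        """Label masks for a list of images (argmax of the logits)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the segmenter before predicting")
        return [predict_mask(self.model_, np.asarray(img)) for img in X]

    def score(self, X, y):
        """Mean IoU over the pooled pixel confusion matrix."""
        k = self.model_.cfg.num_classes
        cm = None
        for pred, truth in zip(self.predict(X), y):
            c = confusion(pred, np.asarray(truth), k)
            cm = c if cm is None else cm + c
        return miou(cm)


class SeedlingMeasurer(BaseEstimator):
    """Mask -> per-seedling shoot/root lengths in mm, via coin calibration.

    ``fit(image)`` locates the reference coin (Hough-gradient voting) and
    stores the mm-per-pixel scale; ``transform(masks)`` measures each mask
    and returns one DataFrame per mask (or a single DataFrame for a single
    mask).
    """

    def __init__(self, coin_diameter_mm: float = 25.0, r_min: int = 10,
                 r_max: int = 200, method: str = "geodesic"):
        self.coin_diameter_mm = coin_diameter_mm
        self.r_min = r_min
        self.r_max = r_max
        self.method = method

    def fit(self, X, y=None):
        """Detect the coin on an image (or use a known mm-per-pixel float)."""
        if np.isscalar(X):
            self.mm_per_pixel_ = float(X)
            self.coin_ = None
        else:
            self.coin_ = detect_coin(np.asarray(X), self.r_min, self.r_max)
            self.calibration_ = calibrate(self.coin_, self.coin_diameter_mm)
            self.mm_per_pixel_ = self.calibration_.mm_per_pixel
        return self

    def transform(self, X) -> pd.DataFrame | list[pd.DataFrame]:
        if not hasattr(self, "mm_per_pixel_"):
            raise RuntimeError("fit the measurer (coin calibration) first")
        from .measure import Calibration
        cal = getattr(self, "calibration_", None) or Calibration(
            self.mm_per_pixel_, self.coin_diameter_mm,
            self.coin_diameter_mm / self.mm_per_pixel_)
        single = isinstance(X, np.ndarray) and X.ndim == 2
        masks = [X] if single else list(X)
        frames = []
        for mask in masks:
            rows = [vars(m) for m in measure_seedlings(
                np.asarray(mask), cal, DEFAULT_SCHEME, method=self.method)]
            df = pd.DataFrame(rows, columns=["instance_id", "shoot_px", "shoot_mm",
                                             "root_px", "root_mm", "seed_present"])
            df["mm_per_pixel"] = cal.mm_per_pixel
            frames.append(df)
        return frames[0] if single else frames

    def fit_transform(self, X, y=None, masks=None):
        return self.fit(X).transform(masks)
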