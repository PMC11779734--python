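"""Training loop, online augmentation, loss, and segmentation metrics.

Metrics follow the usual pixel confusion-matrix reductions: per-class
IoU = TP / (TP + FP + FN) averaged over the classes present (mIoU),
precision = TP / (TP + FP), recall = TP / (TP + FN), and accuracy =
(TP + TN) / total, all derived one-vs-rest from a (k x k) count table with
rows = truth and columns = prediction.

The objective is cross-entropy plus soft Dice (unit weights).  Training
uses SGD with momentum and a cosine learning-rate decay, stopping early
when the validation loss has not improved for ``patience`` epochs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.color import hsv2rgb, rgb2hsv

from .io_datasets import DEFAULT_SCHEME, ImageSample
from .network import DfmaNet, _prepare_image
from .nn import SGD, Adam, Tensor, cosine_lr
from .nn import functional as F

logger = logging.getLogger(__name__)


# -- confusion matrix and metrics -----------------------------------------

@dataclass
class ConfusionMatrix:
    """Pixel count table; ``counts[t, p]`` = pixels with truth t predicted p."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class i."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = int(self.counts.sum() - tp - fp - fn)
        return tp, fp, fn, tn


def confusion(pred: np.ndarray, truth: np.ndarray, num_classes: int) -> ConfusionMatrix:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have the same shape")
    for arr, name in ((pred, "prediction"), (truth, "truth")):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValueError(f"{name} contains labels outside 0..{num_classes - 1}")
    idx = truth.ravel().astype(np.int64) * num_classes + pred.ravel().astype(np.int64)
    counts = np.bincount(idx, minlength=num_classes * num_classes)
    return ConfusionMatrix(counts.reshape(num_classes, num_classes))


def miou(cm: ConfusionMatrix) -> float:
    """Mean IoU over classes; classes absent from truth AND prediction are
    excluded from the mean (they contribute no pixels)."""
    ious = []
    for i in range(cm.num_classes):
        tp, fp, fn, _ = cm.one_vs_rest(i)
        if tp + fp + fn == 0:
            logger.debug("class %d absent from truth and prediction; excluded", i)
            continue
        ious.append(tp / (tp + fp + fn))
    if not ious:
        raise ValueError("mIoU undefined: every class is empty")
    return float(np.mean(ious))


def precision_recall_accuracy(cm: ConfusionMatrix, class_index: int
                              ) -> tuple[float, float, float]:
    """(precision, recall, accuracy) for one class; undefined ratios are NaN."""
    tp, fp, fn, tn = cm.one_vs_rest(class_index)
    pre = tp / (tp + fp) if tp + fp > 0 else float("nan")
    rec = tp / (tp + fn) if tp + fn > 0 else float("nan")
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total > 0 else float("nan")
    return pre, rec, acc


# -- loss ------------------------------------------------------------------

def segmentation_loss(logits: Tensor, truth: np.ndarray, eps: float = 1.0) -> Tensor:
    """Cross-entropy + soft Dice (averaged over classes present in truth)."""
    B, K, H, W = logits.shape
    truth = np.asarray(truth)
    onehot = np.zeros((B, K, H, W), dtype=logits.data.dtype)
    b, h, w = np.meshgrid(np.arange(B), np.arange(H), np.arange(W), indexing="ij")
    onehot[b, truth, h, w] = 1.0
    y = Tensor(onehot)

    lp = F.log_softmax(logits, axis=1)
    ce = -(lp * y).sum(axis=1).mean()

    p = F.softmax(logits, axis=1)
    inter = (p * y).sum(axis=(0, 2, 3))
    psum = p.sum(axis=(0, 2, 3))
    ysum = onehot.sum(axis=(0, 2, 3))
    dice = (2.0 * inter + eps) / (psum + Tensor(ysum) + eps)
    present = (ysum > 0).astype(logits.data.dtype)
    mean_dice = (dice * Tensor(present)).sum() * (1.0 / max(present.sum(), 1.0))
    return ce + (1.0 - mean_dice)


# -- augmentation ----------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    scale_range: tuple[float, float] = (0.25, 2.0)
    aspect_jitter: float = 0.2
    flip_prob: float = 0.5
    pad_value: int = 128
    hsv_jitter: tuple[float, float, float] = (0.05, 0.3, 0.3)
    rotations: tuple[int, ...] = (90, 180, 270)
    enable_scale: bool = True
    enable_flip: bool = True
    enable_hsv: bool = True
    enable_rotate: bool = True
    enable_crop: bool = True
    crop_size: tuple[int, int] | None = None  # default: original size

    def __post_init__(self):
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale range must be positive and ordered")
        if not 0 <= self.pad_value <= 255:
            raise ValueError("pad value must be a uint8 intensity")
        if any(r not in (90, 180, 270) for r in self.rotations):
            raise ValueError("rotations must be multiples of 90 degrees")


def augment(sample: ImageSample, cfg: AugmentConfig,
            rng: np.random.Generator) -> ImageSample:
    """Apply one random augmentation draw; geometry acts identically on the
    image and the mask (nearest-neighbour), photometry on the image only."""
    if sample.mask is None:
        raise ValueError("augmentation requires a sample with a mask")
    img = sample.image.copy()
    mask = sample.mask.copy()
    out_h, out_w = cfg.crop_size if cfg.crop_size else mask.shape

    if cfg.enable_rotate and cfg.rotations and rng.random() < 0.5:
        k = int(rng.choice([r // 90 for r in cfg.rotations]))
        img = np.rot90(img, k=k, axes=(0, 1)).copy()
        mask = np.rot90(mask, k=k).copy()

    if cfg.enable_flip and rng.random() < cfg.flip_prob:
        img = img[:, ::-1].copy()
        mask = mask[:, ::-1].copy()

    if cfg.enable_scale:
        s = rng.uniform(*cfg.scale_range)
        ar = 1.0 + rng.uniform(-cfg.aspect_jitter, cfg.aspect_jitter)
        sy, sx = s * ar, s / ar
        img = ndi.zoom(img, (sy, sx, 1.0), order=1)
        mask = ndi.zoom(mask, (sy, sx), order=0)

    if cfg.enable_crop or img.shape[:2] != (out_h, out_w):
        img, mask = _crop_or_pad(img, mask, out_h, out_w, cfg.pad_value, rng)

    if cfg.enable_hsv:
        dh, ds, dv = cfg.hsv_jitter
        hsv = rgb2hsv(img.astype(np.float64) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-dh, dh)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-ds, ds)), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-dv, dv)), 0, 1)
        img = (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)

    return ImageSample(image=img, mask=mask, id=sample.id, truth=sample.truth)


def _crop_or_pad(img, mask, out_h, out_w, pad_value, rng):
    """Random placement: pad with gray (mask: background) or crop randomly."""
    h, w = mask.shape
    canvas_img = np.full((max(h, out_h), max(w, out_w), 3), pad_value, dtype=img.dtype)
    canvas_mask = np.zeros((max(h, out_h), max(w, out_w)), dtype=mask.dtype)
    oy = rng.integers(0, canvas_mask.shape[0] - h + 1)
    ox = rng.integers(0, canvas_mask.shape[1] - w + 1)
    canvas_img[oy:oy + h, ox:ox + w] = img
    canvas_mask[oy:oy + h, ox:ox + w] = mask
    cy = rng.integers(0, canvas_mask.shape[0] - out_h + 1)
    cx = rng.integers(0, canvas_mask.shape[1] - out_w + 1)
    return (canvas_img[cy:cy + out_h, cx:cx + out_w],
            canvas_mask[cy:cy + out_h, cx:cx + out_w])


# -- training loop ---------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 0.005
    lr_end: float = 0.0001
    momentum: float = 0.937
    batch_size: int = 8
    schedule: str = "cosine"
    max_epochs: int = 500
    patience: int = 20
    optimizer: str = "sgd"
    weight_decay: float = 5e-4
    seed: int = 0

    def __post_init__(self):
        if self.lr_end >= self.lr_init:
            raise ValueError("lr_end must be below lr_init")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("need 0 < patience < max_epochs")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


class EarlyStopper:
    """Stop when the monitored loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record one epoch; returns True when the value improved."""
        if value < self.best:
            self.best = value
            self.best_epoch = epoch
            self.stale = 0
            return True
        self.stale += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.stale >= self.patience


def early_stop_epoch(trace, patience: int) -> int:
    """Number of epochs a run following ``trace`` would execute (rule simulation)."""
    stopper = EarlyStopper(patience)
    for e, v in enumerate(trace, start=1):
        stopper.update(float(v), e)
        if stopper.should_stop:
            return e
    return len(trace)


def evaluate(model: DfmaNet, samples, batch_size: int = 8) -> tuple[float, float]:
    """(mean loss, mIoU) of a model on a list of samples, in eval mode."""
    model.eval()
    total_loss, n = 0.0, 0
    cm = ConfusionMatrix(np.zeros((model.cfg.num_classes,) * 2, dtype=np.int64))
    for lo in range(0, len(samples), batch_size):
        batch = samples[lo:lo + batch_size]
        x = np.concatenate([_prepare_image(s.image) for s in batch])
        truth = np.stack([s.mask for s in batch])
        logits = model(Tensor(x))
        total_loss += segmentation_loss(logits, truth).item() * len(batch)
        n += len(batch)
        pred = np.argmax(logits.data, axis=1)
        cm = cm + confusion(pred, truth, model.cfg.num_classes)
    return total_loss / n, miou(cm)


def train(model: DfmaNet, train_samples, val_samples, cfg: TrainConfig = TrainConfig(),
          aug: AugmentConfig | None = None) -> dict:
    """Train in place; returns the history and restores the best-validation
    weights on the model.  Augmentation (when given) is train-only."""
    if not train_samples or not val_samples:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    if cfg.optimizer == "sgd":
        opt = SGD(params, cfg.lr_init, cfg.momentum, cfg.weight_decay)
    else:
        opt = Adam(params, cfg.lr_init, weight_decay=cfg.weight_decay)
    stopper = EarlyStopper(cfg.patience)
    history = {"train_loss": [], "val_loss": [], "val_miou": [], "lr": []}
    best_state = model.state_dict()

    for epoch in range(cfg.max_epochs):
        lr = cosine_lr(epoch, cfg.max_epochs, cfg.lr_init, cfg.lr_end) \
            if cfg.schedule == "cosine" else cfg.lr_init
        opt.lr = lr
        model.train()
        order = rng.permutation(len(train_samples))
        epoch_loss, seen = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            batch = [train_samples[i] for i in order[lo:lo + cfg.batch_size]]
            if aug is not None:
                batch = [augment(s, aug, rng) for s in batch]
            x = np.concatenate([_prepare_image(s.image) for s in batch])
            truth = np.stack([s.mask for s in batch])
            loss = segmentation_loss(model(Tensor(x)), truth)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
            seen += len(batch)
        val_loss, val_miou = evaluate(model, val_samples, cfg.batch_size)
        history["train_loss"].append(epoch_loss / seen)
        history["val_loss"].append(val_loss)
        history["val_miou"].append(val_miou)
        history["lr"].append(lr)
        if stopper.update(val_loss, epoch + 1):
            best_state = model.state_dict()
        logger.info("epoch %d lr %.5f train %.4f val %.4f miou %.4f",
                    epoch + 1, lr, epoch_loss / seen, val_loss, val_miou)
        if stopper.should_stop:
            break
    history["stopped_epoch"] = len(history["val_loss"])
    history["best_epoch"] = stopper.best_epoch
    model.load_state_dict(best_state)
    return history
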