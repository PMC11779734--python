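"""Data model, annotation I/O, and dataset splitting.

The segmentation task uses a fixed 4-class scheme (background, shoot, root,
seed).  Annotations arrive as Labelme-style JSON polygon files; they are
rasterized to integer label masks at native resolution, later polygons
overwriting earlier ones.  Masks round-trip through single-channel indexed
PNG with a frozen palette.
"""
from __future__ import annotations

import base64
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.draw import polygon as _draw_polygon


class SchemaError(ValueError):
    """An annotation file does not conform to the expected schema."""


@dataclass(frozen=True)
class ClassScheme:
    """Ordered label set; index 0 is always background."""

    names: tuple[str, ...] = ("background", "shoot", "root", "seed")

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("class names must be unique")
        if self.names[0] != "background":
            raise ValueError("class 0 must be background")

    @property
    def num_classes(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown class label {name!r}; "
                              f"expected one of {list(self.names)}") from None


DEFAULT_SCHEME = ClassScheme()

#: frozen palette for indexed mask PNGs: black, green, red, yellow
MASK_PALETTE = ((0, 0, 0), (0, 255, 0), (255, 0, 0), (255, 255, 0))


@dataclass
class ImageSample:
    """An RGB image with an optional aligned label mask and ground truth."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray | None = None  # H x W integer labels
    id: str = ""
    truth: list[dict] | None = None  # per-seedling centerline lengths etc.

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.image.shape[:2]:
                raise ValueError("mask dimensions must equal image dimensions")
            if self.mask.min() < 0 or self.mask.max() >= DEFAULT_SCHEME.num_classes:
                raise ValueError("mask contains values outside the class scheme")


@dataclass
class DatasetSplit:
    train_ids: list[str]
    val_ids: list[str]
    ratio: float

    def __post_init__(self):
        if set(self.train_ids) & set(self.val_ids):
            raise ValueError("train and validation ids overlap")


def rasterize_polygons(shapes: Sequence[tuple[str, np.ndarray]], height: int,
                       width: int, scheme: ClassScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Draw labelled ``(x, y)`` polygons onto a label mask, in order (last wins)."""
    mask = np.zeros((height, width), dtype=np.uint8)
    for label, points in shapes:
        idx = scheme.index(label)
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise SchemaError(f"polygon for {label!r} needs >= 3 (x, y) points")
        rr, cc = _draw_polygon(pts[:, 1], pts[:, 0], shape=(height, width))
        mask[rr, cc] = idx
    return mask


def read_labelme(path: str | Path, scheme: ClassScheme = DEFAULT_SCHEME) -> ImageSample:
    """Load a Labelme JSON annotation into an :class:`ImageSample`.

    The companion image is taken from embedded base64 ``imageData`` when
    present, otherwise from ``imagePath`` resolved next to the JSON file.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if "shapes" not in doc:
        raise SchemaError(f"{path} has no 'shapes' entry")

    if doc.get("imageData"):
        img = Image.open(io.BytesIO(base64.b64decode(doc["imageData"])))
    else:
        img_path = path.parent / doc.get("imagePath", "")
        if not img_path.is_file():
            raise IOError(f"companion image not found: {img_path}")
        img = Image.open(img_path)
    image = np.asarray(img.convert("RGB"))

    h = int(doc.get("imageHeight", image.shape[0]))
    w = int(doc.get("imageWidth", image.shape[1]))
    shapes = [(s["label"], np.asarray(s["points"])) for s in doc["shapes"]]
    mask = rasterize_polygons(shapes, h, w, scheme)
    return ImageSample(image=image, mask=mask, id=path.stem)


def write_mask_png(mask: np.ndarray, path: str | Path,
                   scheme: ClassScheme = DEFAULT_SCHEME) -> None:
    """Write a label mask as an indexed single-channel PNG (frozen palette)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.min() < 0 or mask.max() >= scheme.num_classes:
        raise ValueError(f"mask values must lie in 0..{scheme.num_classes - 1}")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = list(sum(MASK_PALETTE, ())) + [0] * (768 - 3 * len(MASK_PALETTE))
    img.putpalette(palette)
    img.save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(f"{path} is not an indexed-palette mask PNG")
    return np.asarray(img, dtype=np.uint8)


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def split_dataset(ids: Sequence[str], ratio: float, seed: int) -> DatasetSplit:
    """Deterministically shuffle and partition ids into train/validation.

    ``|train| = floor(ratio * n)``; the remainder goes to validation, so 115
    ids at ratio 0.8 give the conventional 92/23 split.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(ratio * len(ids)))
    shuffled = [ids[i] for i in order]
    return DatasetSplit(train_ids=shuffled[:n_train],
                        val_ids=shuffled[n_train:], ratio=ratio)
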