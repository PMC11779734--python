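"""Synthetic germination-board scenes with exact ground truth.

Each scene emulates a dark-cloth germination board photographed from above:
elliptical seeds with a curved shoot and root stroke leaving opposite ends,
plus one bright filled disc standing in for the reference coin.  The
strokes follow quadratic Bezier centerlines (a parabola segment cannot
self-intersect, and the turning angles are bounded so the thick stroke does
not overlap itself), rendered by stamping discs of the stroke width along a
finely sampled polyline.  The ground-truth record stores every centerline's
arc length (fine polyline integration), the coin geometry, and instance
ids, so the measurement pipeline can be scored against exact truth.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse
from skimage.measure import approximate_polygon, find_contours
from skimage.morphology import disk as _disk_struct

from .io_datasets import (DEFAULT_SCHEME, ImageSample, write_image_png,
                          write_mask_png)


class SceneGenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene (pixel units unless noted)."""

    canvas: tuple[int, int] = (512, 512)
    n_seedlings: int = 5
    seed_axes: tuple[float, float] = (7.0, 12.0)     # ellipse semi-axis range
    shoot_length: tuple[float, float] = (60.0, 160.0)
    root_length: tuple[float, float] = (60.0, 180.0)
    shoot_width: tuple[float, float] = (5.0, 9.0)
    root_width: tuple[float, float] = (3.0, 6.0)
    coin_radius: tuple[float, float] = (40.0, 60.0)
    noise_sigma: float = 6.0
    margin: float = 10.0
    max_turn: float = 0.6  # radians per Bezier control leg
    seed: int = 0

    def __post_init__(self):
        for name in ("seed_axes", "shoot_length", "root_length",
                     "shoot_width", "root_width", "coin_radius"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} range must be positive and ordered")
        if self.margin < 0 or self.noise_sigma < 0:
            raise ValueError("margin and noise_sigma must be non-negative")

    @staticmethod
    def close_up(canvas: int = 128, n_seedlings: int = 3, seed: int = 0) -> "SceneSpec":
        """A small-canvas scene with a reduced field of view.

        Organ cross-sections keep the same pixel scale as the default board
        (a closer camera, not a lower-resolution one): seeds stay wider than
        their shoots, strokes stay several pixels wide.  This is the variant
        used for CPU-scale training experiments.
        """
        return SceneSpec(
            canvas=(canvas, canvas), n_seedlings=n_seedlings,
            seed_axes=(4.0, 7.0), shoot_length=(22.0, 50.0),
            root_length=(22.0, 55.0), shoot_width=(4.0, 7.0),
            root_width=(3.0, 5.0), coin_radius=(10.0, 14.0),
            noise_sigma=6.0, margin=4.0, seed=seed)

    def scaled(self, s: float) -> "SceneSpec":
        """Shrink or enlarge the whole scene geometry by factor ``s``."""
        def sc(pair, lo_min=1.0):
            return (max(lo_min, pair[0] * s), max(lo_min, pair[1] * s))

        return replace(
            self,
            canvas=(int(round(self.canvas[0] * s)), int(round(self.canvas[1] * s))),
            seed_axes=sc(self.seed_axes, 2.0),
            shoot_length=sc(self.shoot_length),
            root_length=sc(self.root_length),
            shoot_width=sc(self.shoot_width, 2.0),
            root_width=sc(self.root_width, 2.0),
            coin_radius=sc(self.coin_radius, 5.0),
            margin=max(2.0, self.margin * s),
        )


# scene colors (RGB): dark cloth, pale-green shoot, whitish root, tan seed,
# bright metal coin
_COLORS = {
    "background": (20, 22, 25),
    "shoot": (110, 190, 90),
    "root": (210, 205, 195),
    "seed": (190, 155, 70),
    "coin": (205, 205, 210),
}


def bezier_points(p0, p1, p2, n: int = 2000) -> np.ndarray:
    """Quadratic Bezier sampled at n+1 parameters (rows are (row, col))."""
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def polyline_arc_length(points: np.ndarray) -> float:
    d = np.diff(np.asarray(points, dtype=float), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _rot(v: np.ndarray, ang: float) -> np.ndarray:
    c, s = np.cos(ang), np.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _sample_curve(rng, start, direction, length, max_turn) -> np.ndarray:
    d1 = _rot(direction, rng.uniform(-max_turn, max_turn))
    p1 = start + d1 * (length / 2.0)
    d2 = _rot(d1, rng.uniform(-max_turn, max_turn))
    p2 = p1 + d2 * (length / 2.0)
    return bezier_points(start, p1, p2)


def _stroke_footprint(points: np.ndarray, width: float, shape) -> np.ndarray:
    """Stamp discs of diameter ~width along the polyline (dilation of the
    rasterized centerline by a disc of radius width/2)."""
    canvas = np.zeros(shape, dtype=bool)
    px = np.rint(points).astype(int)
    ok = (px[:, 0] >= 0) & (px[:, 0] < shape[0]) & (px[:, 1] >= 0) & (px[:, 1] < shape[1])
    canvas[px[ok, 0], px[ok, 1]] = True
    r = max(1, int(round(width / 2.0)))
    return ndi.binary_dilation(canvas, structure=_disk_struct(r))


def generate_scene(spec: SceneSpec) -> tuple[ImageSample, dict]:
    """Render one scene; returns the sample (image + mask) and truth record.

    Placement is rejection-sampled; if a layout cannot be completed the
    whole scene is re-drawn from the same random stream (deterministic per
    seed), with a bounded number of restarts before erroring out.
    """
    rng = np.random.default_rng(spec.seed)
    last_err: SceneGenerationError | None = None
    for _ in range(25):
        try:
            return _generate_scene_once(spec, rng)
        except SceneGenerationError as err:
            last_err = err
    raise last_err


def _generate_scene_once(spec: SceneSpec, rng: np.random.Generator
                         ) -> tuple[ImageSample, dict]:
    H, W = spec.canvas
    mask = np.zeros((H, W), dtype=np.uint8)
    occupied = np.zeros((H, W), dtype=bool)

    # coin first: bright disc, label stays background
    r_coin = rng.uniform(*spec.coin_radius)
    pad = r_coin + spec.margin
    if 2 * pad >= min(H, W):
        raise SceneGenerationError("canvas too small for the coin; enlarge it")
    cy = rng.uniform(pad, H - pad)
    cx = rng.uniform(pad, W - pad)
    coin_rr, coin_cc = _draw_disk((cy, cx), r_coin, shape=(H, W))
    coin_mask = np.zeros((H, W), dtype=bool)
    coin_mask[coin_rr, coin_cc] = True
    occupied |= ndi.binary_dilation(coin_mask, iterations=int(spec.margin))

    seedlings = []
    for sid in range(spec.n_seedlings):
        placed = False
        for _ in range(200):
            a = rng.uniform(*spec.seed_axes)
            b = rng.uniform(spec.seed_axes[0], a)
            theta = rng.uniform(0, 2 * np.pi)
            # unit vector along the ellipse major axis (the r_radius axis of
            # skimage.draw.ellipse rotated by theta, in (row, col) coords)
            u = np.array([np.cos(theta), np.sin(theta)])
            ls = rng.uniform(*spec.shoot_length)
            lr = rng.uniform(*spec.root_length)
            pad0 = a + spec.margin
            if 2 * pad0 >= min(H, W):
                continue
            center = np.array([rng.uniform(pad0, H - pad0),
                               rng.uniform(pad0, W - pad0)])
            # strokes begin just inside the seed rim so the rendered classes
            # stay 8-connected at the junction
            shoot_pts = _sample_curve(rng, center + u * (a - 1.0), u, ls, spec.max_turn)
            root_pts = _sample_curve(rng, center - u * (a - 1.0), -u, lr, spec.max_turn)
            ws = rng.uniform(*spec.shoot_width)
            wr = rng.uniform(*spec.root_width)
            if (shoot_pts.min() < spec.margin or root_pts.min() < spec.margin
                    or shoot_pts[:, 0].max() > H - spec.margin
                    or root_pts[:, 0].max() > H - spec.margin
                    or shoot_pts[:, 1].max() > W - spec.margin
                    or root_pts[:, 1].max() > W - spec.margin):
                continue
            seed_rr, seed_cc = _draw_ellipse(center[0], center[1], a, b,
                                             shape=(H, W), rotation=theta)
            seed_m = np.zeros((H, W), dtype=bool)
            seed_m[seed_rr, seed_cc] = True
            shoot_m = _stroke_footprint(shoot_pts, ws, (H, W))
            root_m = _stroke_footprint(root_pts, wr, (H, W))
            if (shoot_m & root_m).any():
                continue  # strokes curving into each other blur the centerlines
            footprint = seed_m | shoot_m | root_m
            grown = ndi.binary_dilation(footprint, iterations=max(1, int(spec.margin)))
            if (grown & occupied).any():
                continue
            # paint: seed first, strokes overwrite the junction pixels
            mask[seed_m] = 3
            mask[root_m] = 2
            mask[shoot_m] = 1
            occupied |= grown
            seedlings.append({
                "id": sid,
                "shoot_len_px": polyline_arc_length(shoot_pts),
                "root_len_px": polyline_arc_length(root_pts),
                "seed_center": [float(center[0]), float(center[1])],
                "seed_axes": [float(a), float(b)],
                "shoot_width": float(ws),
                "root_width": float(wr),
            })
            placed = True
            break
        if not placed:
            raise SceneGenerationError(
                "could not place all seedlings; enlarge the canvas or reduce n_seedlings")

    # render the image
    img = np.empty((H, W, 3), dtype=float)
    img[:] = _COLORS["background"]
    img[coin_mask] = _COLORS["coin"]
    for cls, name in ((1, "shoot"), (2, "root"), (3, "seed")):
        img[mask == cls] = _COLORS[name]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    mm_per_px = 25.0 / (2.0 * r_coin)
    for s in seedlings:
        s["shoot_len_mm"] = s["shoot_len_px"] * mm_per_px
        s["root_len_mm"] = s["root_len_px"] * mm_per_px
    truth = {
        "coin": {"x": float(cx), "y": float(cy), "r": float(r_coin)},
        "mm_per_pixel": mm_per_px,
        "seedlings": seedlings,
        "spec": asdict(spec),
    }
    sample = ImageSample(image=image, mask=mask, id=f"scene_{spec.seed:05d}",
                         truth=seedlings)
    return sample, truth


def mask_to_labelme_shapes(mask: np.ndarray, tolerance: float = 0.8) -> list[dict]:
    """Polygonize class regions into Labelme-style shapes ((x, y) points)."""
    shapes = []
    for cls, name in ((3, "seed"), (2, "root"), (1, "shoot")):
        binary = np.pad(mask == cls, 1)
        for contour in find_contours(binary.astype(float), 0.5):
            poly = approximate_polygon(contour, tolerance) - 1.0  # undo pad
            if len(poly) < 3:
                continue
            pts = [[float(np.clip(x, 0, mask.shape[1] - 1)),
                    float(np.clip(y, 0, mask.shape[0] - 1))]
                   for y, x in poly]
            shapes.append({"label": name, "points": pts, "shape_type": "polygon"})
    return shapes


def generate_dataset(spec: SceneSpec, n_scenes: int, out_dir: str | Path) -> list[str]:
    """Write images/, masks/, labelme/ JSONs and truth.json; returns scene ids."""
    out = Path(out_dir)
    for sub in ("images", "masks", "labelme"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    ids, truths = [], {}
    for i in range(n_scenes):
        sample, truth = generate_scene(replace(spec, seed=spec.seed + i))
        sid = sample.id
        write_image_png(sample.image, out / "images" / f"{sid}.png")
        write_mask_png(sample.mask, out / "masks" / f"{sid}.png")
        doc = {
            "version": "5.0.1",
            "shapes": mask_to_labelme_shapes(sample.mask),
            "imagePath": f"../images/{sid}.png",
            "imageData": None,
            "imageHeight": sample.mask.shape[0],
            "imageWidth": sample.mask.shape[1],
        }
        with open(out / "labelme" / f"{sid}.json", "w") as fh:
            json.dump(doc, fh)
        truths[sid] = truth
        ids.append(sid)
    with open(out / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=1)
    return ids
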