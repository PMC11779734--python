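"""Full encoder-decoder assembly mapping an RGB image to 4-class logits.

Pipeline: FasterNet backbone -> EMA attention on the stride-32 feature ->
PSPA pyramid -> 8-fold CARAFE upsample (stride 32 -> 4) -> concatenation
with the 1x1-projected stride-4 skip feature -> partial-convolution
refinement -> 1x1 classifier -> final 4-fold upsample back to the input
resolution (CARAFE by default, nearest-neighbour switchable).  The
classifier runs at stride 4, so the final upsample restores a
num_classes x H x W logit map.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .attention import EMA, EmaConfig
from .backbone import BackboneConfig, FasterNetBackbone, FasterNetBlock
from .carafe import Carafe, CarafeConfig
from .io_datasets import DEFAULT_SCHEME, ClassScheme
from .nn import Conv2d, ConvBnRelu, Module, Tensor, concat
from .nn import functional as F
from .pyramid import PSPAPyramid, PyramidConfig


@dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    ema: EmaConfig = field(default_factory=EmaConfig)
    aspp: PyramidConfig = field(default_factory=PyramidConfig)
    carafe_mid: CarafeConfig = field(default_factory=lambda: CarafeConfig(sigma=8))
    carafe_final: CarafeConfig = field(default_factory=lambda: CarafeConfig(sigma=4))
    num_classes: int = 4
    low_level_width: int = 48
    decoder_blocks: int = 1
    ema_pre_aspp: bool = True
    ema_post_aspp: bool = False
    final_upsample: str = "carafe"  # or "nearest"

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.carafe_mid.sigma * 4 != 32:
            raise ValueError("mid upsample must bring stride 32 to stride 4")
        if self.final_upsample not in ("carafe", "nearest"):
            raise ValueError("final_upsample must be 'carafe' or 'nearest'")

    @staticmethod
    def reduced(width_mult: float = 0.25) -> "ModelConfig":
        """A width-reduced variant for CPU-scale experiments."""
        def m(x):
            return max(8, int(round(x * width_mult)))

        return ModelConfig(
            backbone=BackboneConfig(depths=(1, 1, 2, 1),
                                    widths=(m(40), m(80), m(160), m(320))),
            ema=EmaConfig(groups=4),
            aspp=PyramidConfig(branch_width=m(128), out_width=m(256)),
            carafe_mid=CarafeConfig(sigma=8, k_up=3, c_m=m(64)),
            carafe_final=CarafeConfig(sigma=4, k_up=3, c_m=16),
            low_level_width=m(48),
        )


class DfmaNet(Module):
    """The segmentation network; ``forward`` returns logits at input size."""

    def __init__(self, cfg: ModelConfig = ModelConfig(),
                 scheme: ClassScheme = DEFAULT_SCHEME,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if cfg.num_classes != scheme.num_classes:
            raise ValueError("num_classes must match the class scheme")
        rng = rng if rng is not None else np.random.default_rng()
        self.cfg = cfg
        self.scheme = scheme
        self.backbone = FasterNetBackbone(cfg.backbone, rng=rng)
        high_ch = cfg.backbone.widths[3]
        low_ch = cfg.backbone.widths[0]
        ow = cfg.aspp.out_width
        self.ema_pre = EMA(high_ch, cfg.ema, rng=rng) if cfg.ema_pre_aspp else None
        self.aspp = PSPAPyramid(high_ch, cfg.aspp, rng=rng)
        self.ema_post = EMA(ow, cfg.ema, rng=rng) if cfg.ema_post_aspp else None
        self.up_mid = Carafe(ow, cfg.carafe_mid, rng=rng)
        self.low_proj = ConvBnRelu(low_ch, cfg.low_level_width, 1, rng=rng)
        dec_ch = ow + cfg.low_level_width
        self.refine_blocks = [
            FasterNetBlock(dec_ch, cfg.backbone.partial_ratio, rng=rng)
            for _ in range(cfg.decoder_blocks)
        ]
        self.refine_conv = ConvBnRelu(dec_ch, ow, 3, padding=1, rng=rng)
        self.classifier = Conv2d(ow, cfg.num_classes, 1, rng=rng)
        if cfg.final_upsample == "carafe":
            self.up_final = Carafe(cfg.num_classes, cfg.carafe_final, rng=rng)
        else:
            self.up_final = None

    # individual stages exposed for the composition tests ------------------
    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        low, high = self.backbone(x)
        if self.ema_pre is not None:
            high = self.ema_pre(high)
        return low, high

    def context(self, high: Tensor) -> Tensor:
        y = self.aspp(high)
        if self.ema_post is not None:
            y = self.ema_post(y)
        return y

    def decode(self, low: Tensor, ctx: Tensor) -> Tensor:
        y = self.up_mid(ctx)
        y = concat([y, self.low_proj(low)], axis=1)
        for blk in self.refine_blocks:
            y = blk(y)
        return self.refine_conv(y)

    def classify(self, y: Tensor) -> Tensor:
        logits = self.classifier(y)
        if self.up_final is not None:
            return self.up_final(logits)
        return F.upsample_nearest(logits, self.cfg.carafe_final.sigma)

    def forward(self, x: Tensor) -> Tensor:
        low, high = self.encode(x)
        return self.classify(self.decode(low, self.context(high)))


def predict_mask(model: DfmaNet, image: np.ndarray) -> np.ndarray:
    """Segment one H x W x 3 image into a label mask (argmax over classes).

    Ties break toward the lower class index (argmax convention).
    """
    x = _prepare_image(image)
    model.eval()
    logits = model(Tensor(x))
    return np.argmax(logits.data[0], axis=0).astype(np.uint8)


def _prepare_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    x = image.astype(np.float32) / 255.0
    return x.transpose(2, 0, 1)[None]


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: DfmaNet, path: str | Path) -> None:
    """Self-describing checkpoint: weights + model config + class scheme."""
    meta = {"config": asdict(model.cfg), "classes": list(model.scheme.names)}
    state = model.state_dict()
    np.savez_compressed(path, __meta__=json.dumps(meta),
                        **{k: v for k, v in state.items()})


def load_checkpoint(path: str | Path) -> DfmaNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    c = meta["config"]

    def tup(x):
        return tuple(tuple(i) if isinstance(i, list) else i for i in x)

    cfg = ModelConfig(
        backbone=BackboneConfig(depths=tuple(c["backbone"]["depths"]),
                                widths=tuple(c["backbone"]["widths"]),
                                partial_ratio=c["backbone"]["partial_ratio"]),
        ema=EmaConfig(**c["ema"]),
        aspp=PyramidConfig(branch_width=c["aspp"]["branch_width"],
                           rate_pairs=tup(c["aspp"]["rate_pairs"]),
                           out_width=c["aspp"]["out_width"],
                           partial_ratio=c["aspp"]["partial_ratio"],
                           serial=c["aspp"]["serial"]),
        carafe_mid=CarafeConfig(**c["carafe_mid"]),
        carafe_final=CarafeConfig(**c["carafe_final"]),
        num_classes=c["num_classes"],
        low_level_width=c["low_level_width"],
        decoder_blocks=c["decoder_blocks"],
        ema_pre_aspp=c["ema_pre_aspp"],
        ema_post_aspp=c["ema_post_aspp"],
        final_upsample=c["final_upsample"],
    )
    model = DfmaNet(cfg, ClassScheme(tuple(meta["classes"])), rng=np.random.default_rng(0))
    model.load_state_dict(state)
    return model
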