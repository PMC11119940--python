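"""Full classifier assembly: backbone → attention → fusion → pooling → head.

Two backbones share the same 4-stage, stride-2-per-stage geometry:

* ``resnet50`` — the standard bottleneck residual network (stages of 3/4/6/3
  blocks, widths 256/512/1024/2048, total stride 4/8/16/32).  Weights may be
  loaded from an ``.npz`` state file; no download is attempted.
* ``tiny`` — a narrow 4-stage CNN with the identical stride layout, used for
  fast CPU training and tests.

Relation-aware attention blocks are inserted after configurable stages
(default 2 and 3, where the position count H·W is moderate).  Stages L2, L3,
L4 — the three deepest — feed the multi-scale fusion head; pooling is
generalized-mean by default, with plain global average (``gap``) or global
max (``gmp``) available for ablation arms; a single linear layer produces
the class logits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import (
    Tensor, Module, Conv2d, BatchNorm2d, Linear, Sequential, ReLU,
)
from .nn.tensor import max_pool2d
from .attention import RGABlock
from .fusion import MultiScaleFusion
from .pooling import GeMPool

__all__ = ["NetworkConfig", "PestNet", "build_model", "forward",
           "count_parameters", "save_checkpoint", "load_checkpoint"]

_TINY_WIDTHS = (16, 24, 32, 48)
_RESNET50_BLOCKS = (3, 4, 6, 3)


@dataclass
class NetworkConfig:
    """Everything needed to build (and rebuild) a model deterministically."""

    num_classes: int = 2
    backbone: str = "tiny"                    # {tiny, resnet50}
    input_size: int = 64                      # side of the square crop fed in
    rga_stages: tuple = (2, 3)                # stages followed by an RGA block
    rga_spatial: bool = True
    rga_channel: bool = True
    rga_reduction_ratio: int = 8
    rga_embed_ratio: int = 8
    use_msff: bool = True
    msff_compress_channels: int = 8
    msff_rescale_mode: str = "strided_conv"
    pooling: str = "gem"                      # {gem, gap, gmp}
    gem_p_init: float = 3.0
    gem_shared: bool = True
    gem_eps: float = 1e-6
    pretrained: str | None = None             # optional .npz backbone state

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.backbone not in ("tiny", "resnet50"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.pooling not in ("gem", "gap", "gmp"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        bad = [s for s in self.rga_stages if s not in (1, 2, 3, 4)]
        if bad:
            raise ValueError(f"unknown backbone stage ids {bad}")
        self.rga_stages = tuple(self.rga_stages)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


# -- backbones ----------------------------------------------------------------

class TinyBackbone(Module):
    """Four stages, stride 2 each (plus a stride-2 stem): total strides
    4/8/16/32, mirroring the residual backbone's geometry at small width."""

    widths = _TINY_WIDTHS

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        w = self.widths
        self.stem = Sequential(
            Conv2d(3, w[0], 3, stride=2, padding=1, rng=rng),
            BatchNorm2d(w[0]), ReLU(),
        )
        self.stages = []
        ch = w[0]
        for wi in w:
            self.stages.append(Sequential(
                Conv2d(ch, wi, 3, stride=2, padding=1, rng=rng),
                BatchNorm2d(wi), ReLU(),
                Conv2d(wi, wi, 3, stride=1, padding=1, rng=rng),
                BatchNorm2d(wi), ReLU(),
            ))
            ch = wi

    def forward_stages(self, x: Tensor) -> list:
        x = self.stem(x)
        outs = []
        for stage in self.stages:
            x = stage(x)
            outs.append(x)
        return outs


class Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch, mid_ch, stride, rng):
        super().__init__()
        out_ch = mid_ch * self.expansion
        self.conv1 = Conv2d(in_ch, mid_ch, 1, rng=rng)
        self.bn1 = BatchNorm2d(mid_ch)
        self.conv2 = Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(mid_ch)
        self.conv3 = Conv2d(mid_ch, out_ch, 1, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down = Sequential(Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng),
                                   BatchNorm2d(out_ch))
        else:
            self.down = None

    def forward(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = self.bn3(self.conv3(h))
        shortcut = x if self.down is None else self.down(x)
        return (h + shortcut).relu()


class ResNet50Backbone(Module):
    widths = (256, 512, 1024, 2048)

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(3, 64, 7, stride=2, padding=3, rng=rng)
        self.bn1 = BatchNorm2d(64)
        self.stages = []
        in_ch = 64
        for i, (blocks, mid) in enumerate(zip(_RESNET50_BLOCKS, (64, 128, 256, 512))):
            stride = 1 if i == 0 else 2  # stage 1 follows the stride-2 maxpool
            layers = [Bottleneck(in_ch, mid, stride, rng)]
            in_ch = mid * Bottleneck.expansion
            for _ in range(blocks - 1):
                layers.append(Bottleneck(in_ch, mid, 1, rng))
            self.stages.append(Sequential(*layers))

    def forward_stages(self, x: Tensor) -> list:
        x = self.bn1(self.conv1(x)).relu()
        x = max_pool2d(x, 3, stride=2, padding=1)
        outs = []
        for stage in self.stages:
            x = stage(x)
            outs.append(x)
        return outs


_STAGE_STRIDES = (4, 8, 16, 32)  # total downsampling at each stage output


class PestNet(Module):
    """The assembled classifier; see the module docstring for the data path."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        if cfg.backbone == "tiny":
            self.backbone = TinyBackbone(rng)
        else:
            self.backbone = ResNet50Backbone(rng)
        widths = self.backbone.widths

        size = cfg.input_size
        stage_hw = [size // s for s in _STAGE_STRIDES]
        if stage_hw[-1] < 1:
            raise ValueError(f"input_size {size} too small for a 4-stage backbone")

        self.rga_blocks = {}
        blocks = []
        for s in cfg.rga_stages:
            blk = RGABlock(
                widths[s - 1], (stage_hw[s - 1], stage_hw[s - 1]),
                use_spatial=cfg.rga_spatial, use_channel=cfg.rga_channel,
                reduction_ratio=cfg.rga_reduction_ratio,
                embed_ratio=_embed_ratio_for(widths[s - 1], cfg.rga_embed_ratio),
                rng=rng,
            )
            self.rga_blocks[s] = blk
            blocks.append(blk)
        self._rga_list = blocks  # parameter discovery walks lists

        if cfg.use_msff:
            self.msff = MultiScaleFusion(
                widths[1], widths[2], widths[3],
                compress_channels=cfg.msff_compress_channels,
                rescale_mode=cfg.msff_rescale_mode, rng=rng,
            )
        else:
            self.msff = None

        feat = widths[3]
        if cfg.pooling == "gem":
            self.pool = GeMPool(channels=feat, p_init=cfg.gem_p_init,
                                shared=cfg.gem_shared, eps=cfg.gem_eps)
        else:
            self.pool = cfg.pooling  # 'gap' / 'gmp' handled in forward
        self.classifier = Linear(feat, cfg.num_classes, rng=rng)

        if cfg.pretrained:
            state = dict(np.load(cfg.pretrained))
            self.backbone.load_state_dict(state)

    def forward(self, images) -> Tensor:
        x = Tensor.as_tensor(images)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected an RGB batch [B,3,H,W], got {x.shape}")
        outs = self.backbone.forward_stages(x)
        feats = []
        for idx, out in enumerate(outs, start=1):
            if idx in self.rga_blocks:
                out = self.rga_blocks[idx](out)
            feats.append(out)
        l2, l3, l4 = feats[1], feats[2], feats[3]
        if self.msff is not None:
            head_in = self.msff(l2, l3, l4)
        else:
            head_in = l4
        if isinstance(self.pool, GeMPool):
            v = self.pool(head_in)
        elif self.pool == "gap":
            v = head_in.mean(axis=(2, 3))
        else:  # gmp
            v = head_in.max(axis=(2, 3))
        return self.classifier(v)


def _embed_ratio_for(channels: int, ratio: int) -> int:
    """Largest divisor of ``channels`` not exceeding the requested ratio."""
    r = min(ratio, channels)
    while channels % r:
        r -= 1
    return r


def build_model(cfg, seed: int = 0) -> PestNet:
    """Construct a model from a config (dict or NetworkConfig), seeded."""
    if isinstance(cfg, dict):
        cfg = NetworkConfig.from_dict(cfg)
    return PestNet(cfg, np.random.default_rng(seed))


def forward(model: PestNet, images) -> Tensor:
    return model(images)


def count_parameters(model: Module) -> int:
    return sum(p.data.size for p in model.parameters())


def save_checkpoint(model: PestNet, path: str, extra: dict | None = None):
    """Single-file checkpoint: parameter/buffer state plus the config."""
    state = model.state_dict()
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str) -> tuple:
    """Load a checkpoint; returns (model in eval mode, extra dict)."""
    data = dict(np.load(path))
    meta = json.loads(bytes(data.pop("__meta__")).decode())
    cfg = NetworkConfig.from_dict(meta["config"])
    model = PestNet(cfg)
    model.load_state_dict(data)
    model.eval()
    return model, meta.get("extra", {})
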