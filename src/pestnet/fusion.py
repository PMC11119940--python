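"""Adaptive multi-scale feature fusion (MSFF) across three backbone stages.

The three stage outputs L2, L3, L4 (successively halved resolution) are
first brought to L4's geometry — spatial size and channel count — giving
X2→4, X3→4, X4→4.  Each aligned map is compressed to 8 channels by a 1×1
convolution; the 24-channel concatenation is mapped to 3 channels and
softmax-normalised per spatial location, yielding weight maps (α, β, γ)
with α+β+γ = 1 everywhere.  The fused map

    y = α·X2→4 + β·X3→4 + γ·X4→4

is a per-location convex combination (so it is pointwise bounded by the
three inputs, and fusing three identical maps returns that map exactly),
followed by a 3×3 stride-1 convolution.

Two rescaling modes are provided: ``strided_conv`` (learned stride-2 3×3
convolutions, one per octave, with a channel projection) and
``interpolate`` (2×2 average pooling per octave plus a 1×1 projection,
optionally initialised to preserve channel means — handy for
exact-arithmetic tests).
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Module, Conv2d, BatchNorm2d, ReLU, Sequential, \
    concatenate, softmax, avg_pool2d

__all__ = ["Rescale", "MultiScaleFusion", "rescale_to_l4", "fuse"]


def _octaves(src_hw, dst_hw) -> int:
    """Number of ×2 downsampling steps from src to dst spatial dims."""
    (sh, sw), (dh, dw) = src_hw, dst_hw
    if sh % dh or sw % dw or sh // dh != sw // dw:
        raise ValueError(f"incompatible geometry {src_hw} -> {dst_hw}")
    ratio = sh // dh
    if ratio & (ratio - 1):
        raise ValueError(f"spatial ratio {ratio} is not a power of two")
    return int(ratio).bit_length() - 1


class Rescale(Module):
    """Bring a feature map to a target stage's spatial and channel geometry."""

    def __init__(self, in_channels: int, out_channels: int, octaves: int,
                 mode: str = "strided_conv",
                 rng: np.random.Generator | None = None,
                 mean_preserving_init: bool = False):
        super().__init__()
        if mode not in ("strided_conv", "interpolate"):
            raise ValueError(f"unknown rescale mode {mode!r}")
        rng = rng or np.random.default_rng(0)
        self.mode = mode
        self.octaves = octaves
        if mode == "strided_conv":
            layers = []
            ch = in_channels
            for _ in range(octaves):
                layers += [Conv2d(ch, out_channels, 3, stride=2, padding=1, rng=rng),
                           BatchNorm2d(out_channels), ReLU()]
                ch = out_channels
            if ch != out_channels or octaves == 0:
                layers.append(Conv2d(ch, out_channels, 1, rng=rng))
            self.body = Sequential(*layers)
            self.proj = None
        else:
            self.body = None
            self.proj = Conv2d(in_channels, out_channels, 1, rng=rng)
            if mean_preserving_init:
                self.proj.weight.data[:] = 1.0 / in_channels
                self.proj.bias.data[:] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "strided_conv":
            return self.body(x)
        for _ in range(self.octaves):
            x = avg_pool2d(x, 2)
        return self.proj(x)


class MultiScaleFusion(Module):
    """Three-level adaptive fusion head.

    Parameters are sized for stage channel counts (ch2, ch3, ch4); L2 sits
    two octaves above L4, L3 one octave above.
    """

    def __init__(self, ch2: int, ch3: int, ch4: int, compress_channels: int = 8,
                 rescale_mode: str = "strided_conv",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.rescale2 = Rescale(ch2, ch4, 2, rescale_mode, rng)
        self.rescale3 = Rescale(ch3, ch4, 1, rescale_mode, rng)
        self.compress = [Conv2d(ch4, compress_channels, 1, rng=rng) for _ in range(3)]
        self.weight_conv = Conv2d(3 * compress_channels, 3, 1, rng=rng)
        self.out_conv = Conv2d(ch4, ch4, 3, stride=1, padding=1, rng=rng)

    # -- pieces exposed for inspection ---------------------------------------
    def fusion_weights(self, x24: Tensor, x34: Tensor, x44: Tensor):
        """Per-location softmax weights (α, β, γ), each [B, 1, H, W]."""
        if not (x24.shape[2:] == x34.shape[2:] == x44.shape[2:]):
            raise ValueError("aligned maps must share spatial dims")
        z = concatenate([conv(x) for conv, x in
                         zip(self.compress, (x24, x34, x44))], axis=1)
        logits = self.weight_conv(z)            # [B, 3, H, W]
        w = softmax(logits, axis=1)
        return w[:, 0:1], w[:, 1:2], w[:, 2:3]

    def fuse_raw(self, x24: Tensor, x34: Tensor, x44: Tensor) -> Tensor:
        """Convex combination of the aligned maps (before the 3×3 conv)."""
        a, b, g = self.fusion_weights(x24, x34, x44)
        return a * x24 + b * x34 + g * x44

    def forward(self, l2: Tensor, l3: Tensor, l4: Tensor) -> Tensor:
        x24 = self.rescale2(l2)
        x34 = self.rescale3(l3)
        fused = self.fuse_raw(x24, x34, l4)
        return self.out_conv(fused)


# -- functional wrappers ------------------------------------------------------

def rescale_to_l4(f, target, mode: str = "interpolate", seed: int = 0,
                  mean_preserving_init: bool = False) -> Tensor:
    """One-shot rescale of ``f`` to ``target``'s spatial/channel geometry."""
    f = Tensor.as_tensor(f)
    target = Tensor.as_tensor(target)
    octaves = _octaves(tuple(f.shape[2:]), tuple(target.shape[2:]))
    mod = Rescale(f.shape[1], target.shape[1], octaves, mode,
                  np.random.default_rng(seed), mean_preserving_init)
    mod.eval()
    return mod(f)


def fuse(l2, l3, l4, compress_channels: int = 8,
         rescale_mode: str = "strided_conv", seed: int = 0) -> Tensor:
    """One-shot MSFF pass with freshly seeded parameters."""
    l2, l3, l4 = map(Tensor.as_tensor, (l2, l3, l4))
    mod = MultiScaleFusion(l2.shape[1], l3.shape[1], l4.shape[1],
                           compress_channels, rescale_mode,
                           np.random.default_rng(seed))
    return mod(l2, l3, l4)
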