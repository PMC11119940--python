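"""Relation-aware global attention (RGA), spatial and channel variants.

Each feature node (a spatial position, or a whole channel map) is scored not
only from its own embedding but from its *pairwise affinities to every other
node*: for node i the affinity row R(i,:) and column R(:,i) are stacked into
a relation vector, concatenated with a channel-pooled embedding of the node
itself, and pushed through a small bottleneck scorer ending in a sigmoid.
The resulting per-node scalar in (0, 1) re-weights the input map, so
attention never changes tensor shape.

Affinities are dot products of ReLU-activated 1×1-conv embeddings,

    r(i, j) = θ(x_i)ᵀ φ(x_j),

hence every entry of the relation matrix is nonnegative.  The spatial
submodule (nodes = H·W positions) runs first; its re-weighted output feeds
the channel submodule (nodes = C channels).

Because the relation machinery sizes its convolutions by the node count,
the modules are constructed for a fixed (channels, H, W) geometry — the
network inserts them at backbone stages where that geometry is known.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    Tensor, Module, Conv2d, BatchNorm2d, Sequential, ReLU,
    concatenate, matmul,
)

__all__ = [
    "SpatialRelation", "ChannelRelation", "SpatialAttention",
    "ChannelAttention", "RGABlock",
    "spatial_relation_matrix", "spatial_attention", "channel_attention",
    "rga_block",
]


def _check_finite(x: Tensor, what: str):
    if not np.all(np.isfinite(x.data)):
        raise ValueError(f"{what} contains non-finite values")


def _embed(in_ch: int, out_ch: int, rng, bn_bypass: bool) -> Sequential:
    """1×1 conv + BN + ReLU embedding used for θ, φ, ψ and δ."""
    return Sequential(
        Conv2d(in_ch, out_ch, 1, bias=False, rng=rng),  # BN absorbs any bias
        BatchNorm2d(out_ch, bypass=bn_bypass),
        ReLU(),
    )


class SpatialRelation(Module):
    """Pairwise affinity matrix among the N = H·W spatial positions.

    ``embed_ratio`` must divide the channel count; θ and φ are independent
    C → C/embed_ratio embeddings.  Setting ``identity_embeddings=True``
    (requires embed_ratio=1) replaces both with the identity map so the
    matrix reduces to R[i,j] = ReLU(x_i)·ReLU(x_j) — used to test the
    dot-product algebra directly.
    """

    def __init__(self, channels: int, embed_ratio: int = 8,
                 rng: np.random.Generator | None = None,
                 bn_bypass: bool = False, identity_embeddings: bool = False):
        super().__init__()
        if embed_ratio < 1 or channels % embed_ratio != 0:
            raise ValueError(
                f"embed_ratio {embed_ratio} must divide channel count {channels}")
        rng = rng or np.random.default_rng(0)
        self.embed_channels = channels // embed_ratio
        self.theta = _embed(channels, self.embed_channels, rng, bn_bypass)
        self.phi = _embed(channels, self.embed_channels, rng, bn_bypass)
        if identity_embeddings:
            if embed_ratio != 1:
                raise ValueError("identity embeddings require embed_ratio=1")
            eye = np.eye(channels).reshape(channels, channels, 1, 1)
            for emb in (self.theta, self.phi):
                emb.layers[0].weight.data = eye.copy()

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x, "input feature map")
        b, c, h, w = x.shape
        n = h * w
        t = self.theta(x).reshape(b, self.embed_channels, n)
        p = self.phi(x).reshape(b, self.embed_channels, n)
        return matmul(t.transpose(0, 2, 1), p)  # [B, N, N], R[i,j]=θ(x_i)·φ(x_j)


class ChannelRelation(Module):
    """Pairwise affinity matrix among the C channel maps.

    The map [B, C, H, W] is viewed as N = H·W feature values per channel
    node ([B, N, C, 1]); embeddings are 1×1 convolutions over that
    N-dimensional axis.
    """

    def __init__(self, spatial: tuple, embed_ratio: int = 8,
                 rng: np.random.Generator | None = None,
                 bn_bypass: bool = False, identity_embeddings: bool = False):
        super().__init__()
        h, w = spatial
        n = h * w
        rng = rng or np.random.default_rng(0)
        if identity_embeddings:
            if embed_ratio != 1:
                raise ValueError("identity embeddings require embed_ratio=1")
            self.embed_channels = n
        else:
            self.embed_channels = max(n // embed_ratio, 1)
        self.spatial = (h, w)
        self.theta = _embed(n, self.embed_channels, rng, bn_bypass)
        self.phi = _embed(n, self.embed_channels, rng, bn_bypass)
        if identity_embeddings:
            eye = np.eye(n).reshape(n, n, 1, 1)
            for emb in (self.theta, self.phi):
                emb.layers[0].weight.data = eye.copy()

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x, "input feature map")
        b, c, h, w = x.shape
        if (h, w) != self.spatial:
            raise ValueError(f"expected spatial dims {self.spatial}, got {(h, w)}")
        n = h * w
        # nodes = channels; per-node features = flattened spatial values
        z = x.reshape(b, c, n).transpose(0, 2, 1).reshape(b, n, c, 1)
        t = self.theta(z).reshape(b, self.embed_channels, c)
        p = self.phi(z).reshape(b, self.embed_channels, c)
        return matmul(t.transpose(0, 2, 1), p)  # [B, C, C]


def _relation_channels(r: Tensor) -> Tensor:
    """[B, N, N] affinity matrix -> [B, 2N, N] relation-vector channels.

    Output channel k at node i is R[i, k] for k < N (row block first) and
    R[k−N, i] for k >= N (column block), matching r_i = [R(i,:), R(:,i)].
    """
    return concatenate([r.transpose(0, 2, 1), r], axis=1)


class _NodeScorer(Module):
    """Bottleneck scorer: Conv1 (reduce by ratio) + BN + ReLU + Conv2 (→1) + BN + sigmoid."""

    def __init__(self, in_ch: int, reduction_ratio: int, rng, bn_bypass: bool):
        super().__init__()
        mid = max(in_ch // reduction_ratio, 1)
        self.conv1 = Conv2d(in_ch, mid, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(mid, bypass=bn_bypass)
        self.conv2 = Conv2d(mid, 1, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(1, bypass=bn_bypass)

    def forward(self, e: Tensor) -> Tensor:
        h = self.bn1(self.conv1(e)).relu()
        return self.bn2(self.conv2(h)).sigmoid()


class SpatialAttention(Module):
    """RGA-S: per-position attention from spatial relations; shape preserving."""

    def __init__(self, channels: int, spatial: tuple, reduction_ratio: int = 8,
                 embed_ratio: int = 8, rng: np.random.Generator | None = None,
                 bn_bypass: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        h, w = spatial
        n = h * w
        self.spatial = (h, w)
        self.relation = SpatialRelation(channels, embed_ratio, rng, bn_bypass)
        self.psi = _embed(channels, max(channels // embed_ratio, 1), rng, bn_bypass)
        self.delta = _embed(2 * n, max(2 * n // reduction_ratio, 1), rng, bn_bypass)
        scorer_in = 1 + max(2 * n // reduction_ratio, 1)
        self.scorer = _NodeScorer(scorer_in, reduction_ratio, rng, bn_bypass)

    def forward(self, x: Tensor):
        _check_finite(x, "input feature map")
        b, c, h, w = x.shape
        if (h, w) != self.spatial:
            raise ValueError(f"expected spatial dims {self.spatial}, got {(h, w)}")
        n = h * w
        r = self.relation(x)  # [B, N, N]
        rel = _relation_channels(r).reshape(b, 2 * n, h, w)
        pooled = self.psi(x).mean(axis=1, keepdims=True)      # poolC -> [B,1,H,W]
        e = concatenate([pooled, self.delta(rel)], axis=1)
        s = self.scorer(e)                                     # [B,1,H,W]
        return x * s, s

    def weights(self, x: Tensor) -> Tensor:
        return self.forward(x)[1]


class ChannelAttention(Module):
    """RGA-C: per-channel attention from channel relations; shape preserving."""

    def __init__(self, channels: int, spatial: tuple, reduction_ratio: int = 8,
                 embed_ratio: int = 8, rng: np.random.Generator | None = None,
                 bn_bypass: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        h, w = spatial
        n = h * w
        self.spatial = (h, w)
        self.channels = channels
        self.relation = ChannelRelation((h, w), embed_ratio, rng, bn_bypass)
        self.psi = _embed(n, max(n // embed_ratio, 1), rng, bn_bypass)
        self.delta = _embed(2 * channels, max(2 * channels // reduction_ratio, 1),
                            rng, bn_bypass)
        scorer_in = 1 + max(2 * channels // reduction_ratio, 1)
        self.scorer = _NodeScorer(scorer_in, reduction_ratio, rng, bn_bypass)

    def forward(self, y_s: Tensor):
        _check_finite(y_s, "input feature map")
        b, c, h, w = y_s.shape
        if (h, w) != self.spatial or c != self.channels:
            raise ValueError(
                f"expected [{self.channels}, {self.spatial}], got {(c, (h, w))}")
        n = h * w
        r = self.relation(y_s)  # [B, C, C]
        rel = _relation_channels(r).reshape(b, 2 * c, c, 1)
        z = y_s.reshape(b, c, n).transpose(0, 2, 1).reshape(b, n, c, 1)
        pooled = self.psi(z).mean(axis=1, keepdims=True)       # [B,1,C,1]
        e = concatenate([pooled, self.delta(rel)], axis=1)
        cw = self.scorer(e)                                    # [B,1,C,1]
        cw = cw.reshape(b, c, 1, 1)
        return y_s * cw, cw.reshape(b, c)

    def weights(self, y_s: Tensor) -> Tensor:
        return self.forward(y_s)[1]


class RGABlock(Module):
    """Sequential RGA-S → RGA-C block; either half can be disabled.

    With both halves disabled the block is the identity map.
    """

    def __init__(self, channels: int, spatial: tuple, use_spatial: bool = True,
                 use_channel: bool = True, reduction_ratio: int = 8,
                 embed_ratio: int = 8, rng: np.random.Generator | None = None,
                 bn_bypass: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spatial_att = (
            SpatialAttention(channels, spatial, reduction_ratio, embed_ratio,
                             rng, bn_bypass) if use_spatial else None
        )
        self.channel_att = (
            ChannelAttention(channels, spatial, reduction_ratio, embed_ratio,
                             rng, bn_bypass) if use_channel else None
        )

    def forward(self, x: Tensor) -> Tensor:
        if self.spatial_att is not None:
            x, _ = self.spatial_att(x)
        if self.channel_att is not None:
            x, _ = self.channel_att(x)
        return x


# -- functional wrappers (one-shot, seeded module construction) ---------------

def _batched(x) -> tuple:
    x = Tensor.as_tensor(x)
    if x.ndim == 3:
        return x.reshape(1, *x.shape), True
    return x, False


def spatial_relation_matrix(x, embed_ratio: int = 8, seed: int = 0,
                            bn_bypass: bool = False,
                            identity_embeddings: bool = False):
    """One-shot spatial relation matrix with freshly seeded embeddings."""
    x, squeeze = _batched(x)
    mod = SpatialRelation(x.shape[1], embed_ratio,
                          np.random.default_rng(seed), bn_bypass,
                          identity_embeddings)
    r = mod(x)
    return r.reshape(r.shape[1], r.shape[2]) if squeeze else r


def spatial_attention(x, reduction_ratio: int = 8, embed_ratio: int = 8,
                      seed: int = 0):
    """One-shot RGA-S pass; returns (re-weighted map, weight map)."""
    x, squeeze = _batched(x)
    mod = SpatialAttention(x.shape[1], tuple(x.shape[2:]), reduction_ratio,
                           embed_ratio, np.random.default_rng(seed))
    y, s = mod(x)
    if squeeze:
        return y.reshape(*y.shape[1:]), s.reshape(*s.shape[2:])
    return y, s


def channel_attention(y_s, reduction_ratio: int = 8, embed_ratio: int = 8,
                      seed: int = 0):
    """One-shot RGA-C pass; returns (re-weighted map, per-channel weights)."""
    y_s, squeeze = _batched(y_s)
    mod = ChannelAttention(y_s.shape[1], tuple(y_s.shape[2:]), reduction_ratio,
                           embed_ratio, np.random.default_rng(seed))
    y, c = mod(y_s)
    if squeeze:
        return y.reshape(*y.shape[1:]), c.reshape(c.shape[1])
    return y, c


def rga_block(x, use_spatial: bool = True, use_channel: bool = True,
              reduction_ratio: int = 8, embed_ratio: int = 8, seed: int = 0):
    """One-shot RGA-S → RGA-C block application."""
    x, squeeze = _batched(x)
    mod = RGABlock(x.shape[1], tuple(x.shape[2:]), use_spatial, use_channel,
                   reduction_ratio, embed_ratio, np.random.default_rng(seed))
    y = mod(x)
    return y.reshape(*y.shape[1:]) if squeeze else y
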