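"""Relation-aware attention: dot-product algebra, weight ranges, shape
preservation, and gradient reachability."""

import numpy as np
import pytest

from pestnet.attention import (ChannelAttention, ChannelRelation, RGABlock,
                               SpatialAttention, SpatialRelation,
                               spatial_relation_matrix)
from pestnet.nn import Tensor


def brute_force_relations(nodes):
    """O(N^2) double loop: R[i,j] = ReLU(x_i) . ReLU(x_j)."""
    act = np.maximum(nodes, 0.0)
    n = act.shape[1]
    r = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            r[i, j] = act[:, i] @ act[:, j]
    return r


@pytest.mark.parametrize("shape", [(4, 2, 2), (3, 4, 4), (6, 4, 2)])
def test_spatial_relation_matches_double_loop(shape, rng):
    """With identity embeddings and bypassed BN, the affinities reduce to
    ReLU'd dot products, checkable by brute force for N <= 16."""
    c, h, w = shape
    x = rng.normal(size=(1, c, h, w))
    mod = SpatialRelation(c, embed_ratio=1, rng=np.random.default_rng(0),
                          bn_bypass=True, identity_embeddings=True)
    r = mod(Tensor(x)).data[0]
    expected = brute_force_relations(x[0].reshape(c, h * w))
    assert r.shape == (h * w, h * w)
    assert np.abs(r - expected).max() < 1e-5


def test_channel_relation_matches_double_loop(rng):
    x = rng.normal(size=(1, 5, 3, 3))
    mod = ChannelRelation((3, 3), embed_ratio=1, rng=np.random.default_rng(0),
                          bn_bypass=True, identity_embeddings=True)
    r = mod(Tensor(x)).data[0]
    # nodes are channels; features are the flattened spatial values
    expected = brute_force_relations(x[0].reshape(5, 9).T)
    assert np.abs(r - expected).max() < 1e-5


def test_relation_matrix_nonnegative_and_zero_input(rng):
    x = rng.normal(size=(2, 8, 3, 3))
    mod = SpatialRelation(8, embed_ratio=2, rng=np.random.default_rng(3),
                          bn_bypass=True)
    assert mod(Tensor(x)).data.min() >= 0.0  # ReLU'd embeddings dot to >= 0
    zero = mod(Tensor(np.zeros((1, 8, 3, 3)))).data
    assert np.allclose(zero, 0.0)


def test_embed_ratio_must_divide_channels():
    with pytest.raises(ValueError):
        SpatialRelation(6, embed_ratio=4)


def test_non_finite_input_rejected():
    mod = SpatialRelation(4, embed_ratio=1)
    bad = np.zeros((1, 4, 2, 2))
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        mod(Tensor(bad))


def test_functional_relation_wrapper_shape(rng):
    x = rng.normal(size=(4, 3, 3))
    r = spatial_relation_matrix(x, embed_ratio=1, seed=0)
    assert r.shape == (9, 9)


@pytest.mark.parametrize("attention_cls", [SpatialAttention, ChannelAttention])
def test_attention_preserves_shape_and_weight_range(attention_cls, rng):
    x = rng.normal(size=(2, 8, 4, 4)) * 3
    mod = attention_cls(8, (4, 4), reduction_ratio=4, embed_ratio=2,
                        rng=np.random.default_rng(1))
    mod.eval()
    y, w = mod(Tensor(x))
    assert y.shape == x.shape
    assert np.all(np.isfinite(y.data))
    assert np.all(w.data > 0.0) and np.all(w.data < 1.0)  # strict sigmoid range


def test_spatial_attention_is_per_position_rescaling(rng):
    """Y[:, i] / x[:, i] must be one scalar per position, shared by channels."""
    x = rng.normal(size=(1, 6, 3, 3))
    x[np.abs(x) < 1e-3] += 0.1
    mod = SpatialAttention(6, (3, 3), reduction_ratio=2, embed_ratio=2,
                           rng=np.random.default_rng(2))
    mod.eval()
    y, s = mod(Tensor(x))
    ratio = y.data / x.data  # [1, C, H, W]
    assert np.allclose(ratio, ratio[:, :1], atol=1e-10)
    assert np.allclose(ratio[0, 0], s.data[0, 0], atol=1e-10)


def test_channel_attention_is_per_channel_rescaling(rng):
    x = rng.normal(size=(1, 5, 4, 4))
    x[np.abs(x) < 1e-3] += 0.1
    mod = ChannelAttention(5, (4, 4), reduction_ratio=2, embed_ratio=2,
                           rng=np.random.default_rng(2))
    mod.eval()
    y, c = mod(Tensor(x))
    ratio = y.data / x.data
    # constant over each channel slice
    assert np.allclose(ratio, ratio[:, :, :1, :1], atol=1e-10)
    assert np.allclose(ratio[0, :, 0, 0], c.data[0], atol=1e-10)


def test_single_node_degenerate_cases(rng):
    """H·W = 1 (spatial) and C = 1 (channel) are valid single-node graphs."""
    x = rng.normal(size=(1, 4, 1, 1))
    sa = SpatialAttention(4, (1, 1), reduction_ratio=2, embed_ratio=2,
                          rng=np.random.default_rng(0))
    y, s = sa(Tensor(x))
    assert y.shape == x.shape and s.data.size == 1
    xc = rng.normal(size=(1, 1, 3, 3))
    ca = ChannelAttention(1, (3, 3), reduction_ratio=2, embed_ratio=2,
                          rng=np.random.default_rng(0))
    y2, c = ca(Tensor(xc))
    assert y2.shape == xc.shape and c.data.size == 1


def test_block_identity_config_reproduces_input(rng):
    x = Tensor(rng.normal(size=(1, 4, 3, 3)))
    block = RGABlock(4, (3, 3), use_spatial=False, use_channel=False)
    assert block(x) is x


def test_block_deterministic_with_frozen_parameters(rng):
    x = Tensor(rng.normal(size=(2, 4, 3, 3)))
    block = RGABlock(4, (3, 3), reduction_ratio=2, embed_ratio=2,
                     rng=np.random.default_rng(9))
    block.eval()
    y1, y2 = block(x), block(x)
    assert np.array_equal(y1.data, y2.data)


def test_gradient_reaches_every_block_parameter(rng):
    """A scalar loss downstream of the block must move every embedding and
    scoring parameter; spot-checked against finite differences."""
    x = Tensor(rng.normal(size=(1, 2, 3, 3)))
    block = RGABlock(2, (3, 3), reduction_ratio=2, embed_ratio=1,
                     rng=np.random.default_rng(4))
    # train-mode BN centres activations, so no embedding can go entirely
    # ReLU-dead; train-mode output is a pure function of parameters (the
    # running buffers it updates are only read in eval mode)

    def loss_value():
        return (block(x) ** 2).sum().item()

    (block(x) ** 2).sum().backward()
    named = list(block.named_parameters())
    assert named, "block exposes parameters"
    for name, p in named:
        assert p.grad is not None, name
        assert np.any(p.grad != 0.0) or "bn2" in name or "beta" in name, name

    # finite-difference spot check on one embedding weight per submodule
    for p in (block.spatial_att.relation.theta.layers[0].weight,
              block.channel_att.scorer.conv1.weight):
        i = np.unravel_index(np.argmax(np.abs(p.grad)), p.grad.shape)
        eps = 1e-6
        orig = p.data[i]
        p.data[i] = orig + eps
        up = loss_value()
        p.data[i] = orig - eps
        dn = loss_value()
        p.data[i] = orig
        num = (up - dn) / (2 * eps)
        assert np.isclose(p.grad[i], num, rtol=1e-4, atol=1e-8)
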