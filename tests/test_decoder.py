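"""GFI skip module, decoder blocks, head, and the end-to-end network."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from rmtfnet.autograd import Tensor
from rmtfnet.decoder import (GFI, DecoderBlock, RMTFNet, RMTFNetConfig,
                             SegmentationHead, rmtf_forward)
from rmtfnet.losses import LossWeights, SSIMParams, hybrid_loss
from rmtfnet.nn import Adam

rng = np.random.default_rng(21)


# -------------------------------------------------------------------- GFI
def test_gfi_output_channels_track_x_for_mismatched_c():
    gfi = GFI(x_channels=32, c_channels=48, rng=rng)
    out = gfi(rng.normal(size=(1, 32, 8, 8)), rng.normal(size=(1, 48, 8, 8)))
    assert out.shape == (1, 32, 8, 8)


def test_gfi_zeroed_kernels_give_zero_map():
    gfi = GFI(4, 4, rng=rng)
    for p in gfi.parameters():
        p.data = np.zeros_like(p.data)
    out = gfi(rng.normal(size=(1, 4, 6, 6)), rng.normal(size=(1, 4, 6, 6)))
    np.testing.assert_allclose(out.data, 0.0)


def test_gfi_matches_manual_convolution_chain():
    """1-channel X=C with identity-like kernels vs hand-computed
    add -> conv -> concat -> conv."""
    gfi = GFI(1, 1, rng=rng)
    X = rng.normal(size=(3, 3))
    ki = gfi.conv_inner.weight.data[0, 0]
    ko = gfi.conv_outer.weight.data          # (1, 2, 3, 3)
    bi = gfi.conv_inner.bias.data[0]
    bo = gfi.conv_outer.bias.data[0]

    inner = correlate2d(X + X, ki, mode="same") + bi
    want = (correlate2d(X, ko[0, 0], mode="same")
            + correlate2d(inner, ko[0, 1], mode="same") + bo)
    got = gfi(X[None, None], X[None, None]).data[0, 0]
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_gfi_rejects_spatial_mismatch():
    gfi = GFI(4, 4, rng=rng)
    with pytest.raises(ValueError):
        gfi(np.zeros((1, 4, 8, 8)), np.zeros((1, 4, 4, 4)))


# ------------------------------------------------------------ decoder block
def test_decoder_block_doubles_and_rectifies():
    block = DecoderBlock(64, 0, 16, rng=rng)
    block.eval()
    out = block(rng.normal(size=(1, 64, 8, 8)))
    assert out.shape == (1, 16, 16, 16)
    assert (out.data >= 0).all()


def test_decoder_block_matches_manual_conv_arithmetic():
    """Eval mode, BN statistics frozen at identity, hand-checked convs."""
    block = DecoderBlock(1, 0, 1, rng=rng)
    block.eval()
    for bn in (block.bn1, block.bn2):
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 1.0 - bn.eps     # so sqrt(var + eps) == 1
    x = rng.normal(size=(1, 1, 4, 4))
    from rmtfnet.fusion_encoder import upsample2
    up = upsample2(x).data[0, 0]
    k1 = block.conv1.weight.data[0, 0]
    k2 = block.conv2.weight.data[0, 0]
    h = np.maximum(correlate2d(up, k1, mode="same"), 0.0)
    want = np.maximum(correlate2d(h, k2, mode="same"), 0.0)
    np.testing.assert_allclose(block(x).data[0, 0], want, atol=1e-10)


def test_decoder_block_rejects_misaligned_skip():
    block = DecoderBlock(8, 4, 8, rng=rng)
    with pytest.raises(ValueError):
        block(np.zeros((1, 8, 8, 8)), np.zeros((1, 4, 8, 8)))


# ------------------------------------------------------------------- head
def test_head_restores_full_resolution():
    head = SegmentationHead(32, rng=rng)
    assert head(rng.normal(size=(1, 32, 128, 128))).shape == (1, 1, 256, 256)


def test_head_zero_kernel_gives_constant_bias_map():
    head = SegmentationHead(4, rng=rng)
    head.conv.weight.data = np.zeros_like(head.conv.weight.data)
    head.conv.bias.data[:] = -1.5
    out = head(rng.normal(size=(1, 4, 8, 8)))
    np.testing.assert_allclose(out.data, -1.5)


# ------------------------------------------------------------- full model
def test_end_to_end_shape_and_batch_independence():
    net = RMTFNet(RMTFNetConfig.tiny(), rng=np.random.default_rng(2))
    net.eval()
    img = rng.uniform(size=(1, 3, 64, 64))
    out1 = net(img)
    assert out1.shape == (1, 1, 64, 64)
    both = net(np.concatenate([img, img], axis=0))
    np.testing.assert_allclose(both.data[0], both.data[1], atol=1e-12)


def test_indivisible_input_rejected():
    net = RMTFNet(RMTFNetConfig.tiny(), rng=np.random.default_rng(2))
    with pytest.raises(ValueError):
        net(np.zeros((1, 3, 60, 60)))


def test_every_skip_influences_logits():
    net = RMTFNet(RMTFNetConfig.tiny(), rng=np.random.default_rng(2))
    net.eval()
    img = rng.uniform(size=(1, 3, 64, 64))
    skips = net.encode(img)

    def decode(skips):
        x = skips[3]
        for i, block in enumerate(net.decoder):
            x = block(x, skips[2 - i] if i < 3 else None)
        return net.head(x).data

    base = decode(skips)
    for i in range(4):
        mutated = list(skips)
        mutated[i] = Tensor(np.zeros_like(skips[i].data))
        assert np.abs(decode(mutated) - base).max() > 1e-8, f"skip {i} unused"


def test_all_parameters_receive_finite_gradients():
    net = RMTFNet(RMTFNetConfig.tiny(), rng=np.random.default_rng(2))
    net.train()
    img = rng.uniform(size=(2, 3, 64, 64))
    mask = (rng.uniform(size=(2, 1, 64, 64)) > 0.8).astype(float)
    loss = hybrid_loss(net(img).sigmoid(), mask)
    loss.backward()
    grads = [p.grad for p in net.parameters()]
    assert all(g is not None and np.isfinite(g).all() for g in grads)


def test_single_optimization_step_decreases_hybrid_loss(phantom_batch):
    imgs, msks = phantom_batch
    net = RMTFNet(RMTFNetConfig.tiny(), rng=np.random.default_rng(4))
    net.train()
    opt = Adam(net.parameters(), lr=1e-4)

    def loss_value():
        return hybrid_loss(net(imgs[:2]).sigmoid(), msks[:2])

    l0 = loss_value()
    l0.backward()
    opt.step()
    net.zero_grad()
    assert loss_value().item() < l0.item()


@pytest.mark.parametrize("variant", ["backbone", "mit_only", "rcnn_only"])
def test_ablation_variants_run_and_shrink(variant):
    full = RMTFNet(RMTFNetConfig.tiny("full"), rng=np.random.default_rng(0))
    abl = RMTFNet(RMTFNetConfig.tiny(variant), rng=np.random.default_rng(0))
    abl.eval()
    out = abl(rng.uniform(size=(1, 3, 64, 64)))
    assert out.shape == (1, 1, 64, 64)
    assert abl.n_parameters() < full.n_parameters()


def test_backbone_skips_are_fused_maps():
    net = RMTFNet(RMTFNetConfig.tiny("backbone"), rng=np.random.default_rng(0))
    assert net.gfis is None
    assert net.skip_channels == net.cfg.rcnn_channels


def test_predict_mask_is_binary():
    net = RMTFNet(RMTFNetConfig.tiny(), rng=np.random.default_rng(2))
    mask = net.predict_mask(rng.uniform(size=(1, 3, 64, 64)))
    assert set(np.unique(mask)) <= {0, 1}
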