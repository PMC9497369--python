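"""Hybrid loss terms against closed forms and brute-force oracles."""

import numpy as np
import pytest

from rmtfnet.autograd import Tensor
from rmtfnet.losses import (LossWeights, SSIMParams, bce_loss,
                            dice_coefficient, dice_loss, hybrid_loss,
                            ssim_loss, ssim_map)
from rmtfnet.metrics import dice_iou

rng = np.random.default_rng(33)


# ------------------------------------------------------------------- dice
def test_dice_perfect_prediction():
    t = (rng.uniform(size=(16, 16)) > 0.7).astype(float)
    assert dice_coefficient(t, t).item() == pytest.approx(1.0, abs=1e-6)
    assert dice_loss(t, t).item() == pytest.approx(0.0, abs=1e-6)


def test_dice_disjoint_masks_near_zero():
    t = np.zeros((8, 8))
    e = np.zeros((8, 8))
    t[:4] = 1.0
    e[4:] = 1.0
    assert dice_coefficient(e, t).item() == pytest.approx(0.0, abs=1e-6)
    assert dice_loss(e, t).item() == pytest.approx(1.0, abs=1e-6)


def test_dice_pixel_counting_example():
    """gt has 4 foreground pixels, prediction hits 2 of them: 2*2/(4+2)."""
    t = np.zeros((4, 4))
    t[0, :4] = 1.0
    e = np.zeros((4, 4))
    e[0, :2] = 1.0
    assert dice_coefficient(e, t).item() == pytest.approx(2 * 2 / 6, abs=1e-6)
    assert dice_loss(e, t).item() == pytest.approx(1 - 2 * 2 / 6, abs=1e-6)


def test_dice_equals_iou_identity_on_random_binary_pairs():
    for _ in range(50):
        a = (rng.uniform(size=(12, 12)) > 0.5).astype(float)
        b = (rng.uniform(size=(12, 12)) > 0.5).astype(float)
        soft = dice_coefficient(a, b).item()
        _, iou = dice_iou(a, b)
        assert soft == pytest.approx(2 * iou / (1 + iou), abs=1e-4)


def test_dice_rejects_shape_mismatch():
    with pytest.raises(ValueError):
        dice_loss(np.zeros((4, 4)), np.zeros((4, 5)))


# -------------------------------------------------------------------- bce
def test_bce_half_probability_closed_form():
    t = np.ones((8, 8))
    e = np.full((8, 8), 0.5)
    assert bce_loss(e, t).item() == pytest.approx(np.log(2), abs=1e-10)


def test_bce_perfect_prediction_bounded_by_clip():
    t = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
    assert bce_loss(t, t).item() < -np.log(1 - 1e-7) + 1e-12


def test_bce_label_symmetry():
    t = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
    e = rng.uniform(0.05, 0.95, size=(8, 8))
    assert bce_loss(e, t).item() == pytest.approx(
        bce_loss(1 - e, 1 - t).item(), abs=1e-12)


# ------------------------------------------------------------------- ssim
def brute_force_ssim(I1, I2, params: SSIMParams):
    """Loop over every valid window, computing the windowed statistics
    directly from the definition."""
    w = params.window_size
    ax = np.arange(w) - (w - 1) / 2
    g = np.exp(-(ax**2) / (2 * params.window_sigma**2))
    kern = np.outer(g, g)
    kern /= kern.sum()
    H, W = I1.shape
    out = np.zeros((H - w + 1, W - w + 1))
    for i in range(H - w + 1):
        for j in range(W - w + 1):
            p1 = I1[i:i + w, j:j + w]
            p2 = I2[i:i + w, j:j + w]
            mu1 = (kern * p1).sum()
            mu2 = (kern * p2).sum()
            v1 = (kern * (p1 - mu1) ** 2).sum()
            v2 = (kern * (p2 - mu2) ** 2).sum()
            cov = (kern * (p1 - mu1) * (p2 - mu2)).sum()
            out[i, j] = (((2 * mu1 * mu2 + params.C1) * (2 * cov + params.C2))
                         / ((mu1**2 + mu2**2 + params.C1)
                            * (v1 + v2 + params.C2)))
    return out


def test_ssim_identical_images():
    img = rng.uniform(size=(16, 16))
    assert np.allclose(ssim_map(img, img).data, 1.0, atol=1e-9)
    assert ssim_loss(img, img).item() == pytest.approx(0.0, abs=1e-9)


def test_ssim_constant_images():
    a = np.full((16, 16), 0.4)
    assert np.allclose(ssim_map(a, a.copy()).data, 1.0)


def test_ssim_matches_brute_force_oracle():
    params = SSIMParams(window_size=7, window_sigma=1.5)
    for _ in range(10):
        I1 = rng.uniform(size=(16, 16))
        I2 = rng.uniform(size=(16, 16))
        got = ssim_map(I1, I2, params).data[0, 0]
        want = brute_force_ssim(I1, I2, params)
        np.testing.assert_allclose(got, want, atol=1e-6)
        assert ssim_loss(I1, I2, params).item() == pytest.approx(
            1 - want.mean(), abs=1e-6)


def test_ssim_loss_range_and_window_check():
    I1 = rng.uniform(size=(16, 16))
    I2 = rng.uniform(size=(16, 16))
    assert 0.0 <= ssim_loss(I1, I2).item() <= 2.0
    with pytest.raises(ValueError):
        ssim_map(np.zeros((8, 8)), np.zeros((8, 8)), SSIMParams(window_size=11))
    with pytest.raises(ValueError):
        SSIMParams(window_size=4)


# ----------------------------------------------------------------- hybrid
def test_hybrid_weight_selection_and_homogeneity():
    t = (rng.uniform(size=(16, 16)) > 0.7).astype(float)
    e = rng.uniform(size=(16, 16))
    only_dice = hybrid_loss(e, t, LossWeights(1, 0, 0)).item()
    assert only_dice == pytest.approx(dice_loss(e, t).item(), abs=1e-12)
    single = hybrid_loss(e, t, LossWeights(1, 1, 1)).item()
    double = hybrid_loss(e, t, LossWeights(2, 2, 2)).item()
    assert double == pytest.approx(2 * single, rel=1e-12)


def test_hybrid_vanishes_at_perfect_prediction():
    t = (rng.uniform(size=(16, 16)) > 0.7).astype(float)
    assert hybrid_loss(t, t).item() == pytest.approx(0.0, abs=1e-5)


def test_all_zero_weights_rejected():
    with pytest.raises(ValueError):
        LossWeights(0, 0, 0)
    with pytest.raises(ValueError):
        LossWeights(-1, 1, 1)


def test_loss_terms_nonnegative_with_finite_gradients():
    t = (rng.uniform(size=(12, 12)) > 0.6).astype(float)
    e = Tensor(rng.uniform(0.01, 0.99, size=(12, 12)), requires_grad=True)
    for fn in (dice_loss, bce_loss, ssim_loss):
        e.grad = None
        val = fn(e, t)
        assert val.item() >= 0.0
        val.backward()
        assert np.isfinite(e.grad).all()
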