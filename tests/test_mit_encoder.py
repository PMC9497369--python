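"""Mix-transformer encoder: patch grids, attention oracle, pyramid contract."""

import numpy as np
import pytest

from rmtfnet.autograd import Tensor
from rmtfnet.mit_encoder import (EfficientSelfAttention, MiTConfig, MixFFN,
                                 MixTransformer, OverlapPatchEmbed,
                                 StageConfig, TokenMap, mit_forward)

rng = np.random.default_rng(7)


# ------------------------------------------------------- patch embedding
@pytest.mark.parametrize("H,K,S,P,expected", [
    (256, 7, 4, 3, 64),    # stage-1 grid: quarter resolution
    (64, 3, 2, 1, 32),     # later-stage grid: floor((64+2-3)/2)+1
    (5, 5, 1, 0, 1),       # H = K degenerate single-token grid
])
def test_patch_grid_size(H, K, S, P, expected):
    embed = OverlapPatchEmbed(3, 8, K, S, P, rng=rng)
    t = embed(rng.uniform(size=(1, 3, H, H)))
    assert (t.height, t.width) == (expected, expected)
    assert t.n_tokens == expected * expected


def test_patch_embed_rejects_too_small_input():
    embed = OverlapPatchEmbed(3, 8, kernel=7, stride=4, pad=0, rng=rng)
    with pytest.raises(ValueError):
        embed(np.zeros((1, 3, 4, 4)))


def test_token_map_requires_consistent_grid():
    with pytest.raises(ValueError):
        TokenMap(np.zeros((1, 10, 4)), height=3, width=3)


# ------------------------------------------------------------- attention
def naive_multihead_attention(tokens, attn: EfficientSelfAttention):
    """Independent O(N^2) full attention using the module's own weights."""
    B, N, C = tokens.shape
    h = attn.heads
    hd = C // h
    q = tokens @ attn.q.weight.data + attn.q.bias.data
    kv = tokens @ attn.kv.weight.data + attn.kv.bias.data
    k, v = kv[:, :, :C], kv[:, :, C:]
    out = np.zeros_like(tokens)
    for b in range(B):
        heads = []
        for i in range(h):
            sl = slice(i * hd, (i + 1) * hd)
            qi, ki, vi = q[b, :, sl], k[b, :, sl], v[b, :, sl]
            scores = qi @ ki.T / np.sqrt(hd)
            scores = scores - scores.max(axis=1, keepdims=True)
            w = np.exp(scores)
            w /= w.sum(axis=1, keepdims=True)
            heads.append(w @ vi)
        out[b] = np.concatenate(heads, axis=1)
    return out @ attn.proj.weight.data + attn.proj.bias.data


def test_attention_r1_matches_naive_full_attention():
    attn = EfficientSelfAttention(dim=8, heads=2, reduction=1, rng=rng)
    tokens = rng.normal(size=(2, 16, 8))
    got = attn(TokenMap(tokens, 4, 4)).tokens.data
    want = naive_multihead_attention(tokens, attn)
    rel = np.abs(got - want).max() / np.abs(want).max()
    assert rel < 1e-5


@pytest.mark.parametrize("R,N", [(4, 64), (16, 64), (64, 4096)])
def test_key_value_sequence_reduced_to_n_over_r(R, N):
    side = int(np.sqrt(N))
    attn = EfficientSelfAttention(dim=8, heads=2, reduction=R, rng=rng)
    attn(TokenMap(rng.normal(size=(1, N, 8)), side, side))
    assert attn.last_scores_shape == (N, N // R)


def test_attention_rows_are_probability_distributions():
    attn = EfficientSelfAttention(dim=8, heads=2, reduction=4, rng=rng)
    attn(TokenMap(rng.normal(size=(1, 16, 8)), 4, 4))
    rows = attn.last_attn
    np.testing.assert_allclose(rows.sum(axis=-1), 1.0, atol=1e-12)
    assert (rows >= 0).all()


def test_attention_rejects_indivisible_token_count():
    attn = EfficientSelfAttention(dim=8, heads=2, reduction=4, rng=rng)
    with pytest.raises(ValueError):
        attn(TokenMap(rng.normal(size=(1, 6, 8)), 2, 3))


# --------------------------------------------------------------- Mix-FFN
def test_mix_ffn_preserves_shape():
    ffn = MixFFN(dim=6, mlp_ratio=4, rng=rng)
    t = TokenMap(rng.normal(size=(2, 16, 6)), 4, 4)
    out = ffn(t)
    assert out.tokens.shape == t.tokens.shape


def test_mix_ffn_zeroed_weights_is_identity():
    ffn = MixFFN(dim=4, mlp_ratio=2, rng=rng)
    for p in ffn.parameters():
        p.data = np.zeros_like(p.data)
    t = TokenMap(rng.normal(size=(1, 9, 4)), 3, 3)
    np.testing.assert_allclose(ffn(t).tokens.data, t.tokens.data)


def test_mix_ffn_matches_manual_composition():
    """Hand-evaluated expand -> depthwise 3x3 conv -> GELU -> contract (+x)."""
    from scipy.signal import correlate2d
    from scipy.special import erf

    ffn = MixFFN(dim=2, mlp_ratio=2, rng=rng)
    tokens = rng.normal(size=(1, 4, 2))       # 2x2 grid, C=2, hidden=4
    t = TokenMap(tokens, 2, 2)
    got = ffn(t).tokens.data

    x = tokens[0] @ ffn.fc1.weight.data + ffn.fc1.bias.data     # (4, 4)
    grid = x.T.reshape(4, 2, 2)
    conv = np.stack([
        correlate2d(grid[c], ffn.dwconv.weight.data[c, 0], mode="same")
        + ffn.dwconv.bias.data[c]
        for c in range(4)])
    y = conv.reshape(4, 4).T
    y = 0.5 * y * (1 + erf(y / np.sqrt(2)))
    y = y @ ffn.fc2.weight.data + ffn.fc2.bias.data
    np.testing.assert_allclose(got[0], tokens[0] + y, atol=1e-10)


# ------------------------------------------------------------ full encoder
def test_pyramid_resolutions_and_channels():
    cfg = MiTConfig.tiny()
    pyr = mit_forward(rng.uniform(size=(2, 3, 256, 256)), cfg, seed=0)
    sizes = [m.shape[2] for m in pyr]
    chans = [m.shape[1] for m in pyr]
    assert sizes == [64, 32, 16, 8]
    assert chans == sorted(chans) and len(set(chans)) == 4
    assert all(np.isfinite(m.data).all() for m in pyr)
    assert all(m.shape[0] == 2 for m in pyr)


def test_resolution_cascade_other_input_size():
    pyr = mit_forward(rng.uniform(size=(1, 3, 96, 64)), MiTConfig.tiny(), seed=0)
    assert [m.shape[2:] for m in pyr] == [(24, 16), (12, 8), (6, 4), (3, 2)]


def test_indivisible_input_rejected():
    with pytest.raises(ValueError):
        mit_forward(np.zeros((1, 3, 100, 100)), MiTConfig.tiny())


def test_batch_independence():
    model = MixTransformer(MiTConfig.tiny(), rng=np.random.default_rng(5))
    model.eval()
    img = rng.uniform(size=(1, 3, 64, 64))
    single = model(img)
    double = model(np.concatenate([img, img], axis=0))
    for s, d in zip(single, double):
        np.testing.assert_allclose(d.data[0], s.data[0], atol=1e-12)
        np.testing.assert_allclose(d.data[1], s.data[0], atol=1e-12)


def test_fixed_seed_is_bitwise_stable():
    img = rng.uniform(size=(1, 3, 64, 64))
    a = mit_forward(img, MiTConfig.tiny(), seed=9)
    b = mit_forward(img, MiTConfig.tiny(), seed=9)
    for ma, mb in zip(a, b):
        assert np.array_equal(ma.data, mb.data)


def test_stage_config_validation():
    with pytest.raises(ValueError):
        StageConfig(3, 4, 1, 8, 1, 2, 4)      # stride > kernel
    with pytest.raises(ValueError):
        StageConfig(3, 2, 1, 9, 1, 2, 4)      # dim not divisible by heads
    with pytest.raises(ValueError):
        StageConfig(3, 2, 1, 8, 1, 2, 8)      # R not a perfect square
    with pytest.raises(ValueError):           # channels must increase
        MiTConfig(stages=tuple(
            StageConfig(3, 2, 1, 8, 1, 2, r) for r in (64, 16, 4, 1)))


def test_default_reductions_are_64_16_4_1():
    cfg = MiTConfig.build("B")
    assert tuple(s.reduction for s in cfg.stages) == (64, 16, 4, 1)
    assert cfg.embed_dims == (64, 128, 320, 512)
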