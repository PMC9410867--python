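"""Channel-fusion and grouped spatial attention against nested-loop oracles."""

import numpy as np
import pytest

from ribfrac.nn import ChannelFusionAttention, SpatialGroupAttention, global_average_pool


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_channel_attention(f_e, f_d, w, b):
    """Direct evaluation: GAP both maps, concatenate, slide a 1D kernel with
    same-padding, sigmoid, split C/C, rescale each input per channel."""
    n_batch, c = f_e.shape[:2]
    k = len(w)
    p = (k - 1) // 2
    out_e = np.empty_like(f_e)
    out_d = np.empty_like(f_d)
    for n in range(n_batch):
        s = np.concatenate(
            [
                [f_e[n, ch].mean() for ch in range(c)],
                [f_d[n, ch].mean() for ch in range(c)],
            ]
        )
        sp = np.concatenate([np.zeros(p), s, np.zeros(p)])
        conv = np.array([sum(sp[i + j] * w[j] for j in range(k)) + b for i in range(2 * c)])
        gates = _sigmoid(conv)
        for ch in range(c):
            out_e[n, ch] = f_e[n, ch] * gates[ch]
            out_d[n, ch] = f_d[n, ch] * gates[c + ch]
    return out_e, out_d


def oracle_spatial_attention(f, proj_w, proj_b, spat_w, spat_b, groups):
    """Direct evaluation: per group, 1x1x1 projection to one channel, 7^3 (or
    k^3) convolution with same-padding, sigmoid, broadcast-multiply."""
    n_batch, c, L, W, H = f.shape
    cg = c // groups
    k = spat_w[0].shape[-1]
    p = (k - 1) // 2
    out = np.empty_like(f)
    for n in range(n_batch):
        for g in range(groups):
            fg = f[n, g * cg : (g + 1) * cg]
            s = np.tensordot(proj_w[g], fg, axes=([0], [0])) + proj_b[g]
            sp = np.pad(s, p)
            m = np.zeros((L, W, H))
            for i in range(L):
                for j in range(W):
                    for l in range(H):
                        acc = 0.0
                        for a in range(k):
                            for bb in range(k):
                                for cc in range(k):
                                    acc += sp[i + a, j + bb, l + cc] * spat_w[g][a, bb, cc]
                        m[i, j, l] = _sigmoid(acc + spat_b[g])
            out[n, g * cg : (g + 1) * cg] = fg * m
    return out


def test_gap_is_channel_mean(rng):
    f = rng.normal(size=(2, 3, 2, 2, 2))
    got = global_average_pool(f)
    assert got[1, 2] == pytest.approx(f[1, 2].mean())
    f0 = np.arange(8, dtype=float).reshape(1, 1, 2, 2, 2)
    assert global_average_pool(f0)[0, 0] == pytest.approx(3.5)
    assert (global_average_pool(np.zeros((1, 4, 2, 2, 2))) == 0).all()


@pytest.mark.parametrize("c,kernel", [(2, 3), (4, 5), (3, 3)])
def test_channel_attention_matches_oracle(rng, c, kernel):
    mod = ChannelFusionAttention(c, kernel, shared=True, rng=np.random.default_rng(0))
    w = rng.normal(size=kernel)
    b = float(rng.normal())
    mod.conv_e.w.value = w.copy()
    mod.conv_e.b.value = np.array([b])
    f_e = rng.normal(size=(2, c, 3, 4, 2))
    f_d = rng.normal(size=(2, c, 3, 4, 2))
    got_e, got_d = mod.forward(f_e, f_d, training=False)
    exp_e, exp_d = oracle_channel_attention(f_e, f_d, w, b)
    np.testing.assert_allclose(got_e, exp_e, atol=1e-5)
    np.testing.assert_allclose(got_d, exp_d, atol=1e-5)


def test_channel_attention_zero_weights_halve_features(rng):
    mod = ChannelFusionAttention(3, 5, rng=np.random.default_rng(0))
    mod.conv_e.w.value[:] = 0.0
    mod.conv_e.b.value[:] = 0.0
    f_e = rng.normal(size=(1, 3, 2, 2, 2))
    f_d = rng.normal(size=(1, 3, 2, 2, 2))
    out_e, out_d = mod.forward(f_e, f_d, training=False)
    np.testing.assert_allclose(out_e, 0.5 * f_e, atol=1e-7)
    np.testing.assert_allclose(out_d, 0.5 * f_d, atol=1e-7)


def test_channel_attention_rejects_mismatched_pair(rng):
    mod = ChannelFusionAttention(2, 3, rng=np.random.default_rng(0))
    with pytest.raises(ValueError, match="mismatch"):
        mod.forward(rng.normal(size=(1, 2, 2, 2, 2)), rng.normal(size=(1, 2, 3, 2, 2)))


@pytest.mark.parametrize("c,groups,kernel", [(4, 4, 7), (4, 2, 3), (2, 1, 7)])
def test_spatial_attention_matches_oracle(rng, c, groups, kernel):
    mod = SpatialGroupAttention(c, groups, rng=np.random.default_rng(0))
    cg = c // groups
    proj_w, proj_b, spat_w, spat_b = [], [], [], []
    for g in range(groups):
        mod.spatial[g] = type(mod.spatial[g])(1, 1, kernel=kernel, pad=(kernel - 1) // 2,
                                              rng=np.random.default_rng(g))
        pw = rng.normal(size=cg)
        pb = float(rng.normal())
        sw = rng.normal(size=(kernel, kernel, kernel))
        sb = float(rng.normal())
        mod.proj[g].w.value = pw.reshape(1, cg, 1, 1, 1).copy()
        mod.proj[g].b.value = np.array([pb])
        mod.spatial[g].w.value = sw.reshape(1, 1, kernel, kernel, kernel).copy()
        mod.spatial[g].b.value = np.array([sb])
        proj_w.append(pw)
        proj_b.append(pb)
        spat_w.append(sw)
        spat_b.append(sb)
    f = rng.normal(size=(1, c, 3, 3, 3))
    got = mod.forward(f, training=False)
    exp = oracle_spatial_attention(f, proj_w, proj_b, spat_w, spat_b, groups)
    np.testing.assert_allclose(got, exp, atol=1e-5)


def test_spatial_attention_zero_weights_halve_features(rng):
    mod = SpatialGroupAttention(4, 4, rng=np.random.default_rng(0))
    for g in range(4):
        mod.proj[g].w.value[:] = 0.0
        mod.proj[g].b.value[:] = 0.0
        mod.spatial[g].w.value[:] = 0.0
        mod.spatial[g].b.value[:] = 0.0
    f = rng.normal(size=(2, 4, 3, 3, 3))
    np.testing.assert_allclose(mod.forward(f, training=False), 0.5 * f, atol=1e-7)


def test_spatial_attention_group_independence(rng):
    """Zeroing the weights of group j only changes that group's output channels."""
    f = rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float64)
    base = SpatialGroupAttention(8, 4, rng=np.random.default_rng(7))
    ref = base.forward(f, training=False)
    j = 2
    base.proj[j].w.value[:] = 0.0
    base.spatial[j].w.value[:] = 0.0
    mod_out = base.forward(f, training=False)
    cg = 2
    for g in range(4):
        sl = slice(g * cg, (g + 1) * cg)
        if g == j:
            assert not np.allclose(mod_out[:, sl], ref[:, sl])
        else:
            np.testing.assert_array_equal(mod_out[:, sl], ref[:, sl])


def test_spatial_attention_invalid_groups():
    with pytest.raises(ValueError, match="does not divide"):
        SpatialGroupAttention(6, 4, rng=np.random.default_rng(0))


def test_attention_is_strictly_shrinking(rng):
    """Gates in (0,1): outputs keep the sign and strictly shrink nonzero values."""
    cmod = ChannelFusionAttention(4, 5, rng=np.random.default_rng(1))
    smod = SpatialGroupAttention(4, 2, rng=np.random.default_rng(2))
    f_e = rng.normal(size=(2, 4, 3, 3, 3))
    f_d = rng.normal(size=(2, 4, 3, 3, 3))
    out_e, out_d = cmod.forward(f_e, f_d, training=False)
    s_out = smod.forward(f_e, training=False)
    for out, ref in [(out_e, f_e), (out_d, f_d), (s_out, f_e)]:
        assert (np.sign(out) == np.sign(ref)).all()
        nz = ref != 0
        assert (np.abs(out[nz]) < np.abs(ref[nz])).all()
        assert out.shape == ref.shape
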