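"""Architecture contracts: shapes, attention math, fusion, classifier."""

import numpy as np
import pytest

from npcstage.networks import (
    Backbone3D,
    Classifier,
    FFAModule,
    MultiTaskModel,
    NetConfig,
    SegNet3D,
    ShapeConfigError,
    mask_apply,
    seg_forward,
)
from npcstage.nn import MultiHeadSelfAttention3d, Tensor

TINY = NetConfig(input_shape=(8, 16, 16), base_channels=2, channel_cap=8, backbone_width=4)


def two_loop_attention_oracle(x, wq, wk, wv, wo, pos, heads):
    """Independent O(L^2) attention implementation with explicit loops."""
    n, length, c = x.shape
    hd = c // heads
    q = x @ wq[0] + wq[1]
    k = x @ wk[0] + wk[1]
    v = x @ wv[0] + wv[1]
    out = np.zeros((n, length, c))
    for b in range(n):
        for h in range(heads):
            sl = slice(h * hd, (h + 1) * hd)
            for i in range(length):
                logits = np.empty(length)
                for j in range(length):
                    logits[j] = (q[b, i, sl] @ k[b, j, sl] + q[b, i, sl] @ pos[j, sl]) / np.sqrt(hd)
                weights = np.exp(logits - logits.max())
                weights /= weights.sum()
                for j in range(length):
                    out[b, i, sl] += weights[j] * v[b, j, sl]
    return out @ wo[0] + wo[1]


class TestSegNet:
    def test_prob_map_shape_and_range(self, rng):
        out = seg_forward(rng.standard_normal((8, 16, 16)), TINY)
        assert out.prob_map.shape == (1, 1, 8, 16, 16)
        assert (out.prob_map.data >= 0).all() and (out.prob_map.data <= 1).all()

    def test_zeroed_head_outputs_half_everywhere(self, rng):
        net = SegNet3D(TINY, np.random.default_rng(0))
        net.head.weight.data[:] = 0
        net.head.bias.data[:] = 0
        out = net(Tensor(rng.standard_normal((1, 1, 8, 16, 16)).astype(np.float32)))
        np.testing.assert_allclose(out.prob_map.data, 0.5, atol=1e-7)

    def test_tap_resolutions_follow_schedule(self, rng):
        cfg = TINY.resolved()
        out = seg_forward(rng.standard_normal((8, 16, 16)), cfg)
        sizes = [list(cfg.input_shape)]
        for pools in cfg.seg_pools:
            sizes.append([s // f for s, f in zip(sizes[-1], pools)])
        # taps: seventh encoder (pre-pool 7), eighth encoder and first decoder (deepest)
        assert list(out.tap_e7.shape[2:]) == sizes[6]
        assert list(out.tap_e8.shape[2:]) == sizes[7]
        assert list(out.tap_d1.shape[2:]) == sizes[6]

    def test_incompatible_shape_names_axis(self, rng):
        net = SegNet3D(TINY, np.random.default_rng(0))
        with pytest.raises(ShapeConfigError, match="row|slice|column"):
            net(Tensor(np.zeros((1, 1, 8, 20, 16), dtype=np.float32)))

    def test_bad_pool_factor_rejected(self):
        cfg = NetConfig(input_shape=(8, 16, 16), seg_pools=((1, 3, 1),) + ((1, 1, 1),) * 6)
        with pytest.raises(ShapeConfigError):
            cfg.resolved()


class TestMaskApply:
    def test_identity_zero_and_binary(self, rng):
        x = Tensor(rng.standard_normal((1, 1, 2, 3, 3)))
        ones = Tensor(np.ones_like(x.data))
        np.testing.assert_array_equal(mask_apply(x, ones).data, x.data)
        zeros = Tensor(np.zeros_like(x.data))
        assert mask_apply(x, zeros).data.sum() == 0
        binary = Tensor((rng.random(x.shape) < 0.5).astype(np.float32))
        masked = mask_apply(x, binary)
        np.testing.assert_array_equal(masked.data[binary.data == 0], 0)
        np.testing.assert_array_equal(masked.data[binary.data == 1],
                                      x.data[binary.data == 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_apply(Tensor(np.zeros((1, 1, 2, 2, 2))), Tensor(np.zeros((1, 1, 2, 2, 3))))


class TestAttention:
    @pytest.fixture
    def mhsa(self):
        return MultiHeadSelfAttention3d(8, (1, 2, 2), heads=4,
                                        rng=np.random.default_rng(3), dtype=np.float64)

    def test_matches_two_loop_oracle(self, mhsa, rng):
        x = Tensor(rng.standard_normal((2, 4, 8)))
        pos = mhsa.position_encoding()
        got = mhsa.attend(x, pos).data
        expected = two_loop_attention_oracle(
            x.data, (mhsa.wq.weight.data, mhsa.wq.bias.data),
            (mhsa.wk.weight.data, mhsa.wk.bias.data),
            (mhsa.wv.weight.data, mhsa.wv.bias.data),
            (mhsa.wo.weight.data, mhsa.wo.bias.data), pos.data, heads=4)
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_zero_query_projection_averages_values(self, mhsa, rng):
        # all logits equal -> uniform softmax -> per-head mean of v
        mhsa.wq.weight.data[:] = 0
        mhsa.wq.bias.data[:] = 0
        x = Tensor(rng.standard_normal((1, 4, 8)))
        v = x.data @ mhsa.wv.weight.data + mhsa.wv.bias.data
        expected = np.broadcast_to(v.mean(axis=1, keepdims=True), v.shape) \
            @ mhsa.wo.weight.data + mhsa.wo.bias.data
        got = mhsa.attend(x, mhsa.position_encoding()).data
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_single_position_degenerate_softmax(self, rng):
        m = MultiHeadSelfAttention3d(8, (1, 1, 1), heads=4,
                                     rng=np.random.default_rng(3), dtype=np.float64)
        x = Tensor(rng.standard_normal((3, 1, 8)))
        v = x.data @ m.wv.weight.data + m.wv.bias.data
        expected = v @ m.wo.weight.data + m.wo.bias.data
        np.testing.assert_allclose(m.attend(x, m.position_encoding()).data, expected,
                                   atol=1e-10)

    def test_constant_values_pass_through(self, mhsa, rng):
        # attention weights sum to 1, so a constant value sequence is preserved
        x = Tensor(rng.standard_normal((1, 4, 8)))
        mhsa.wv.weight.data[:] = 0
        mhsa.wv.bias.data[:] = 1.0        # v identically 1
        got = mhsa.attend(x, mhsa.position_encoding()).data
        expected = np.ones((1, 4, 8)) @ mhsa.wo.weight.data + mhsa.wo.bias.data
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_permutation_equivariance_without_positions(self, mhsa, rng):
        x = rng.standard_normal((1, 4, 8))
        zero_pos = Tensor(np.zeros((4, 8)))
        perm = np.array([2, 0, 3, 1])
        out = mhsa.attend(Tensor(x), zero_pos).data
        out_perm = mhsa.attend(Tensor(x[:, perm]), zero_pos).data
        np.testing.assert_allclose(out[:, perm], out_perm, atol=1e-10)

    def test_heads_must_divide_channels(self):
        with pytest.raises(ValueError):
            MultiHeadSelfAttention3d(6, (1, 2, 2), heads=4, rng=np.random.default_rng(0))


class TestBackboneAndFusion:
    def test_final_grid_follows_declared_strides(self, rng):
        cfg = TINY.resolved()
        bb = Backbone3D(cfg, np.random.default_rng(0))
        sizes = list(cfg.input_shape)
        for pools in cfg.backbone_pools:
            sizes = [s // f for s, f in zip(sizes, pools)]
        assert bb.final_grid == tuple(sizes)
        out = bb(Tensor(rng.standard_normal((2, 1) + cfg.input_shape).astype(np.float32)))
        assert out.shape == (2, bb.out_channels) + bb.final_grid

    def test_attention_and_conv_fallback_same_shape(self, rng):
        x = Tensor(rng.standard_normal((1, 1) + TINY.input_shape).astype(np.float32))
        from dataclasses import replace
        a = Backbone3D(TINY, np.random.default_rng(0))(x)
        b = Backbone3D(replace(TINY, attention=False), np.random.default_rng(0))(x)
        assert a.shape == b.shape

    def test_ffa_output_on_backbone_grid(self, rng):
        grid = (2, 2, 2)
        ffa = FFAModule((4, 4, 4), 8, grid, heads=4, rng=np.random.default_rng(0))
        taps = tuple(Tensor(rng.standard_normal((1, 4, 2, 4, 4)).astype(np.float32))
                     for _ in range(3))
        feat = Tensor(rng.standard_normal((1, 8) + grid).astype(np.float32))
        assert ffa(taps, feat).shape == (1, 8) + grid

    def test_wo_ffa_same_shape_fewer_params(self, rng):
        full = MultiTaskModel(TINY, seed=0, mode="full")
        ablated = MultiTaskModel(TINY, seed=0, mode="wo_ffa")
        n_full = sum(p.data.size for p in full.parameters())
        n_wo = sum(p.data.size for p in ablated.parameters())
        assert n_wo < n_full
        x = Tensor(rng.standard_normal((1, 1) + TINY.input_shape).astype(np.float32))
        _, p1 = full(x)
        _, p2 = ablated(x)
        assert p1.probs.shape == p2.probs.shape == (1, 4)


class TestClassifier:
    def test_zero_features_zero_affine_uniform(self):
        clf = Classifier(8, np.random.default_rng(0))
        pred = clf(Tensor(np.zeros((3, 8, 2, 2, 2))))
        np.testing.assert_allclose(pred.probs.data, 0.25, atol=1e-12)

    def test_probs_sum_to_one(self, rng):
        clf = Classifier(8, np.random.default_rng(0))
        clf.fc.weight.data[:] = rng.standard_normal((8, 4))
        pred = clf(Tensor(rng.standard_normal((5, 8, 2, 2, 2))))
        np.testing.assert_allclose(pred.probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_argmax_consistency_and_stage(self, rng):
        clf = Classifier(8, np.random.default_rng(0))
        clf.fc.weight.data[:] = rng.standard_normal((8, 4))
        pred = clf(Tensor(rng.standard_normal((6, 8, 2, 2, 2))))
        np.testing.assert_array_equal(np.argmax(pred.probs.data, 1),
                                      np.argmax(pred.logits.data, 1))
        np.testing.assert_array_equal(pred.stage(), np.argmax(pred.logits.data, 1) + 1)


@pytest.mark.parametrize("shape", [(8, 16, 16), (8, 24, 24), (12, 24, 24)])
def test_shape_closure_across_config_grid(shape, rng):
    cfg = NetConfig(input_shape=shape, base_channels=2, channel_cap=8, backbone_width=4)
    model = MultiTaskModel(cfg, seed=0)
    x = Tensor(rng.standard_normal((2, 1) + shape).astype(np.float32))
    seg, pred = model(x)
    assert seg.prob_map.shape == (2, 1) + shape
    assert pred.probs.shape == (2, 4)
    np.testing.assert_allclose(pred.probs.data.sum(axis=1), 1.0, atol=1e-6)
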