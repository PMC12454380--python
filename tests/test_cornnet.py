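"""Attention contracts, loss closed forms, and network-level invariants."""

import numpy as np
import pytest

from corncloud._autograd import Tensor
from corncloud.cornnet import (
    CornNet, NetConfig, _three_nn_interp,
    channel_attention, class_rebalance_weights, composite_loss,
    farthest_point_sampling, resample_indices, spatial_attention,
)

RNG = np.random.default_rng(0)


def _zero_ca_params(c, red=2):
    return (Tensor(np.zeros((c, red))), Tensor(np.zeros(red)),
            Tensor(np.zeros((red, c))), Tensor(np.zeros(c)))


class TestAttention:
    def test_zero_weight_channel_attention_halves_features(self):
        F = Tensor(RNG.normal(size=(3, 7, 8)))
        mc, out = channel_attention(F, *_zero_ca_params(8))
        np.testing.assert_array_equal(mc.data, 0.5)
        np.testing.assert_allclose(out.data, 0.5 * F.data, atol=1e-15)

    def test_zero_weight_spatial_attention_halves_features(self):
        F = Tensor(RNG.normal(size=(3, 7, 8)))
        ms, out = spatial_attention(F, Tensor(np.zeros((2, 1))), Tensor(np.zeros(1)))
        np.testing.assert_array_equal(ms.data, 0.5)
        np.testing.assert_allclose(out.data, 0.5 * F.data, atol=1e-15)

    def test_attention_maps_strictly_in_unit_interval(self):
        F = Tensor(RNG.normal(size=(2, 5, 4)))
        w1, b1 = Tensor(RNG.normal(size=(4, 2))), Tensor(RNG.normal(size=2))
        w2, b2 = Tensor(RNG.normal(size=(2, 4))), Tensor(RNG.normal(size=4))
        mc, f1 = channel_attention(F, w1, b1, w2, b2)
        ms, f2 = spatial_attention(f1, Tensor(RNG.normal(size=(2, 1))),
                                   Tensor(RNG.normal(size=1)))
        for m in (mc, ms):
            assert (m.data > 0).all() and (m.data < 1).all()
        assert f2.shape == F.shape

    def test_single_point_channel_attention_closed_form(self):
        # with one point, avgpool == maxpool, so Mc = sigmoid(2·MLP(F))
        F = Tensor(RNG.normal(size=(1, 1, 6)))
        w1, b1 = Tensor(RNG.normal(size=(6, 3))), Tensor(RNG.normal(size=3))
        w2, b2 = Tensor(RNG.normal(size=(3, 6))), Tensor(RNG.normal(size=6))
        mc, _ = channel_attention(F, w1, b1, w2, b2)
        h = np.maximum(F.data[0, 0] @ w1.data + b1.data, 0) @ w2.data + b2.data
        expect = 1 / (1 + np.exp(-2 * h))
        np.testing.assert_allclose(mc.data[0], expect, atol=1e-12)

    def test_spatial_attention_permutation_equivariance(self):
        F = Tensor(RNG.normal(size=(1, 9, 5)))
        wc, bc = Tensor(RNG.normal(size=(2, 1))), Tensor(RNG.normal(size=1))
        ms, _ = spatial_attention(F, wc, bc)
        perm = RNG.permutation(9)
        ms_p, _ = spatial_attention(Tensor(F.data[:, perm]), wc, bc)
        np.testing.assert_allclose(ms_p.data, ms.data[:, perm], atol=1e-12)


class TestSamplingAndInterp:
    def test_fps_returns_subset_of_requested_size(self):
        pts = RNG.normal(size=(50, 3))
        idx = farthest_point_sampling(pts, 10)
        assert len(idx) == 10 and len(set(idx)) == 10
        with pytest.raises(ValueError):
            farthest_point_sampling(pts, 51)

    def test_constant_coarse_features_interpolate_to_constant(self):
        fine = RNG.normal(size=(1, 20, 3))
        coarse = RNG.normal(size=(1, 6, 3))
        feats = Tensor(np.full((1, 6, 4), 3.25))
        out = _three_nn_interp(fine, coarse, feats)
        np.testing.assert_allclose(out.data, 3.25, atol=1e-9)

    def test_coincident_fine_point_receives_coarse_feature(self):
        coarse = RNG.normal(size=(1, 6, 3))
        fine = coarse[:, :1, :].copy()
        feats = Tensor(RNG.normal(size=(1, 6, 4)))
        out = _three_nn_interp(fine, coarse, feats)
        np.testing.assert_allclose(out.data[0, 0], feats.data[0, 0], atol=1e-4)

    def test_resample_padding_repeats_existing_indices(self):
        idx = resample_indices(10, 16, np.random.default_rng(0))
        assert len(idx) == 16
        assert set(idx[:10]) == set(range(10))
        assert set(idx[10:]) <= set(range(10))
        sub = resample_indices(100, 16, np.random.default_rng(0))
        assert len(set(sub)) == 16


@pytest.fixture(scope="module")
def net_and_batch():
    cfg = NetConfig.small(npoint=256, seed=0)
    net = CornNet(cfg)
    coords = RNG.normal(size=(2, 256, 3))
    coords /= np.linalg.norm(coords, axis=-1).max()
    feats = np.concatenate([coords, np.tile([0, 0, 1.0], (2, 256, 1))], axis=-1)
    return net, coords, feats


class TestForward:
    def test_probabilities_sum_to_one(self, net_and_batch):
        net, coords, feats = net_and_batch
        pred, _ = net.forward(coords, feats)
        np.testing.assert_allclose(pred.probs.sum(-1), 1.0, atol=1e-5)
        assert set(np.unique(pred.labels)) <= {0, 1}

    def test_eval_forward_is_deterministic(self, net_and_batch):
        net, coords, feats = net_and_batch
        p1, _ = net.forward(coords, feats)
        p2, _ = net.forward(coords, feats)
        np.testing.assert_array_equal(p1.probs, p2.probs)

    def test_point_permutation_equivariance(self, net_and_batch):
        net, coords, feats = net_and_batch
        pred, _ = net.forward(coords, feats)
        perm = RNG.permutation(256)
        pred_p, _ = net.forward(coords[:, perm], feats[:, perm])
        np.testing.assert_allclose(pred_p.probs, pred.probs[:, perm], atol=1e-5)

    def test_checkpoint_roundtrip(self, net_and_batch, tmp_path):
        net, coords, feats = net_and_batch
        net.save(tmp_path / "ckpt")
        back = CornNet.load(tmp_path / "ckpt")
        p1, _ = net.forward(coords, feats)
        p2, _ = back.forward(coords, feats)
        np.testing.assert_array_equal(p1.probs, p2.probs)


class TestLoss:
    def test_single_point_half_probability_is_ln2(self):
        loss = composite_loss(np.array([0.5]), np.array([1]))
        assert loss == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_prediction_is_tiny(self):
        p = np.array([1.0, 0.0, 1.0])
        y = np.array([1, 0, 1])
        assert composite_loss(p, y) <= 1e-6

    def test_lambda_weighted_l1_example(self):
        loss = composite_loss(np.array([1.0]), np.array([1]),
                              aux_regression=[(1, 0.5), (0, 0.25)], lam=2.0)
        assert loss == pytest.approx(2 * 0.75, abs=1e-6)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            composite_loss(np.array([0.5]), np.array([1]), lam=-1.0)

    def test_loss_nonnegative_under_random_inputs(self):
        for _ in range(20):
            p = RNG.uniform(0, 1, 30)
            y = RNG.integers(0, 2, 30)
            assert composite_loss(p, y) >= 0.0


class TestClassWeights:
    def test_balanced_batch_uniform(self):
        assert class_rebalance_weights(np.array([0, 1] * 10)) == (1.0, 1.0)

    def test_imbalanced_ratio_is_inverse_frequency(self):
        y = np.array([0] * 90 + [1] * 10)
        w0, w1 = class_rebalance_weights(y)
        assert w1 / w0 == pytest.approx(9.0, abs=1e-12)
        assert (w0 + w1) / 2 == pytest.approx(1.0, abs=1e-12)

    def test_one_class_batch_falls_back_to_uniform(self):
        assert class_rebalance_weights(np.zeros(50)) == (1.0, 1.0)
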