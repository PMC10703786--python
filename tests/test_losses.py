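"""Loss components: worked values, limit-case equivalences, and the schedule."""

import numpy as np
import pytest

from tpunet import losses as L
from tpunet import nn
from tests.conftest import random_prob_mask

LOG2 = float(np.log(2.0))


def _dice(p, g, eps=1e-6):
    return (2 * (p * g).sum() + eps) / (p.sum() + g.sum() + eps)


class TestBCE:
    def test_single_pixel_half_probability(self):
        for g in (0.0, 1.0):
            val = L.bce(np.array([[0.5]]), np.array([[g]])).item()
            assert val == pytest.approx(LOG2, abs=1e-9)

    def test_constant_half_probability(self):
        p = np.full((3, 7), 0.5)
        g = (np.random.default_rng(0).random((3, 7)) > 0.5).astype(float)
        assert L.bce(p, g).item() == pytest.approx(LOG2, abs=1e-9)

    def test_perfect_prediction_is_negligible(self):
        g = (np.random.default_rng(1).random((8, 8)) > 0.5).astype(float)
        assert L.bce(g, g).item() <= -np.log(1 - 1e-6) + 1e-9

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            L.bce(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDeepSupervision:
    def test_four_constant_half_heads(self):
        outs = [nn.Tensor(np.full((1, 1, 4, 4), 0.5)) for _ in range(4)]
        g = np.zeros((1, 1, 4, 4))
        expected = 4 * 0.1 * LOG2  # 0.27726
        assert L.deep_supervision_loss(outs, g).item() == pytest.approx(expected, abs=1e-6)

    def test_zero_weights_give_zero(self):
        cfg = L.LossConfig(lambda_ds=(0, 0, 0, 0))
        outs = [nn.Tensor(np.full((1, 1, 4, 4), 0.3)) for _ in range(4)]
        assert L.deep_supervision_loss(outs, np.zeros((1, 1, 4, 4)), cfg).item() == 0.0

    def test_permutation_invariance_with_equal_weights(self):
        rng = np.random.default_rng(2)
        outs = [nn.Tensor(rng.uniform(0.1, 0.9, (1, 1, 4, 4))) for _ in range(4)]
        g = (rng.random((1, 1, 4, 4)) > 0.5).astype(float)
        v1 = L.deep_supervision_loss(outs, g).item()
        v2 = L.deep_supervision_loss(outs[::-1], g).item()
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_wrong_head_count_raises(self):
        with pytest.raises(ValueError):
            L.deep_supervision_loss([nn.Tensor(np.full((1, 1, 2, 2), 0.5))] * 3, np.zeros((1, 1, 2, 2)))


class TestFocal:
    def test_reduces_to_half_bce(self):
        cfg = L.LossConfig(gamma_focal=0.0, alpha_t=0.5)
        rng = np.random.default_rng(3)
        for _ in range(20):
            p, g = random_prob_mask(rng)
            focal = L.focal_loss(p, g, cfg).item()
            half_bce = 0.5 * L.bce(p, g).item()
            assert focal == pytest.approx(half_bce, abs=1e-9)

    def test_single_pixel_worked_value(self):
        # alpha_t * (1-p)^gamma * (-log p) = 0.8 * 0.25 * log 2
        val = L.focal_loss(np.array([[0.5]]), np.array([[1.0]])).item()
        assert val == pytest.approx(0.8 * 0.25 * LOG2, abs=1e-6)
        assert val == pytest.approx(0.138629, abs=1e-5)

    def test_perfect_prediction_negligible(self):
        g = (np.random.default_rng(4).random((6, 6)) > 0.5).astype(float)
        assert L.focal_loss(g, g).item() < 1e-5


class TestTversky:
    def test_perfect_binary_prediction(self):
        g = np.zeros((8, 8))
        g[2:5, 2:5] = 1
        assert L.tversky_index(g, g).item() == pytest.approx(1.0, abs=1e-6)

    def test_half_weights_equal_dice(self):
        cfg = L.LossConfig(alpha_tv=0.5, beta_tv=0.5)
        rng = np.random.default_rng(5)
        for _ in range(20):
            p, g = random_prob_mask(rng)
            t = L.tversky_index(p, g, cfg).item()
            assert t == pytest.approx(_dice(p, g), abs=1e-6)

    def test_two_pixel_worked_value(self):
        p = np.array([[1.0, 0.0]])
        g = np.array([[1.0, 1.0]])
        t = L.tversky_index(p, g).item()  # TP=1, FP=0, FN=1 -> 1/(1+0.7)
        assert t == pytest.approx(1 / 1.7, abs=1e-6)
        assert t == pytest.approx(0.58824, abs=1e-5)
        ft = L.focal_tversky_loss(p, g).item()
        assert ft == pytest.approx((1 - 1 / 1.7) ** 2, abs=1e-6)
        assert ft == pytest.approx(0.16955, abs=1e-5)

    def test_gamma_one_equals_one_minus_dice(self):
        cfg = L.LossConfig(alpha_tv=0.5, beta_tv=0.5, gamma_tv=1.0)
        rng = np.random.default_rng(6)
        for _ in range(20):
            p, g = random_prob_mask(rng)
            assert L.focal_tversky_loss(p, g, cfg).item() == pytest.approx(1 - _dice(p, g), abs=1e-6)


def _brute_force_distance_map(mask):
    """O(n^2) nearest-opposite-pixel scan (the independent oracle)."""
    mask = np.asarray(mask).astype(bool)
    out = np.zeros(mask.shape, dtype=float)
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    if len(fg) == 0 or len(bg) == 0:
        return out
    for y, x in fg:
        out[y, x] = np.sqrt(((bg - [y, x]) ** 2).sum(axis=1)).min()
    for y, x in bg:
        out[y, x] = np.sqrt(((fg - [y, x]) ** 2).sum(axis=1)).min()
    return out


class TestDistanceMapAndHD:
    def test_corner_pixel_worked_value(self):
        mask = np.zeros((3, 3))
        mask[0, 0] = 1
        dmap = L.distance_map(mask)
        assert dmap[2, 2] == pytest.approx(2 * np.sqrt(2), abs=1e-9)
        assert (dmap >= 0).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            mask = (rng.random((9, 9)) > 0.6).astype(np.uint8)
            assert np.allclose(L.distance_map(mask), _brute_force_distance_map(mask), atol=1e-9)

    def test_degenerate_masks_are_all_zero(self):
        assert not L.distance_map(np.zeros((5, 5))).any()
        assert not L.distance_map(np.ones((5, 5))).any()

    def test_hd_loss_zero_for_perfect_binary(self):
        g = np.zeros((1, 1, 8, 8))
        g[0, 0, 2:5, 3:6] = 1
        assert L.hd_loss(g, g).item() == 0.0

    def test_hd_loss_nonnegative(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p, g = random_prob_mask(rng)
            assert L.hd_loss(p, g).item() >= 0.0

    def test_hd_loss_1d_toy_elementwise_oracle(self):
        g = np.array([[1.0, 0.0, 0.0, 0.0]])
        p = np.array([[1.0, 1.0, 0.0, 0.0]])
        dg = _brute_force_distance_map(g)
        dp = _brute_force_distance_map(p)
        expected = np.mean((g - p) ** 2 * (dp**2 + dg**2))
        assert L.hd_loss(p, g).item() == pytest.approx(expected, abs=1e-9)


class TestScheduleAndComposition:
    def test_hd_alpha_schedule(self):
        assert L.hd_alpha(0) == 0.0
        assert L.hd_alpha(120) == pytest.approx(0.6, abs=1e-12)
        assert L.hd_alpha(500) == 1.0
        with pytest.raises(ValueError):
            L.hd_alpha(-1)

    def test_hd_alpha_nondecreasing_and_capped(self):
        values = [L.hd_alpha(e) for e in range(0, 600, 25)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert max(values) <= 1.0

    def test_seg_loss_epoch_zero_has_no_boundary_term(self):
        rng = np.random.default_rng(9)
        p, g = random_prob_mask(rng)
        region_only = (L.focal_loss(p, g) + L.focal_tversky_loss(p, g)).item()
        assert L.seg_loss(p, g, epoch=0).item() == pytest.approx(region_only, abs=1e-12)

    def test_seg_loss_monotone_in_epoch(self):
        rng = np.random.default_rng(10)
        p, g = random_prob_mask(rng)
        assert L.hd_loss(p, g).item() > 0
        assert L.seg_loss(p, g, 200).item() >= L.seg_loss(p, g, 0).item()

    def test_total_loss_composes_components(self):
        rng = np.random.default_rng(11)
        from tpunet.arch import NetworkOutput

        p, g = random_prob_mask(rng, (1, 1, 6, 6))
        heads = [nn.Tensor(np.full((1, 1, 6, 6), 0.5)) for _ in range(4)]
        out = NetworkOutput(prediction=nn.as_tensor(p), deepsup=heads)
        expected = (
            L.deep_supervision_loss(heads, g).item()
            + 0.6 * L.seg_loss(p, g, 30).item()
        )
        assert L.total_loss(out, g, 30).item() == pytest.approx(expected, rel=1e-9)

    def test_lambda_zero_reduces_to_deep_supervision(self):
        cfg = L.LossConfig(lambda_seg=0.0)
        rng = np.random.default_rng(12)
        from tpunet.arch import NetworkOutput

        p, g = random_prob_mask(rng, (1, 1, 4, 4))
        heads = [nn.as_tensor(rng.uniform(0.2, 0.8, (1, 1, 4, 4))) for _ in range(4)]
        out = NetworkOutput(prediction=nn.as_tensor(p), deepsup=heads)
        assert L.total_loss(out, g, 0, cfg).item() == pytest.approx(
            L.deep_supervision_loss(heads, g, cfg).item(), rel=1e-12
        )

    def test_all_components_nonnegative(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            p, g = random_prob_mask(rng)
            assert L.bce(p, g).item() >= 0
            assert L.focal_loss(p, g).item() >= 0
            assert 0 <= L.tversky_index(p, g).item() <= 1
            assert L.focal_tversky_loss(p, g).item() >= 0
            assert L.hd_loss(p, g).item() >= 0

    def test_components_differentiable_in_open_interval(self):
        rng = np.random.default_rng(14)
        p_data, g = random_prob_mask(rng, (1, 1, 5, 5))
        for fn in (L.bce, L.focal_loss, L.focal_tversky_loss, L.hd_loss):
            p = nn.Tensor(p_data.copy(), requires_grad=True)
            fn(p, g).backward()
            assert p.grad is not None
            assert np.isfinite(p.grad).all()
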