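import math

import numpy as np
import pytest

from starseg.star_loss import (
    LossConfig,
    combined_grad,
    combined_loss,
    cross_entropy_grad,
    cross_entropy_loss,
    dice_grad,
    dice_loss,
    shape_loss_grad,
    star_shape_loss,
    star_shape_loss_non_scaled,
    star_shape_loss_unsegmented,
    _shape_value,
)

from oracles import random_pair, shape_loss_oracle

ALL_VARIANTS = ("segmented", "non_scaled", "unsegmented")


def _variant_value(pred, label, cfg, variant):
    if variant == "segmented":
        return star_shape_loss(pred, label, cfg).shape_term
    if variant == "non_scaled":
        return star_shape_loss_non_scaled(pred, label, cfg)
    return star_shape_loss_unsegmented(pred, label)


class TestBaseLosses:
    def test_cross_entropy_uniform_half(self):
        pred = np.full((4, 4), 0.5)
        label = np.zeros((4, 4))
        label[:2] = 1
        assert cross_entropy_loss(pred, label) == pytest.approx(math.log(2), rel=1e-12)

    def test_cross_entropy_hand_value(self):
        pred = np.array([[0.8, 0.3]])
        label = np.array([[1.0, 0.0]])
        expected = -(math.log(0.8) + math.log(0.7)) / 2
        assert cross_entropy_loss(pred, label) == pytest.approx(expected, rel=1e-12)

    def test_cross_entropy_near_zero_at_truth(self):
        label = np.eye(5)
        assert cross_entropy_loss(label, label) < 1e-6

    def test_dice_identity_and_disjoint(self):
        label = np.zeros((6, 6))
        label[2:4, 2:4] = 1
        assert dice_loss(label, label) == pytest.approx(0.0, abs=0.05)
        assert dice_loss(np.zeros_like(label), label, smooth=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_dice_hand_value(self):
        label = np.zeros((3, 3))
        label[0] = 1  # 3 foreground pixels
        pred = np.where(label > 0, 0.5, 0.0)
        expected = 1 - (2 * 1.5 + 1) / (1.5 + 3 + 1)
        assert dice_loss(pred, label) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy_loss(np.zeros((2, 3)), np.zeros((3, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_base_grads_match_finite_differences(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(0.05, 0.95, (5, 5))
        label = (rng.random((5, 5)) < 0.5).astype(float)
        for fn, grad_fn in ((cross_entropy_loss, cross_entropy_grad),
                            (dice_loss, dice_grad)):
            g = grad_fn(pred, label)
            h = 1e-6
            for idx in [(0, 0), (2, 3), (4, 4)]:
                up, dn = pred.copy(), pred.copy()
                up[idx] += h
                dn[idx] -= h
                fd = (fn(up, label) - fn(dn, label)) / (2 * h)
                assert g[idx] == pytest.approx(fd, abs=1e-6)


class TestShapeTermOracleEquivalence:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_matches_triple_loop_on_random_instances(self, variant):
        rng = np.random.default_rng(202)
        cfg = LossConfig(mu=0.1, rho=1.0)
        for _ in range(12):
            pred, label = random_pair(rng)
            expected = shape_loss_oracle(pred, label, cfg.mu, cfg.rho, variant)[0]
            got = _variant_value(pred, label, cfg, variant)
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-15)

    def test_branch_subtotals_match_oracle(self, hole_fixture):
        pred, label = hole_fixture
        cfg = LossConfig(mu=0.1, rho=1.0)
        bk = star_shape_loss(pred, label, cfg)
        _, edge, hole, other = shape_loss_oracle(pred, label, 0.1, 1.0, "segmented")
        assert bk.edge_fn == pytest.approx(edge, rel=1e-12)
        assert bk.internal_hole == pytest.approx(hole, rel=1e-12)
        assert bk.other == pytest.approx(other, rel=1e-12)


class TestShapeTermProperties:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_zero_at_truth(self, block_9x9, variant):
        cfg = LossConfig()
        assert _variant_value(block_9x9.copy(), block_9x9, cfg, variant) == 0.0

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_non_negative_on_random_inputs(self, variant):
        rng = np.random.default_rng(77)
        cfg = LossConfig(mu=0.3, rho=0.7)
        for _ in range(10):
            pred, label = random_pair(rng, size=10)
            assert _variant_value(pred, label, cfg, variant) >= 0.0

    def test_hole_fixture_fires_only_internal_branch(self, hole_fixture):
        pred, label = hole_fixture
        bk = star_shape_loss(pred, label, LossConfig(mu=0.1, rho=1.0))
        assert bk.internal_hole > 0
        assert bk.edge_fn == 0.0

    def test_rim_fixture_fires_edge_branch(self, rim_fixture):
        # PsN is evaluated at q: pairs with q deep inside predicted
        # foreground take the internal-hole branch even for a rim FN pixel
        # p, so only edge_fn > 0 is guaranteed here
        pred, label = rim_fixture
        bk = star_shape_loss(pred, label, LossConfig(mu=0.1, rho=1.0))
        assert bk.edge_fn > 0

    def test_branch_subtotals_sum_to_total(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            pred, label = random_pair(rng)
            bk = star_shape_loss(pred, label, LossConfig(mu=0.2, rho=0.9))
            assert bk.shape_term == pytest.approx(
                bk.edge_fn + bk.internal_hole + bk.other, rel=1e-12)

    def test_rho_monotonicity_on_hole_fixture(self, hole_fixture):
        pred, label = hole_fixture
        values = [star_shape_loss(pred, label, LossConfig(mu=0.1, rho=r)).shape_term
                  for r in (0.2, 0.5, 1.0, 2.0, 4.0)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_mu_monotonicity_on_rim_fixture(self, rim_fixture):
        pred, label = rim_fixture
        values = [star_shape_loss(pred, label, LossConfig(mu=m, rho=1.0)).shape_term
                  for m in (0.05, 0.1, 0.3, 0.6, 1.2)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_non_scaled_dominates_segmented(self, hole_fixture):
        # every |qc| >= 1, so dropping the 1/|qc| factor can only grow terms
        pred, label = hole_fixture
        cfg = LossConfig(mu=0.1, rho=1.0)
        assert (star_shape_loss_non_scaled(pred, label, cfg)
                >= star_shape_loss(pred, label, cfg).shape_term)

    def test_unsegmented_equals_otherwise_branch_without_fn(self, block_9x9):
        # over-segmentation only: no false negatives, so the segmented loss
        # is pure C-branch and coincides with the unsegmented form
        pred = np.where(block_9x9 > 0, 0.9, 0.1)
        pred[0, :] = 0.8  # false positives on the border row
        bk = star_shape_loss(pred, block_9x9, LossConfig())
        assert bk.edge_fn == 0 and bk.internal_hole == 0
        assert star_shape_loss_unsegmented(pred, block_9x9) == pytest.approx(
            bk.other, rel=1e-12)

    def test_empty_label_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no foreground"):
            v = star_shape_loss_unsegmented(np.full((5, 5), 0.3), np.zeros((5, 5)))
        assert v == 0.0


class TestGradient:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_matches_central_differences(self, variant):
        label = np.zeros((6, 6))
        label[1:5, 1:5] = 1
        pred = np.where(label > 0, 0.9, 0.1)
        pred[2, 3] = 0.2  # a false negative inside the lesion
        cfg = LossConfig(mu=0.1, rho=1.0, variant=variant)
        g = shape_loss_grad(pred, label, cfg)
        h = 1e-6
        fd = np.zeros_like(g)
        for i in range(6):
            for j in range(6):
                up, dn = pred.copy(), pred.copy()
                up[i, j] += h
                dn[i, j] -= h
                fd[i, j] = (_shape_value(up, label, cfg).shape_term
                            - _shape_value(dn, label, cfg).shape_term) / (2 * h)
        assert np.abs(g - fd).max() < 1e-4


class TestCombinedLoss:
    def test_beta_zero_equals_base(self, hole_fixture):
        pred, label = hole_fixture
        cfg = LossConfig(alpha=1.0, beta=0.0, base="dice")
        bk = combined_loss([pred], [label], cfg)
        assert bk.total == pytest.approx(dice_loss(pred, label), rel=1e-12)

    def test_perfect_prediction_with_only_shape_weight(self, block_9x9):
        cfg = LossConfig(alpha=0.0, beta=1.0)
        bk = combined_loss([block_9x9.copy()], [block_9x9], cfg)
        assert bk.total == 0.0

    def test_reduces_to_base_at_truth(self, block_9x9):
        for variant in ALL_VARIANTS:
            cfg = LossConfig(variant=variant)
            bk = combined_loss([block_9x9.copy()], [block_9x9], cfg)
            assert bk.shape_term == 0.0
            assert bk.total == pytest.approx(cfg.alpha * bk.base_term, rel=1e-12)

    def test_duplicated_batch_equals_single(self, hole_fixture):
        pred, label = hole_fixture
        cfg = LossConfig()
        single = combined_loss([pred], [label], cfg)
        double = combined_loss([pred, pred], [label, label], cfg)
        assert double.total == pytest.approx(single.total, rel=1e-12)

    def test_total_is_weighted_sum(self, hole_fixture):
        pred, label = hole_fixture
        cfg = LossConfig(alpha=0.7, beta=2.0)
        bk = combined_loss([pred], [label], cfg)
        assert bk.total == pytest.approx(
            0.7 * bk.base_term + 2.0 * bk.shape_term, rel=1e-12)
        assert bk.shape_term == pytest.approx(
            sum(bk.per_branch.values()), rel=1e-12)

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError, match="empty"):
            combined_loss([], [], LossConfig())

    def test_combined_grad_includes_shape_part(self, hole_fixture):
        pred, label = hole_fixture
        cfg = LossConfig(alpha=1.0, beta=0.5)
        g = combined_grad(pred, label, cfg)
        expected = dice_grad(pred, label) + 0.5 * shape_loss_grad(pred, label, cfg)
        assert np.allclose(g, expected)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=-1)
        with pytest.raises(ValueError):
            LossConfig(base="focal")
        with pytest.raises(ValueError):
            LossConfig(variant="bogus")
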