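import warnings

import numpy as np
import pytest

from cardioseg.losses import (
    DistanceMap,
    LossConfig,
    dice_loss,
    dice_loss_grad,
    distance_map,
    distance_map_stack,
    hybrid_loss,
    hybrid_loss_grad,
    one_hot,
    sd_loss,
    sd_loss_grad,
)


def random_problem(rng, n_classes=3, shape=(4, 4)):
    """Random softmax prediction, one-hot gold, and distance maps."""
    logits = rng.standard_normal((n_classes, *shape))
    pred = np.exp(logits) / np.exp(logits).sum(axis=0)
    gold = one_hot(rng.integers(0, n_classes, shape), n_classes)
    dmaps = rng.uniform(0, 1, (n_classes, *shape))
    return pred, gold, dmaps


def brute_force_dice(pred, gold, k, C_indices):
    total = 0.0
    for c in C_indices:
        num = sum(pred[c].ravel()[i] * gold[c].ravel()[i] for i in range(pred[c].size))
        den = sum(p * p for p in pred[c].ravel()) + sum(g * g for g in gold[c].ravel())
        total += k * num / den
    return 1.0 - total / len(C_indices)


def brute_force_sd(pred, gold, dmaps, gamma, C_indices):
    total = 0.0
    for c in C_indices:
        v = pred[c].size
        s = sum(
            (pred[c].ravel()[i] - gold[c].ravel()[i]) ** 2 * dmaps[c].ravel()[i] ** gamma
            for i in range(v)
        )
        total += s / v
    return total / len(C_indices)


def brute_force_boundary_distances(mask, spacing):
    """O(n^2) nearest-boundary-voxel distance for every voxel."""
    from cardioseg.metrics import surface_voxels

    boundary = np.argwhere(surface_voxels(mask))
    sp = np.asarray(spacing, dtype=float)
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        d = ((boundary - np.asarray(idx)) * sp) ** 2
        out[idx] = np.sqrt(d.sum(axis=1).min())
    return out


class TestDiceLoss:
    def test_perfect_prediction_scores(self):
        gold = one_hot(np.array([[0, 1], [2, 1]]), 3)
        assert dice_loss(gold, gold, LossConfig()) == pytest.approx(0.0)
        assert dice_loss(gold, gold, LossConfig(dice_as_printed=True)) == pytest.approx(0.5)

    def test_matches_brute_force_summation(self, rng):
        pred, gold, _ = random_problem(rng)
        for printed in (False, True):
            cfg = LossConfig(dice_as_printed=printed)
            k = 1.0 if printed else 2.0
            expected = brute_force_dice(pred, gold, k, range(3))
            assert dice_loss(pred, gold, cfg) == pytest.approx(expected, rel=1e-12)

    def test_uniform_prediction_against_oracle(self, rng):
        gold = one_hot(rng.integers(0, 4, (4, 4)), 4)
        pred = np.full((4, 4, 4), 0.25)
        expected = brute_force_dice(pred, gold, 2.0, range(4))
        assert dice_loss(pred, gold) == pytest.approx(expected, rel=1e-12)

    def test_exclude_background_channel(self, rng):
        pred, gold, _ = random_problem(rng)
        cfg = LossConfig(include_background=False)
        expected = brute_force_dice(pred, gold, 2.0, range(1, 3))
        assert dice_loss(pred, gold, cfg) == pytest.approx(expected, rel=1e-12)

    def test_non_probability_prediction_rejected(self, rng):
        gold = one_hot(rng.integers(0, 3, (4, 4)), 3)
        with pytest.raises(ValueError, match="probability"):
            dice_loss(gold * 3.0, gold)

    def test_shape_mismatch_rejected(self, rng):
        pred, gold, _ = random_problem(rng)
        with pytest.raises(ValueError):
            dice_loss(pred[:, :2], gold)


class TestDistanceMap:
    def test_zero_on_boundary_one_at_farthest(self):
        gold = np.zeros((8, 8), dtype=int)
        gold[2:5, 2:5] = 1
        dm = distance_map(gold, 1, (1.0, 1.0))
        from cardioseg.metrics import surface_voxels

        boundary = surface_voxels(gold == 1)
        assert np.all(dm.data[boundary] == 0.0)
        assert dm.data.max() == pytest.approx(1.0)
        assert np.all(dm.data >= 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_small_masks(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(4, 13))
        mask = rng.random((size, size)) < 0.4
        if not mask.any():
            mask[0, 0] = True
        gold = mask.astype(int)
        spacing = (1.0, float(rng.uniform(0.5, 2.0)))
        dm = distance_map(gold, 1, spacing, normalization="none")
        expected = brute_force_boundary_distances(mask, spacing)
        np.testing.assert_allclose(dm.data, expected, rtol=1e-9)

    def test_absent_class_degenerate_policy(self):
        gold = np.zeros((4, 4), dtype=int)
        with pytest.warns(RuntimeWarning, match="absent"):
            dm = distance_map(gold, 3, (1, 1))
        assert dm.degenerate
        np.testing.assert_array_equal(dm.data, 1.0)


class TestSDLoss:
    def test_zero_at_perfect_prediction(self, rng):
        gold = one_hot(rng.integers(0, 3, (4, 4)), 3)
        dmaps = rng.uniform(0, 1, gold.shape)
        assert sd_loss(gold, gold, dmaps) == pytest.approx(0.0)

    def test_gamma_zero_reduces_to_brier(self, rng):
        pred, gold, dmaps = random_problem(rng)
        cfg = LossConfig(gamma=0.0)
        brier = np.mean([(  (pred[c] - gold[c]) ** 2).mean() for c in range(3)])
        assert sd_loss(pred, gold, dmaps, cfg) == pytest.approx(brier, rel=1e-12)

    def test_matches_brute_force(self, rng):
        pred, gold, dmaps = random_problem(rng)
        for gamma in (0.5, 1.0, 2.0):
            cfg = LossConfig(gamma=gamma)
            expected = brute_force_sd(pred, gold, dmaps, gamma, range(3))
            assert sd_loss(pred, gold, dmaps, cfg) == pytest.approx(expected, rel=1e-12)

    def test_missing_distance_maps_rejected(self, rng):
        pred, gold, dmaps = random_problem(rng)
        with pytest.raises(ValueError, match="distance map"):
            sd_loss(pred, gold, dmaps[:2])


class TestHybridLoss:
    def test_alpha_zero_equals_dice(self, rng):
        pred, gold, dmaps = random_problem(rng)
        cfg = LossConfig(alpha=0.0)
        assert hybrid_loss(pred, gold, dmaps, cfg) == pytest.approx(dice_loss(pred, gold, cfg))

    def test_additivity(self, rng):
        pred, gold, dmaps = random_problem(rng)
        for alpha in (0.5, 1.0, 2.0):
            cfg = LossConfig(alpha=alpha)
            expected = dice_loss(pred, gold, cfg) + alpha * sd_loss(pred, gold, dmaps, cfg)
            assert hybrid_loss(pred, gold, dmaps, cfg) == pytest.approx(expected, abs=1e-12)

    def test_zero_at_perfect_prediction(self, rng):
        gold = one_hot(rng.integers(0, 3, (4, 4)), 3)
        dmaps = distance_map_stack(gold.argmax(axis=0), 3, (1, 1))
        assert hybrid_loss(gold, gold, dmaps) == pytest.approx(0.0)

    def test_gradient_against_finite_differences(self, rng):
        pred, gold, dmaps = random_problem(rng)
        cfg = LossConfig()
        value, grad = hybrid_loss_grad(pred, gold, dmaps, cfg)
        assert value == pytest.approx(hybrid_loss(pred, gold, dmaps, cfg))
        eps = 1e-6
        for _ in range(5):
            c = rng.integers(0, 3)
            i, j = rng.integers(0, 4, 2)
            bumped = pred.copy()
            bumped[c, i, j] += eps
            # evaluated without the probability-sum guard: the
            # perturbed input is deliberately non-normalized
            d_num = (hybrid_unchecked(bumped, gold, dmaps, cfg) - value) / eps
            assert d_num == pytest.approx(grad[c, i, j], rel=5e-3, abs=1e-6)

    def test_gradient_step_decreases_loss(self, rng):
        gold = one_hot(rng.integers(0, 3, (6, 6)), 3)
        dmaps = distance_map_stack(gold.argmax(axis=0), 3, (1, 1))
        pred = np.full(gold.shape, 1.0 / 3.0)
        cfg = LossConfig()
        v0, grad = hybrid_loss_grad(pred, gold, dmaps, cfg)
        stepped = np.clip(pred - 0.1 * grad / np.abs(grad).max(), 1e-6, 1)
        stepped /= stepped.sum(axis=0)
        v1 = hybrid_loss(stepped, gold, dmaps, cfg)
        assert v1 < v0


def hybrid_unchecked(pred, gold, dmaps, cfg):
    """Hybrid loss evaluated without the probability-normalization guard
    (used for finite-difference perturbations)."""
    from cardioseg.losses import _dice_terms, _sd_weights, _channel_slice

    terms = _dice_terms(pred.astype(np.float64), gold.astype(np.float64), cfg)
    total = sum((k / 2.0) if den == 0 else k * num / den for _, num, den, k in terms)
    value = 1.0 - total / len(terms)
    chans = _channel_slice(cfg, pred.shape[0])
    v = pred[0].size
    w = _sd_weights(np.asarray(dmaps, dtype=np.float64), cfg.gamma)
    sd = sum(float((((pred[c] - gold[c]) ** 2) * w[c]).sum()) / v for c in chans) / len(
        list(chans)
    )
    return value + cfg.alpha * sd
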