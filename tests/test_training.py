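"""Boosting learning: weight rules against brute-force pixel-counting
oracles, augmentation measure, focus sampling and the ignore contract."""

import numpy as np
import pytest

from metaseg import nn
from metaseg.fcn_model import ModelSpec, build_modified_fcn
from metaseg.training import (
    AugmentationSpec,
    BoostConfig,
    ConsistencyError,
    TrainConfig,
    TrainingSetEmptyError,
    TrainTile,
    boosted_augment,
    draw_jitter,
    focus_sample,
    init_weights,
    photometric_jitter,
    pixel_loss,
    rotate90,
    run_boosting,
    update_weights,
)


def brute_force_tumor_fraction(mask):
    count = 0
    for value in mask.ravel():
        if value == 1:
            count += 1
    return count / mask.size


def brute_force_error_fraction(pred, truth):
    errors = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if t != 255 and p != t:
            errors += 1
    return errors / truth.size


class TestInitWeights:
    def test_all_tumor_tile_gets_weight_one(self):
        mask = np.ones((64, 64), np.uint8)
        assert init_weights({"t": mask}, gamma=0.05) == {"t": 1.0}

    def test_two_percent_tumor_below_gamma_gets_zero(self):
        mask = np.zeros((64, 64), np.uint8)
        n = int(round(0.02 * mask.size))
        mask.ravel()[:n] = 1
        assert init_weights({"t": mask}, gamma=0.05) == {"t": 0.0}

    def test_matches_pixel_counting_oracle_on_random_masks(self, rng):
        masks = {k: rng.choice([0, 1, 255], size=(64, 64),
                               p=[0.7, 0.2, 0.1]).astype(np.uint8)
                 for k in range(200)}
        weights = init_weights(masks, gamma=0.05)
        for k, mask in masks.items():
            expected = 1.0 if brute_force_tumor_fraction(mask) >= 0.05 else 0.0
            assert weights[k] == expected

    def test_non_square_mask_rejected(self):
        with pytest.raises(ValueError):
            init_weights({"t": np.zeros((64, 32), np.uint8)}, gamma=0.05)


class TestUpdateWeights:
    def test_perfect_prediction_keeps_weight(self):
        truth = np.ones((64, 64), np.uint8)
        out = update_weights({"t": 1.0}, {"t": truth.copy()}, {"t": truth},
                             gamma=0.05, chi=1.0)
        assert out == {"t": 1.0}

    def test_six_percent_error_increments_weight(self):
        truth = np.zeros((64, 64), np.uint8)
        pred = truth.copy()
        n = int(np.ceil(0.06 * truth.size))
        pred.ravel()[:n] = 1
        out = update_weights({"t": 1.0}, {"t": pred}, {"t": truth},
                             gamma=0.05, chi=1.0)
        assert out == {"t": 2.0}

    def test_matches_mismatch_counting_oracle(self, rng):
        for _ in range(200):
            truth = rng.choice([0, 1, 255], size=(64, 64),
                               p=[0.6, 0.3, 0.1]).astype(np.uint8)
            pred = rng.integers(0, 2, (64, 64)).astype(np.uint8)
            out = update_weights({"t": 2.0}, {"t": pred}, {"t": truth},
                                 gamma=0.05, chi=0.5)
            e = brute_force_error_fraction(pred, truth)
            assert out["t"] == (2.5 if e >= 0.05 else 2.0)

    def test_weights_never_decrease(self, rng):
        weights = {k: float(rng.integers(0, 3)) for k in range(50)}
        preds = {k: rng.integers(0, 2, (32, 32)).astype(np.uint8)
                 for k in weights}
        truths = {k: rng.integers(0, 2, (32, 32)).astype(np.uint8)
                  for k in weights}
        out = update_weights(weights, preds, truths, gamma=0.05, chi=1.0)
        assert all(out[k] >= weights[k] for k in weights)

    def test_missing_prediction_raises(self):
        with pytest.raises(ConsistencyError):
            update_weights({"t": 1.0}, {}, {"t": np.zeros((8, 8), np.uint8)},
                           gamma=0.05, chi=1.0)


class TestBoostedAugment:
    def test_zero_weight_excludes_tile(self, rng):
        tile = np.zeros((32, 32, 3), np.uint8)
        mask = np.zeros((32, 32), np.uint8)
        assert boosted_augment(tile, mask, 0.0, AugmentationSpec(), rng) == []

    def test_identity_spec_returns_exact_copy(self, rng):
        tile = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        mask = rng.choice([0, 1, 255], size=(32, 32)).astype(np.uint8)
        (img, msk), = boosted_augment(tile, mask, 1.0,
                                      AugmentationSpec.identity(), rng)
        assert np.array_equal(img, tile) and img is not tile
        assert np.array_equal(msk, mask)

    def test_copies_scale_with_weight(self, rng):
        tile = np.zeros((16, 16, 3), np.uint8)
        mask = np.zeros((16, 16), np.uint8)
        spec = AugmentationSpec()
        for w, n in [(1.0, 1), (2.0, 2), (3.4, 3), (3.6, 4)]:
            assert len(boosted_augment(tile, mask, w, spec, rng)) == n

    def test_rotation_composition(self, rng):
        tile = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        assert np.array_equal(rotate90(rotate90(tile, 90), 90),
                              rotate90(tile, 180))
        mask = rng.integers(0, 2, (32, 32)).astype(np.uint8)
        assert np.array_equal(rotate90(rotate90(mask, 90), 90),
                              rotate90(mask, 180))

    def test_geometric_transform_applied_identically(self, rng):
        # a single marked pixel must move together in tile and mask
        tile = np.zeros((32, 32, 3), np.uint8)
        mask = np.zeros((32, 32), np.uint8)
        tile[3, 10] = 255
        mask[3, 10] = 1
        spec = AugmentationSpec(contrast_range=0, saturation_range=0,
                                brightness_range=0)
        for img, msk in boosted_augment(tile, mask, 5.0, spec, rng):
            assert np.array_equal((img[..., 0] == 255), (msk == 1))

    def test_mask_values_stay_in_label_set(self, rng):
        tile = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
        mask = rng.choice([0, 1, 255], size=(32, 32)).astype(np.uint8)
        for _, msk in boosted_augment(tile, mask, 8.0, AugmentationSpec(), rng):
            assert set(np.unique(msk)) <= {0, 1, 255}

    def test_jitter_ranges_and_coverage(self):
        rng = np.random.default_rng(123)
        spec = AugmentationSpec()
        draws = np.array([draw_jitter(spec, rng) for _ in range(10_000)])
        for col, bound in zip(draws.T, (0.20, 0.20, 0.125)):
            assert col.min() >= -bound and col.max() <= bound
            assert (col.max() - col.min()) >= 0.9 * 2 * bound

    def test_photometric_identity_for_zero_params(self, rng):
        tile = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        assert np.array_equal(photometric_jitter(tile, 0, 0, 0), tile)

    def test_brightness_scales_values(self):
        tile = np.full((8, 8, 3), 100, np.uint8)
        out = photometric_jitter(tile, 0, 0, 0.1)
        assert (out == 110).all()


class TestFocusSample:
    def test_fully_annotated_mask_unchanged(self):
        mask = np.zeros((32, 32), np.uint8)
        mask[4:10, 4:10] = 1
        tissue = np.ones_like(mask, bool)
        out = focus_sample(mask, tissue)
        assert np.array_equal(out, mask)

    def test_partial_region_background_becomes_ignore(self):
        mask = np.zeros((32, 32), np.uint8)
        mask[0:4, 0:4] = 1
        tissue = np.ones_like(mask, bool)
        partial = np.zeros_like(tissue)
        partial[16:, 16:] = True
        out = focus_sample(mask, tissue, partial_region=partial)
        assert (out[16:, 16:] == 255).all()
        assert (out[0:4, 0:4] == 1).all()
        assert (out[4:16, :] == 0).all()

    def test_dilation_band_around_annotation(self):
        mask = np.zeros((32, 32), np.uint8)
        mask[10:14, 10:14] = 1
        tissue = np.ones_like(mask, bool)
        out = focus_sample(mask, tissue, dilation_px=2)
        assert (out[10:14, 10:14] == 1).all()  # annotation preserved
        assert out[9, 10] == 255 and out[14, 10] == 255
        assert out[0, 0] == 0  # far pixels untouched

    def test_ignore_never_overwrites_tumor(self):
        mask = np.zeros((16, 16), np.uint8)
        mask[:, :] = 1
        tissue = np.ones_like(mask, bool)
        out = focus_sample(mask, tissue,
                           partial_region=np.ones_like(tissue))
        assert (out == 1).all()

    def test_non_tissue_background_not_ignored(self):
        mask = np.zeros((16, 16), np.uint8)
        tissue = np.zeros_like(mask, bool)
        out = focus_sample(mask, tissue, partial_region=np.ones_like(mask, bool))
        assert (out == 0).all()


class TestPixelLoss:
    def test_one_hot_match_is_zero(self):
        truth = np.array([[0, 1], [1, 0]], np.uint8)
        prob = np.zeros((2, 2, 2), np.float32)
        prob[..., 0] = truth == 0
        prob[..., 1] = truth == 1
        assert pixel_loss(prob, truth) == 0.0

    def test_uniform_two_class_sum_is_n_ln2(self):
        truth = np.zeros((8, 8), np.uint8)
        truth[0, :4] = 255
        prob = np.full((8, 8, 2), 0.5, np.float32)
        n_valid = 64 - 4
        assert pixel_loss(prob, truth, "sum") == pytest.approx(
            n_valid * np.log(2), rel=1e-6)
        assert pixel_loss(prob, truth, "mean") == pytest.approx(
            np.log(2), rel=1e-6)

    def test_ignore_pixels_contribute_nothing(self, rng):
        truth = rng.integers(0, 2, (16, 16)).astype(np.uint8)
        truth[:4] = 255
        prob = rng.random((16, 16, 2)).astype(np.float32)
        prob /= prob.sum(axis=2, keepdims=True)
        base = pixel_loss(prob, truth)
        flipped = truth.copy()
        flipped[:4] = 255  # stays ignore; now perturb the prob there
        prob2 = prob.copy()
        prob2[:4] = rng.random((4, 16, 2)).astype(np.float32)
        prob2[:4] /= prob2[:4].sum(axis=2, keepdims=True)
        assert pixel_loss(prob2, flipped) == base

    def test_all_ignored_warns_and_returns_zero(self):
        truth = np.full((8, 8), 255, np.uint8)
        prob = np.full((8, 8, 2), 0.5, np.float32)
        with pytest.warns(RuntimeWarning):
            assert pixel_loss(prob, truth) == 0.0


class TestLogitsLossGradient:
    def test_gradient_zero_at_ignore_pixels(self, rng):
        logits = rng.normal(0, 1, (1, 2, 8, 8)).astype(np.float32)
        target = rng.integers(0, 2, (1, 8, 8)).astype(np.uint8)
        target[0, :3] = 255
        loss, dlogits, n_valid = nn.cross_entropy_with_logits(logits, target)
        assert n_valid == 5 * 8
        assert (dlogits[0, :, :3] == 0).all()

    def test_label_changes_inside_ignore_leave_loss_and_grad_identical(self, rng):
        logits = rng.normal(0, 1, (1, 2, 8, 8)).astype(np.float32)
        target = rng.integers(0, 2, (1, 8, 8)).astype(np.uint8)
        target[0, 2:5, 2:5] = 255
        l1, d1, _ = nn.cross_entropy_with_logits(logits, target)
        perturbed = logits.copy()
        perturbed[0, :, 2:5, 2:5] += rng.normal(0, 3, (2, 3, 3))
        l2, d2, _ = nn.cross_entropy_with_logits(perturbed, target)
        assert l1 == l2
        assert np.array_equal(d1[0, :, 5:], d2[0, :, 5:])


def _tiny_training_setup(rng, n_tiles=6, u=32):
    spec = ModelSpec(input_size=u, pad=16,
                     blocks=((2, 2), (2, 2), (3, 2), (3, 2), (3, 2)))
    tiles = []
    for k in range(n_tiles):
        pixels = rng.integers(0, 255, (u, u, 3)).astype(np.uint8)
        labels = np.zeros((u, u), np.uint8)
        if k % 2 == 0:
            labels[: u // 2] = 1  # tumor-rich tiles get weight 1
        tiles.append(TrainTile(key=("s", 0, k), pixels=pixels, labels=labels))
    return spec, tiles


class TestRunBoosting:
    def test_weights_monotone_and_history_complete(self, rng):
        spec, tiles = _tiny_training_setup(rng)
        model = build_modified_fcn(spec, seed=0)
        boost = BoostConfig(rounds=2, negative_quota=0.5)
        cfg = TrainConfig(learning_rate=1e-3, epochs_per_round=1,
                          batch_size=2, seed=0, loss_reduction="mean")
        model, history = run_boosting(model, tiles, boost, cfg)
        assert len(history) == 2
        for rec in history:
            for key, w_in in rec["weights_in"].items():
                assert rec["weights_out"][key] >= w_in
        # round 2 starts from round 1's output weights
        assert history[1]["weights_in"] == history[0]["weights_out"]

    def test_seeded_runs_are_bit_identical(self, rng):
        spec, tiles = _tiny_training_setup(rng)
        results = []
        for _ in range(2):
            model = build_modified_fcn(spec, seed=0)
            cfg = TrainConfig(learning_rate=1e-3, epochs_per_round=1,
                              batch_size=2, seed=3, loss_reduction="mean")
            model, history = run_boosting(
                model, tiles, BoostConfig(rounds=2), cfg)
            results.append((model.state_dict(), history))
        (s1, h1), (s2, h2) = results
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)
        assert h1 == h2

    def test_empty_training_set_raises(self, rng):
        spec, tiles = _tiny_training_setup(rng)
        for t in tiles:
            t.labels[:] = 0  # nothing annotated -> all weights zero
        model = build_modified_fcn(spec, seed=0)
        with pytest.raises(TrainingSetEmptyError):
            run_boosting(model, tiles, BoostConfig(rounds=1),
                         TrainConfig(learning_rate=1e-3, seed=0,
                                     loss_reduction="mean"))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BoostConfig(gamma=0.0).validate()
        with pytest.raises(ValueError):
            BoostConfig(chi=-1).validate()
        with pytest.raises(ValueError):
            TrainConfig(loss_reduction="median").validate()
        with pytest.raises(ValueError):
            TrainConfig(dropout=1.0).validate()
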