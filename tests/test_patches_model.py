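"""Patch extraction, the RPS loss, and the ordinal classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from focusqc.nn import FocusNet
from focusqc.patches_model import (ModelSpec, TrainConfig, _rps_batch_grad,
                                   extract_random_patch, load_model,
                                   predict_patch, predict_patches, rps_loss,
                                   save_model, tile_patches)


class TestPatchExtraction:
    def test_exact_size_image_returns_itself(self, rng):
        img = rng.uniform(0, 100, (84, 84))
        np.testing.assert_array_equal(extract_random_patch(img, seed=0), img)

    def test_crop_corner_within_bounds(self, rng):
        img = rng.uniform(0, 100, (520, 696))
        for seed in range(20):
            patch = extract_random_patch(img, seed=seed)
            assert patch.shape == (84, 84)

    def test_seeded_crop_deterministic(self, rng):
        img = rng.uniform(0, 100, (200, 200))
        a = extract_random_patch(img, seed=5)
        b = extract_random_patch(img, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            extract_random_patch(np.zeros((50, 90)))


class TestTilePatches:
    def test_grid_on_full_sized_frame(self, rng):
        """A 696 x 520 frame tiles into an 8 x 6 = 48 patch grid."""
        img = rng.uniform(0, 100, (520, 696))
        tiles = tile_patches(img)
        assert len(tiles) == 48
        rows = {r for _, r, _ in tiles}
        cols = {c for _, _, c in tiles}
        assert rows == set(range(6)) and cols == set(range(8))

    def test_single_patch_image(self, rng):
        img = rng.uniform(0, 100, (84, 84))
        tiles = tile_patches(img)
        assert len(tiles) == 1 and tiles[0][1:] == (0, 0)

    def test_tiles_disjoint_and_cover_grid(self, rng):
        img = np.arange(170 * 170, dtype=float).reshape(170, 170)
        tiles = tile_patches(img)
        seen = set()
        for patch, r, c in tiles:
            np.testing.assert_array_equal(
                patch, img[r * 84:(r + 1) * 84, c * 84:(c + 1) * 84])
            assert (r, c) not in seen
            seen.add((r, c))


class TestRpsLoss:
    def test_zero_at_truth(self):
        pred = np.zeros(11)
        pred[4] = 1.0
        assert rps_loss(pred, 4) == pytest.approx(0.0)

    @pytest.mark.parametrize("d", [1, 2, 3, 5, 10])
    def test_one_hot_offset_costs_ordinal_distance(self, d):
        """A one-hot prediction d levels away scores exactly d."""
        pred = np.zeros(11)
        pred[d] = 1.0
        assert rps_loss(pred, 0) == pytest.approx(float(d))

    def test_uniform_vs_level_zero(self):
        """Hand-derived value: sum_{m=1}^{10} (m/11)^2 = 385/121."""
        assert rps_loss(np.full(11, 1 / 11), 0) == pytest.approx(385 / 121)

    def test_monotone_in_ordinal_distance(self):
        costs = []
        for d in range(11):
            pred = np.zeros(11)
            pred[d] = 1.0
            costs.append(rps_loss(pred, 0))
        assert np.all(np.diff(costs) > 0)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            rps_loss(np.full(11, 0.2), 0)

    @given(st.integers(0, 10), st.integers(0, 10))
    @settings(max_examples=30, deadline=None)
    def test_batch_gradient_matches_scalar_loss(self, true_level, peak):
        """The vectorized training loss equals the scalar definition."""
        probs = np.full((1, 11), 0.05)
        probs[0, peak] += 1 - probs.sum()
        loss, _ = _rps_batch_grad(probs, np.array([true_level]))
        assert loss == pytest.approx(rps_loss(probs[0], true_level))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients agree with central differences on a tiny net."""
        net = FocusNet(n_levels=4, seed=0, conv_filters=(2, 3),
                       kernel_size=3, fc_units=6, dropout=0.0, input_size=14)
        for k in net.params:
            net.params[k] = net.params[k].astype(np.float64)
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (2, 1, 14, 14))
        labels = np.array([0, 2])

        def loss_of():
            probs, _ = net.forward(x, train=False)
            return _rps_batch_grad(probs, labels)[0]

        probs, cache = net.forward(x, train=False)
        _, dlogits = _rps_batch_grad(probs, labels)
        grads = net.backward(dlogits.astype(np.float64), cache)

        eps = 1e-6
        check_rng = np.random.default_rng(2)
        for name, g in grads.items():
            flat = net.params[name].ravel()
            for idx in check_rng.choice(flat.size, size=min(8, flat.size),
                                        replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_of()
                flat[idx] = orig - eps
                lm = loss_of()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(numeric, abs=1e-5), name


class TestTrainingAndPrediction:
    def test_training_reduces_loss(self, mini_model):
        trace = mini_model.loss_trace
        assert np.mean(trace[-30:]) < np.mean(trace[:30])

    def test_prediction_is_valid_distribution(self, mini_model, rng):
        patch = rng.uniform(0, 5000, (84, 84))
        dist = predict_patch(mini_model, patch)
        assert dist.shape == (11,)
        assert np.all(dist >= 0)
        assert dist.sum() == pytest.approx(1.0, abs=1e-6)

    def test_inference_deterministic(self, mini_model, rng):
        patch = rng.uniform(0, 5000, (84, 84))
        np.testing.assert_array_equal(predict_patch(mini_model, patch),
                                      predict_patch(mini_model, patch))

    def test_wrong_patch_shape_rejected(self, mini_model):
        with pytest.raises(ValueError):
            predict_patch(mini_model, np.zeros((50, 50)))

    def test_training_loss_trace_reproducible(self, small_dataset):
        train_set, _ = small_dataset
        cfg = TrainConfig(steps=5, batch_size=4, seed=21)
        a = np.asarray(
            __import__("focusqc").train(train_set, ModelSpec(), cfg).loss_trace)
        b = np.asarray(
            __import__("focusqc").train(train_set, ModelSpec(), cfg).loss_trace)
        np.testing.assert_array_equal(a, b)

    def test_missing_label_classes_warn(self, small_dataset):
        from focusqc import train
        train_set, _ = small_dataset
        partial = train_set.subset(train_set.labels < 5)
        with pytest.warns(UserWarning, match="levels"):
            train(partial, ModelSpec(),
                  TrainConfig(steps=2, batch_size=4, seed=0))

    def test_checkpoint_round_trip(self, mini_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        save_model(mini_model, str(path))
        loaded = load_model(str(path))
        patch = rng.uniform(0, 5000, (84, 84))
        np.testing.assert_array_equal(predict_patch(mini_model, patch),
                                      predict_patch(loaded, patch))

    def test_level0_patches_score_lower_than_level10(self, mini_model,
                                                     small_dataset):
        """Even a briefly trained model orders the extreme levels."""
        _, test_set = small_dataset
        fg = test_set.foreground_flags

        def mean_level(level):
            sel = fg & (test_set.labels == level)
            if not sel.any():
                pytest.skip("no foreground patches at this level")
            dists = predict_patches(mini_model, test_set.patches[sel])
            return float(np.mean(dists @ np.arange(11)))

        assert mean_level(0) < mean_level(10)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(input_size=64)
    with pytest.raises(ValueError):
        ModelSpec(dropout=1.0)
    with pytest.raises(ValueError):
        TrainConfig(steps=0)
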