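import math

import numpy as np
import pytest

from modicovi.density_model import (
    GaussianFeature,
    TrainingScene,
    WeedModel,
    compose_training_scenes,
    feature_matrix,
    feature_value,
    predict,
    sample_feature_pool,
    select_features,
)
from modicovi.synthetic_scenes import Sprite, make_dicot, make_monocot


def kernel_loop_oracle(pairs, feature, normalized):
    """Scalar double-loop recomputation of the Gaussian density feature."""
    total = 0.0
    for row in np.atleast_2d(pairs):
        e = 0.0
        for axis in range(5):
            diff = row[axis] - feature.center[axis]
            if axis == 2:  # angular axis wraps
                diff = math.atan2(math.sin(diff), math.cos(diff))
            e += (diff / feature.bandwidth[axis]) ** 2
        total += math.exp(-e)
    n = np.atleast_2d(pairs).shape[0]
    return total / n if normalized else total


def random_pair_scene(rng, n_pairs):
    pairs = np.column_stack(
        [
            rng.uniform(-125, 125, n_pairs),
            rng.uniform(-125, 125, n_pairs),
            rng.uniform(-np.pi, np.pi, n_pairs),
            rng.uniform(1, 125, n_pairs),
            rng.uniform(0, 2, n_pairs),
        ]
    )
    return TrainingScene(pairs=pairs, true_weed_pixels=0, true_total_veg_pixels=1)


class TestFeatureValue:
    def test_single_pair_at_center_scores_one(self):
        f = GaussianFeature(center=[1, 2, 0.5, 3, 0.1], bandwidth=[1, 1, 1, 1, 1])
        pairs = np.array([[1, 2, 0.5, 3, 0.1]])
        assert feature_value(pairs, f, normalized=False) == 1.0
        assert feature_value(pairs, f, normalized=True) == 1.0

    def test_far_pair_underflows_to_zero(self):
        f = GaussianFeature(center=[0, 0, 0, 10, 0], bandwidth=[1, 1, 1, 1, 1])
        pairs = np.array([[1e6, 0, 0, 10, 0]])
        assert feature_value(pairs, f) == 0.0

    def test_empty_pair_list_scores_zero(self):
        f = GaussianFeature(center=np.zeros(5), bandwidth=np.ones(5))
        assert feature_value(np.empty((0, 5)), f) == 0.0

    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_double_loop_oracle(self, normalized):
        rng = np.random.default_rng(17)
        pairs = random_pair_scene(rng, 7).pairs
        for f in sample_feature_pool(n=10, rng_seed=23):
            got = feature_value(pairs, f, normalized=normalized)
            ref = kernel_loop_oracle(pairs, f, normalized)
            assert got == pytest.approx(ref, abs=1e-12, rel=1e-12)

    def test_normalized_is_unnormalized_over_n(self):
        rng = np.random.default_rng(2)
        pairs = random_pair_scene(rng, 13).pairs
        for f in sample_feature_pool(n=5, rng_seed=5):
            assert feature_value(pairs, f, True) == feature_value(pairs, f, False) / 13

    def test_bounds_and_permutation_invariance(self):
        rng = np.random.default_rng(21)
        pairs = random_pair_scene(rng, 40).pairs
        f = sample_feature_pool(n=1, rng_seed=9)[0]
        raw = feature_value(pairs, f, normalized=False)
        assert 0.0 <= raw <= 40.0
        assert 0.0 <= feature_value(pairs, f, normalized=True) <= 1.0
        shuffled = pairs[rng.permutation(40)]
        assert feature_value(shuffled, f) == pytest.approx(raw, rel=1e-12)

    def test_matrix_agrees_with_per_feature_values(self):
        rng = np.random.default_rng(31)
        scenes = [random_pair_scene(rng, n).pairs for n in (0, 5, 33)]
        pool = sample_feature_pool(n=12, rng_seed=1)
        mat = feature_matrix(scenes, pool)
        ref = np.array([[feature_value(p, f) for f in pool] for p in scenes])
        np.testing.assert_allclose(mat, ref, rtol=1e-10, atol=1e-12)


class TestFeaturePool:
    def test_empty_pool(self):
        assert sample_feature_pool(n=0) == []

    def test_pool_of_450_within_ranges(self):
        pool = sample_feature_pool(n=450, rng_seed=0)
        assert len(pool) == 450
        from modicovi.density_model import DEFAULT_RANGES

        ranges = np.asarray(DEFAULT_RANGES)
        for f in pool:
            assert (f.center >= ranges[:, 0]).all() and (f.center <= ranges[:, 1]).all()
            assert (f.bandwidth > 0).all()

    def test_seed_reproducibility(self):
        a = sample_feature_pool(n=20, rng_seed=7)
        b = sample_feature_pool(n=20, rng_seed=7)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.center, fb.center)
            assert np.array_equal(fa.bandwidth, fb.bandwidth)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            GaussianFeature(center=np.zeros(5), bandwidth=[1, 1, 0, 1, 1])


class TestComposeTrainingScenes:
    def test_single_dicot_scene_counts_sprite_pixels(self):
        dicot = make_dicot(radius_px=15, n_lobes=0)
        mono = make_monocot(length_px=60, width_px=6, curvature=0.0)
        scenes = compose_training_scenes(
            [dicot, mono], n_scenes=4, canvas_shape=(128, 128), rng_seed=0,
            max_monocots=0, max_dicots=1, rotate=False,
        )
        for s in scenes:
            assert s.true_weed_pixels in (0, dicot.pixel_count)

    def test_monocot_only_scenes_have_no_weed(self):
        mono = make_monocot(length_px=80, width_px=8)
        dicot = make_dicot(radius_px=10)
        scenes = compose_training_scenes(
            [mono, dicot], n_scenes=3, canvas_shape=(256, 256), rng_seed=1,
            max_dicots=0,
        )
        assert all(s.true_weed_pixels == 0 for s in scenes)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            compose_training_scenes([make_dicot(radius_px=10)], n_scenes=1)

    def test_weed_count_never_exceeds_vegetation(self):
        bank = [make_monocot(rng_seed=1), make_dicot(rng_seed=2)]
        scenes = compose_training_scenes(bank, n_scenes=5, rng_seed=3)
        for s in scenes:
            assert 0 <= s.true_weed_pixels <= s.true_total_veg_pixels


class TestSelectFeatures:
    def test_pool_equal_k_is_plain_least_squares(self):
        rng = np.random.default_rng(0)
        scenes = [random_pair_scene(rng, 20) for _ in range(8)]
        pool = sample_feature_pool(n=3, rng_seed=1)
        targets = rng.uniform(0, 100, 8)
        model = select_features(pool, scenes, k=3, iterations=50, rng_seed=2, targets=targets)
        g = feature_matrix([s.pairs for s in scenes], pool)
        w, *_ = np.linalg.lstsq(g, targets, rcond=None)
        np.testing.assert_allclose(np.sort(model.weights), np.sort(w), rtol=1e-8)
        assert len(model.mse_trace) == 1

    def test_planted_linear_model_recovered(self):
        # targets are an exact linear function of 3 planted pool features
        rng = np.random.default_rng(5)
        scenes = [random_pair_scene(rng, 30) for _ in range(40)]
        pool = sample_feature_pool(n=10, rng_seed=6)
        g = feature_matrix([s.pairs for s in scenes], pool)
        true_w = np.array([2.0, -1.5, 0.7])
        planted = [2, 5, 7]
        targets = g[:, planted] @ true_w
        model = select_features(
            pool, scenes, k=3, iterations=3000, rng_seed=7, targets=targets
        )
        assert model.mse_trace[-1] < 1e-10

    def test_accepted_mse_trace_strictly_decreasing(self):
        rng = np.random.default_rng(8)
        scenes = [random_pair_scene(rng, 25) for _ in range(30)]
        pool = sample_feature_pool(n=40, rng_seed=9)
        targets = rng.uniform(0, 50, 30)
        model = select_features(pool, scenes, k=5, iterations=500, rng_seed=10, targets=targets)
        trace = np.array(model.mse_trace)
        assert (np.diff(trace) < 0).all()


class TestPredictAndPersistence:
    def test_zero_weights_predict_zero(self):
        model = WeedModel(features=sample_feature_pool(n=4, rng_seed=0), weights=np.zeros(4))
        pairs = random_pair_scene(np.random.default_rng(1), 10).pairs
        assert predict(pairs, model) == 0.0

    def test_prediction_is_dot_product(self):
        f = GaussianFeature(center=[0, 0, 0, 10, 0.1], bandwidth=np.ones(5))
        model = WeedModel(features=[f, f], weights=[2.0, 1.0])
        pairs = random_pair_scene(np.random.default_rng(2), 6).pairs
        g = feature_value(pairs, f)
        assert predict(pairs, model) == pytest.approx(3 * g, rel=1e-12)

    def test_json_round_trip(self):
        model = WeedModel(
            features=sample_feature_pool(n=3, rng_seed=4),
            weights=[1.5, -2.0, 0.25],
            intercept=3.0,
            normalized=True,
            target_mode="ratio",
        )
        clone = WeedModel.from_json(model.to_json())
        assert clone.normalized and clone.target_mode == "ratio"
        assert clone.intercept == 3.0
        np.testing.assert_array_equal(clone.weights, model.weights)
        for a, b in zip(clone.features, model.features):
            np.testing.assert_array_equal(a.center, b.center)
            np.testing.assert_array_equal(a.bandwidth, b.bandwidth)
        pairs = random_pair_scene(np.random.default_rng(5), 9).pairs
        assert predict(pairs, clone) == predict(pairs, model)
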