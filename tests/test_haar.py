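import numpy as np
import pytest

from kiwicount.haar import (
    HaarFeature,
    adaboost,
    box_sum,
    feature_value,
    feature_value_matrix,
    generate_feature_pool,
    initial_weights,
    integral_image,
    train_stump,
)


def brute_force_integral(image: np.ndarray) -> np.ndarray:
    h, w = image.shape
    out = np.zeros((h + 1, w + 1), dtype=np.int64)
    for y in range(1, h + 1):
        for x in range(1, w + 1):
            out[y, x] = int(image[:y, :x].sum())
    return out


class TestIntegralImage:
    def test_three_by_three_ones(self):
        ii = integral_image(np.ones((3, 3), dtype=np.int64))
        assert np.array_equal(
            ii[1:, 1:], np.array([[1, 2, 3], [2, 4, 6], [3, 6, 9]]))

    def test_corner_is_total_sum(self, rng):
        image = rng.integers(0, 255, size=(9, 13), dtype=np.int64)
        assert integral_image(image)[-1, -1] == image.sum()

    def test_matches_double_loop_summation(self, rng):
        for _ in range(30):
            image = rng.integers(0, 255, size=(16, 16), dtype=np.int64)
            assert np.array_equal(integral_image(image),
                                  brute_force_integral(image))


class TestBoxSum:
    def test_full_image_and_unit_rects(self, rng):
        image = rng.integers(0, 255, size=(10, 12), dtype=np.int64)
        ii = integral_image(image)
        assert box_sum(ii, 0, 0, 12, 10) == image.sum()
        ones = integral_image(np.ones((8, 8), dtype=np.int64))
        assert box_sum(ones, 2, 3, 4, 5) == 20

    def test_matches_direct_summation(self, rng):
        image = rng.integers(0, 255, size=(20, 20), dtype=np.int64)
        ii = integral_image(image)
        for _ in range(200):
            x, y = int(rng.integers(0, 19)), int(rng.integers(0, 19))
            w = int(rng.integers(1, 20 - x + 1))
            h = int(rng.integers(1, 20 - y + 1))
            assert box_sum(ii, x, y, w, h) == image[y:y + h, x:x + w].sum()

    def test_out_of_bounds_rejected(self):
        ii = integral_image(np.ones((5, 5), dtype=np.int64))
        with pytest.raises(ValueError):
            box_sum(ii, 3, 3, 4, 4)


def brute_force_feature(image, feature: HaarFeature, scale=1.0):
    shaded_sum = white_sum = 0.0
    shaded_area = white_area = 0
    for rx, ry, rw, rh, sign in feature.rects(scale):
        s = image[ry:ry + rh, rx:rx + rw].sum()
        if sign > 0:
            shaded_sum += s
            shaded_area += rw * rh
        else:
            white_sum += s
            white_area += rw * rh
    return shaded_sum / shaded_area - white_sum / white_area


class TestHaarFeatures:
    def test_constant_image_gives_zero(self):
        image = np.full((24, 24), 77, dtype=np.int64)
        ii = integral_image(image)
        for feature in generate_feature_pool(24)[::97]:
            assert feature_value(ii, feature) == pytest.approx(0.0)

    def test_edge_feature_antisymmetric_under_inversion(self):
        image = np.zeros((24, 24), dtype=np.int64)
        image[12:, :] = 200  # bright bottom
        feature = HaarFeature("two_rect_vertical", 4, 4, 12, 16)
        ii_a = integral_image(image)
        ii_b = integral_image(200 - image)
        va = feature_value(ii_a, feature)
        vb = feature_value(ii_b, feature)
        assert va > 0 and vb == pytest.approx(-va)

    def test_matches_direct_rectangle_sums(self, rng):
        image = rng.integers(0, 255, size=(40, 40), dtype=np.int64)
        ii = integral_image(image)
        pool = generate_feature_pool(24)
        for idx in rng.choice(len(pool), size=120, replace=False):
            feature = pool[idx]
            for scale in (1.0, 1.3):
                assert feature_value(ii, feature, (2, 3), scale) == \
                    pytest.approx(brute_force_feature(
                        image[3:, 2:], feature, scale))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            HaarFeature("two_rect_horizontal", 0, 0, 5, 6)  # odd width
        with pytest.raises(ValueError):
            HaarFeature("three_rect_vertical", 0, 0, 6, 7)
        with pytest.raises(ValueError):
            HaarFeature("diagonal", 0, 0, 6, 6)


def brute_force_stump(values, labels, weights):
    """Exhaustive midpoint-threshold x parity search."""
    vs = np.sort(np.unique(values))
    candidates = np.concatenate(
        ([vs[0] - 1.0], (vs[1:] + vs[:-1]) / 2, [vs[-1] + 1.0]))
    best = (None, None, np.inf)
    for theta in candidates:
        for parity in (1, -1):
            pred = (parity * values < parity * theta).astype(int)
            err = weights[pred != labels].sum()
            if err < best[2] - 1e-12:
                best = (theta, parity, err)
    return best


class TestTrainStump:
    def test_perfect_separation_gives_zero_error(self):
        values = np.array([0.1, 0.2, 0.3, 5.0, 6.0, 7.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        weights = np.full(6, 1 / 6)
        theta, parity, err = train_stump(values, labels, weights)
        assert err == pytest.approx(0.0)
        assert parity == -1  # positives sit above the threshold
        assert 0.3 < theta < 5.0
        pred = (parity * values < parity * theta).astype(int)
        assert np.array_equal(pred, labels)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_stump(np.arange(4.0), np.ones(4, dtype=int),
                        np.full(4, 0.25))

    def test_matches_exhaustive_search(self, rng):
        for _ in range(120):
            n = int(rng.integers(4, 30))
            values = np.round(rng.normal(size=n), 2)
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            weights = rng.random(n) + 0.01
            weights /= weights.sum()
            _, _, err = train_stump(values, labels, weights)
            _, _, err_bf = brute_force_stump(values, labels, weights)
            assert err == pytest.approx(err_bf, abs=1e-10)

    def test_random_labels_error_near_min_class_mass(self, rng):
        values = rng.normal(size=400)
        labels = rng.integers(0, 2, size=400)
        weights = np.full(400, 1 / 400)
        _, _, err = train_stump(values, labels, weights)
        _, _, err_bf = brute_force_stump(values, labels, weights)
        assert err == pytest.approx(err_bf, abs=1e-10)
        assert err <= min((labels == 0).mean(), (labels == 1).mean()) + 0.02


def _toy_windows(rng, n_pos=12, n_neg=12, window=12):
    """Windows with a dark center blob for positives, flat for negatives."""
    pos = rng.normal(128, 6, size=(n_pos, window, window))
    for p in pos:
        p[4:8, 4:8] -= 90
    neg = rng.normal(128, 6, size=(n_neg, window, window))
    return (np.clip(np.concatenate([pos, neg]), 0, 255),
            np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)])


class TestAdaBoost:
    def test_initial_weights_per_class(self):
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        w = initial_weights(labels)
        assert np.allclose(w, 0.1)
        labels = np.array([1, 1, 0, 0, 0, 0])
        w = initial_weights(labels)
        assert np.allclose(w[labels == 1], 1 / 4)
        assert np.allclose(w[labels == 0], 1 / 8)

    def test_beta_arithmetic(self):
        # e = 0.2 -> beta = 0.25 -> vote log(1/beta)
        e = 0.2
        beta = e / (1 - e)
        assert beta == pytest.approx(0.25)
        assert np.log(1 / beta) == pytest.approx(np.log(4))

    def test_separable_toy_reaches_zero_training_error(self, rng):
        samples, labels = _toy_windows(rng)
        pool = generate_feature_pool(12, position_stride=2, size_stride=2,
                                     min_size=4)
        clf = adaboost(samples, labels, T=3, feature_pool=pool)
        margins = clf.margins(samples)
        pred = (margins >= clf.default_threshold).astype(int)
        assert np.array_equal(pred, labels)
        assert all(e < 0.5 for e in clf.history["errors"])
        assert all(abs(s - 1.0) < 1e-9 for s in clf.history["weight_sums"])

    def test_training_error_non_increasing_in_rounds(self, rng):
        samples, labels = _toy_windows(rng, 20, 20)
        noise = rng.normal(0, 25, size=samples.shape)
        samples = np.clip(samples + noise, 0, 255)
        pool = generate_feature_pool(12, position_stride=2, size_stride=2,
                                     min_size=4)
        errors = []
        for T in (1, 3, 5, 8):
            clf = adaboost(samples, labels, T=T, feature_pool=pool)
            pred = (clf.margins(samples) >= clf.default_threshold).astype(int)
            errors.append((pred != labels).mean())
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_variance_normalization_consistent_between_paths(self, rng):
        samples, labels = _toy_windows(rng)
        pool = generate_feature_pool(12, position_stride=3, size_stride=3,
                                     min_size=4)
        clf = adaboost(samples, labels, T=2, feature_pool=pool,
                       variance_normalize=True)
        assert clf.variance_normalize
        direct = feature_value_matrix(
            samples, [wc.feature for wc in clf.weak], variance_normalize=True)
        votes = np.zeros(len(samples))
        for alpha, wc, row in zip(clf.alphas, clf.weak, direct):
            votes += alpha * wc.evaluate(row)
        assert np.allclose(votes, clf.margins(samples))
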