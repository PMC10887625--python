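"""Analysis CNN: reduction, heads, training contracts and oracles."""

import numpy as np
import pytest

from specfood.analysis_cnn import (
    ANALYSIS_SIZE,
    AnalysisConfig,
    predict,
    reduce_image,
    stack_inputs,
    train_classifier,
    train_estimator,
)


class TestReduceImage:
    def test_constant_image_preserved(self):
        img = np.full((640, 480), 0.7)
        out = reduce_image(img)
        assert out.shape == (64, 64)
        assert np.allclose(out, 0.7)

    def test_identity_at_target_size(self, rng):
        img = rng.random((64, 64))
        assert reduce_image(img) is img

    def test_bounds_preserved(self, rng):
        img = rng.random((128, 96))
        out = reduce_image(img)
        assert out.min() >= img.min() - 1e-6
        assert out.max() <= img.max() + 1e-6

    def test_rgb_planes_supported(self, rng):
        out = reduce_image(rng.random((128, 128, 3)))
        assert out.shape == (64, 64, 3)

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            reduce_image(rng.random((32, 32)))


class TestStackInputs:
    def test_channel_count(self, small_dataset):
        stacks, _ = small_dataset
        X = stack_inputs(stacks, [850, 970])
        assert X.shape == (len(stacks), 5, ANALYSIS_SIZE, ANALYSIS_SIZE)
        assert stack_inputs(stacks, []).shape[1] == 3

    def test_missing_band_raises_keyerror(self, small_dataset):
        stacks, _ = small_dataset
        with pytest.raises(KeyError, match="405"):
            stack_inputs(stacks, [405])


def _two_class_data(rng, n=24, separation=0.35):
    """Linearly separable synthetic planes: class means differ clearly."""
    X, y = [], []
    for i in range(n):
        label = i % 2
        base = 0.3 + separation * label
        X.append(np.clip(base + rng.normal(0, 0.02, (3, 64, 64)), 0, 1))
        y.append(label)
    return np.asarray(X, dtype=np.float32), np.asarray(y)


class TestClassifier:
    def test_separable_classes_reach_perfect_heldout_accuracy(self, rng):
        X, y = _two_class_data(rng)
        Xt, yt = _two_class_data(np.random.default_rng(99))
        cfg = AnalysisConfig(epochs=15, seed=0)
        model = train_classifier(X, y, cfg)
        # nearest-centroid oracle solves this task perfectly; the CNN must too
        centroids = [X[y == c].mean(axis=0) for c in (0, 1)]
        oracle = [int(np.argmin([np.mean((x - c) ** 2) for c in centroids]))
                  for x in Xt]
        assert oracle == list(yt)
        pred = [predict(model, x) for x in Xt]
        assert np.mean(np.asarray(pred) == yt) == 1.0

    def test_deterministic_given_seed(self, rng):
        X, y = _two_class_data(rng, n=12)
        cfg = AnalysisConfig(epochs=3, seed=5)
        m1 = train_classifier(X, y, cfg)
        m2 = train_classifier(X, y, cfg)
        for a, b in zip(m1.layers, m2.layers):
            for pa, pb in zip(a.params(), b.params()):
                assert np.array_equal(pa, pb)
        assert m1.loss_history == m2.loss_history

    def test_softmax_output_sums_to_one(self, rng):
        X, y = _two_class_data(rng, n=12)
        model = train_classifier(X, y, AnalysisConfig(epochs=2, seed=0))
        p = model.predict_proba(X[:4])
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_label_validation(self, rng):
        X, _ = _two_class_data(rng, n=12)
        with pytest.raises(ValueError):
            train_classifier(X, np.zeros(12, dtype=int),
                             AnalysisConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            train_classifier(X, np.array([-1] + [1] * 11),
                             AnalysisConfig(epochs=1, seed=0))


class TestEstimator:
    def test_constant_targets_reach_zero_mape(self, rng):
        X, _ = _two_class_data(rng, n=12)
        targets = np.full(12, 150.0)
        model = train_estimator(X, targets, AnalysisConfig(epochs=60, seed=1))
        preds = [predict(model, x) for x in X]
        from specfood.metrics_report import mape

        assert mape(targets, preds) < 1.0

    def test_zero_target_rejected_without_floor(self, rng):
        X, _ = _two_class_data(rng, n=12)
        with pytest.raises(ValueError, match="floor"):
            train_estimator(X, [0.0] + [100.0] * 11,
                            AnalysisConfig(epochs=1, seed=0))

    def test_area_regression_oracle(self, rng):
        # kcal proportional to food-pixel area: a linear function of the
        # mean band plane, so an accurate estimator exists; demand < 10%
        # held-out MAPE at small scale.
        from specfood.metrics_report import mape
        from specfood.spectral_scene import make_catalog, make_dataset

        cat = make_catalog(2, 0, 0.3, (100.0, 100.0), seed=8)
        stacks, recs = make_dataset(cat, 24, [850], 4, 0.0, (64, 64), seed=9)
        t_stacks, t_recs = make_dataset(cat, 8, [850], 4, 0.0, (64, 64), seed=10)
        X = stack_inputs(stacks, [850])
        Xt = stack_inputs(t_stacks, [850])
        y = np.asarray([r.kcal for r in recs])
        yt = np.asarray([r.kcal for r in t_recs])
        model = train_estimator(X, y, AnalysisConfig(epochs=60, seed=2))
        preds = [predict(model, x) for x in Xt]
        assert mape(yt, preds) < 10.0


class TestPredict:
    def test_argmax_semantics(self, rng):
        X, y = _two_class_data(rng, n=12)
        model = train_classifier(X, y, AnalysisConfig(epochs=2, seed=0))
        p = model.predict_proba(X[:1])[0]
        assert predict(model, X[0]) == int(np.argmax(p))

    def test_channel_mismatch(self, rng):
        X, y = _two_class_data(rng, n=12)
        model = train_classifier(X, y, AnalysisConfig(epochs=1, seed=0))
        with pytest.raises(ValueError, match="channel"):
            predict(model, rng.random((5, 64, 64)).astype(np.float32))
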