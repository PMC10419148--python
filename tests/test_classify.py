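"""Classifier unit tests: metrics identities, ROC/AUC oracle, CNN behaviour."""

import numpy as np
import pandas as pd
import pytest

from holocyte import classify as cl
from holocyte.exceptions import ConfigurationError


def concordance_auc(scores, labels):
    """Pairwise-concordance oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def gaussian_clouds(n=1000, sep=5.0, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack([
        rng.normal(-sep, sd, size=(n, 25)),
        rng.normal(+sep, sd, size=(n, 25)),
    ])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return x, y


class TestTrainLogistic:
    def test_separable_clouds_near_perfect(self):
        x, y = gaussian_clouds()
        _, report = cl.train_logistic(x, y, cl.TrainConfig(seed=0, repeats=3))
        assert report.accuracy_mean >= 99.0
        assert report.auc >= 0.999

    def test_permuted_labels_at_chance(self):
        x, y = gaussian_clouds(n=1000)
        rng = np.random.default_rng(3)
        y_perm = rng.permutation(y)
        _, report = cl.train_logistic(x, y_perm, cl.TrainConfig(seed=1, repeats=5))
        assert abs(report.accuracy_mean - 50.0) < 5.0

    def test_deterministic_given_seed(self):
        x, y = gaussian_clouds(n=200)
        _, r1 = cl.train_logistic(x, y, cl.TrainConfig(seed=5, repeats=2))
        _, r2 = cl.train_logistic(x, y, cl.TrainConfig(seed=5, repeats=2))
        assert r1.accuracy_mean == r2.accuracy_mean
        assert r1.auc == r2.auc
        assert r1.roc_points == r2.roc_points

    def test_single_class_rejected(self):
        x = np.zeros((10, 25))
        with pytest.raises(ConfigurationError):
            cl.train_logistic(x, np.zeros(10, int))

    def test_non_finite_features_named(self):
        x, y = gaussian_clouds(n=50)
        x[7, 3] = np.nan
        with pytest.raises(ConfigurationError, match="7"):
            cl.train_logistic(x, y)

    def test_string_labels_accepted(self):
        x, y = gaussian_clouds(n=200)
        labels = np.where(y == 1, "SCD", "NOR")
        _, report = cl.train_logistic(x, labels, cl.TrainConfig(seed=0, repeats=2))
        assert report.accuracy_mean >= 99.0


class TestMetricsIdentities:
    def test_accuracy_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            y = rng.integers(0, 2, size=100)
            if y.min() == y.max():
                continue
            pred = rng.integers(0, 2, size=100)
            sens, spec, acc = cl._split_metrics(y, pred)
            p, n = (y == 1).sum(), (y == 0).sum()
            assert acc == pytest.approx((sens * p + spec * n) / (p + n), rel=1e-12)

    def test_label_swap_swaps_sensitivity_and_specificity(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, size=200)
        pred = rng.integers(0, 2, size=200)
        sens, spec, _ = cl._split_metrics(y, pred)
        sens_sw, spec_sw, _ = cl._split_metrics(1 - y, 1 - pred)
        assert sens == spec_sw
        assert spec == sens_sw


class TestRocAuc:
    def test_hand_computed_example(self):
        points, auc = cl.roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75, rel=1e-12)

    def test_perfect_scores(self):
        _, auc = cl.roc_auc([1.0, 1.0, 0.0, 0.0], [1, 1, 0, 0])
        assert auc == 1.0

    def test_constant_scores_are_chance(self):
        _, auc = cl.roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == pytest.approx(0.5, rel=1e-12)

    def test_equals_concordance_oracle_with_ties(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = rng.integers(4, 30)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 5, size=n) / 4.0  # coarse grid forces ties
            _, auc = cl.roc_auc(scores, labels)
            assert auc == pytest.approx(concordance_auc(scores, labels), rel=1e-10)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        points, _ = cl.roc_auc(scores, labels)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            cl.roc_auc([0.1, 0.9], [1, 1])


class _StubModel:
    def predict_proba(self, x):
        scores = np.asarray(x, float)[:, 0]
        return np.vstack([1 - scores, scores]).T


class TestPredictCells:
    def test_exact_half_score_is_normal(self):
        model = cl.TrainedModel("LR", _StubModel(), ("f",), {})
        scores, hard = cl.predict_cells(model, np.array([[0.5], [0.500001]]))
        assert hard[0] == 0  # strict inequality at the boundary
        assert hard[1] == 1

    def test_identical_cells_identical_scores(self):
        x, y = gaussian_clouds(n=100)
        model, _ = cl.train_logistic(x, y, cl.TrainConfig(seed=0, repeats=1))
        dup = np.vstack([x[0], x[0]])
        scores, _ = cl.predict_cells(model, dup)
        assert scores[0] == scores[1]

    def test_schema_mismatch_rejected(self):
        x, y = gaussian_clouds(n=100)
        model, _ = cl.train_logistic(x, y, cl.TrainConfig(seed=0, repeats=1))
        with pytest.raises(ConfigurationError):
            cl.predict_cells(model, np.zeros((5, 7)))

    def test_training_data_of_separable_fit_all_correct(self):
        x, y = gaussian_clouds(n=300)
        model, _ = cl.train_logistic(x, y, cl.TrainConfig(seed=0, repeats=1))
        _, hard = cl.predict_cells(model, x)
        assert np.array_equal(hard, y)


class TestEvaluateSample:
    def test_percentage_arithmetic(self):
        model = cl.TrainedModel("LR", _StubModel(), ("f",), {})
        x = np.zeros((100, 1))
        x[:26, 0] = 1.0  # 26 cells scored as SCD
        pred = cl.evaluate_sample(model, x, sample_id="s")
        assert pred.pct_scd == pytest.approx(26.0)
        assert pred.pct_normal == pytest.approx(74.0)
        assert pred.pct_normal + pred.pct_scd == pytest.approx(100.0)
        assert pred.n_cells == 100

    def test_empty_sample_rejected(self):
        model = cl.TrainedModel("LR", _StubModel(), ("f",), {})
        with pytest.raises(ConfigurationError):
            cl.evaluate_sample(model, np.zeros((0, 1)))


def disc_vs_crescent_crops(n_per_class=120, seed=0):
    """Noiseless synthetic crops: discs vs 3:1 crescents."""
    from holocyte import synthgen as sg
    im = sg.ImagingConfig(background_phase_sd=0.0, background_residual_sd=0.0)
    rng = np.random.default_rng(seed)
    imgs, labels = [], []
    for i in range(n_per_class):
        r = 3.0 + 0.4 * rng.random()
        imgs.append(sg.make_normal_phase_image(
            sg.CellShapeParams("normal_like", radius_um=r, elongation=1.0,
                               dimple_depth=0.4, peak_phase_rad=1.2), im, rng))
        labels.append(0)
        imgs.append(sg.make_sickled_phase_image(
            sg.CellShapeParams("critically_sickled", radius_um=2.5, elongation=3.0,
                               curvature=0.4, peak_phase_rad=1.8, dimple_depth=0.0), im, rng))
        labels.append(1)
    return imgs, np.array(labels)


class TestTrainCnn:
    def test_separable_crops_high_accuracy(self):
        imgs, labels = disc_vs_crescent_crops()
        cfg = cl.TrainConfig(seed=0, repeats=1, cnn_epochs=5)
        _, report = cl.train_cnn(imgs, labels, cfg)
        assert report.accuracy_mean >= 95.0

    def test_deterministic_given_seed(self):
        imgs, labels = disc_vs_crescent_crops(n_per_class=40)
        cfg = cl.TrainConfig(seed=3, repeats=1, cnn_epochs=2)
        _, r1 = cl.train_cnn(imgs, labels, cfg)
        _, r2 = cl.train_cnn(imgs, labels, cfg)
        assert r1.accuracy_mean == r2.accuracy_mean
        assert r1.auc == r2.auc

    def test_permuted_labels_near_chance(self):
        imgs, labels = disc_vs_crescent_crops(n_per_class=80)
        rng = np.random.default_rng(1)
        cfg = cl.TrainConfig(seed=1, repeats=2, cnn_epochs=2)
        _, report = cl.train_cnn(imgs, rng.permutation(labels), cfg)
        assert abs(report.accuracy_mean - 50.0) <= 15.0

    def test_prepare_inputs_scales_to_unit_range(self):
        imgs, _ = disc_vs_crescent_crops(n_per_class=3)
        x = cl.prepare_cnn_inputs(imgs, cl.TrainConfig())
        assert x.shape == (6, 32, 32)
        assert x.min() >= 0.0 and x.max() <= 1.0
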