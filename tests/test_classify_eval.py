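"""Classifier wrappers, the benchmark protocol, significance and scoring."""

import numpy as np
import pytest

from saxsshape import (
    Dataset,
    INFORMATIVE_PAIRS,
    MethodSpec,
    ValidationError,
    compare_wilcoxon,
    confusion_report,
    cross_validate,
    real_data_score,
    score_sessions,
    train_method,
    transfer_matrix,
)
from saxsshape.classify_eval import make_classifier


def _feature_dataset(x, y, q0=0.001, q1=0.15):
    """Wrap a plain feature matrix as a Dataset on a fabricated q grid."""
    n, j = x.shape
    q = np.broadcast_to(np.linspace(q0, q1, j), (n, j)).copy()
    return Dataset(x, q, y, ["synthetic"] * n)


class TestClassifiers:
    def test_all_classifiers_separate_gaussian_blobs(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (250, 5)), rng.normal(5, 0.3, (250, 5))])
        y = np.array([0] * 250 + [1] * 250)
        test_x = np.vstack([rng.normal(0, 0.3, (50, 5)), rng.normal(5, 0.3, (50, 5))])
        test_y = np.array([0] * 50 + [1] * 50)
        for name in ("KNN", "RF", "XGB"):
            clf = make_classifier(name, {}, seed=0)
            clf.fit(x, y)
            assert (clf.predict(test_x) == test_y).mean() >= 0.99

    def test_perceptron_layer_separates_blob_curves(self, rng):
        """The CNN+softmax head (PL) reaches >= 99% on trivially separable curves."""
        n = 40
        x = rng.standard_normal((2 * n, 150)).astype(np.float32) * 0.05
        x[:n, 20:50] += 2.0
        x[n:, 90:120] += 2.0
        y = np.array([0] * n + [1] * n)
        ds = _feature_dataset(x, y)
        spec = MethodSpec(preprocess=[], representation="cnn", classifier="PL")
        fitted = train_method(spec, ds.intensities, ds.q_grids, ds.labels, seed=0,
                              train_opts={"cnn_epochs": 15, "batch_size": 16})
        assert (fitted.predict(ds.intensities, ds.q_grids) == y).mean() >= 0.99

    def test_knn_k1_perfect_on_training_set(self, rng):
        x = rng.random((30, 4))
        y = rng.integers(0, 3, 30)
        clf = make_classifier("KNN", {"n_neighbors": 1}, seed=0)
        clf.fit(x, y)
        assert (clf.predict(x) == y).all()

    def test_rf_seeded_deterministic(self, rng):
        x = rng.random((60, 6))
        y = rng.integers(0, 2, 60)
        preds = []
        for _ in range(2):
            clf = make_classifier("RF", {"n_estimators": 50}, seed=42)
            clf.fit(x, y)
            preds.append(clf.predict(x))
        np.testing.assert_array_equal(*preds)

    def test_pl_requires_cnn_representation(self):
        with pytest.raises(ValidationError, match="PL"):
            MethodSpec(representation="identity", classifier="PL")


class TestCrossValidate:
    def test_perfect_feature_gives_accuracy_one(self, rng):
        y = np.repeat(np.arange(3), 30)
        x = rng.random((90, 10)) * 0.01
        x[:, 0] = y  # label encoded in the dominant feature
        report = cross_validate(
            MethodSpec(preprocess=[], representation="identity", classifier="RF",
                       hyperparameters={"n_estimators": 100}),
            _feature_dataset(x, y), k=5, repeats=2, seed=0,
        )
        assert report.mean_accuracy == 1.0

    def test_shuffled_labels_give_chance_level(self, rng):
        """Pure-noise features score at the 1/9 chance level within 3σ."""
        n_per_class = 30
        y = rng.permutation(np.repeat(np.arange(9), n_per_class))
        x = rng.random((9 * n_per_class, 12))
        report = cross_validate(
            MethodSpec(preprocess=[], representation="identity", classifier="KNN"),
            _feature_dataset(x, y), k=3, repeats=3, seed=1,
        )
        n_total = 9 * n_per_class * 3  # every curve tested once per repeat
        p = 1.0 / 9.0
        band = 3.0 * np.sqrt(p * (1 - p) / n_total)
        assert abs(report.mean_accuracy - p) < band + 0.02

    def test_report_contains_exactly_repeats_accuracies(self, rng):
        y = np.repeat(np.arange(2), 20)
        x = rng.random((40, 5))
        x[:, 0] = y
        report = cross_validate(
            MethodSpec(preprocess=[], representation="identity", classifier="KNN"),
            _feature_dataset(x, y), k=4, repeats=6, seed=0,
        )
        assert report.accuracies.shape == (6,)
        assert np.all((report.accuracies >= 0) & (report.accuracies <= 1))

    def test_class_smaller_than_k_rejected(self, rng):
        y = np.array([0, 0, 0, 1, 1])
        x = rng.random((5, 3))
        with pytest.raises(ValidationError, match="at least"):
            cross_validate(MethodSpec(preprocess=[], representation="identity"),
                           _feature_dataset(x, y), k=4)

    def test_leakage_canary(self, rng):
        """A label-encoding feature present only at prediction time must not
        help: everything is fitted strictly on the training data."""
        y = rng.permutation(np.repeat(np.arange(3), 80))
        x = rng.random((240, 8))
        ds = _feature_dataset(x, y)
        spec = MethodSpec(preprocess=["TH", "STD"], representation="identity",
                          classifier="RF", hyperparameters={"n_estimators": 50})
        train, test = np.arange(120), np.arange(120, 240)
        fitted = train_method(spec, ds.intensities[train], ds.q_grids[train],
                              ds.labels[train], seed=0)
        doctored = ds.intensities[test].copy()
        doctored[:, 0] = y[test]  # canary injected only into the held-out set
        acc = (fitted.predict(doctored, ds.q_grids[test]) == y[test]).mean()
        assert acc < 1.0 / 3.0 + 0.15


class TestWilcoxon:
    def test_identical_vectors_indistinguishable(self):
        a = [0.8] * 20
        assert compare_wilcoxon(a, a) == "indistinguishable"

    def test_fully_separated_vectors(self):
        assert compare_wilcoxon([0.9] * 20, [0.5] * 20) == "better"
        assert compare_wilcoxon([0.5] * 20, [0.9] * 20) == "worse"

    def test_tiny_shift_below_noise_indistinguishable(self, rng):
        a = rng.normal(0.80, 0.05, 20)
        b = a + 0.002
        assert compare_wilcoxon(a, b, alpha=0.01) == "indistinguishable"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            compare_wilcoxon([0.5] * 10, [0.5] * 20)


class TestTransferMatrix:
    def test_grid_length_mismatch_rejected(self, rng):
        y = np.repeat(np.arange(2), 10)
        a = _feature_dataset(rng.random((20, 8)), y)
        b = _feature_dataset(rng.random((20, 9)), y)
        with pytest.raises(ValidationError, match="resample_to_grid"):
            transfer_matrix(MethodSpec(preprocess=[], representation="identity"),
                            {"A": a}, {"B": b})

    def test_diagonal_structure_on_disjoint_domains(self, rng):
        """Training on one synthetic 'configuration' transfers poorly to a
        shifted one, while matched train/test stays accurate."""
        def make(shift, seed):
            r = np.random.default_rng(seed)
            y = np.repeat(np.arange(2), 40)
            x = r.normal(0, 0.2, (80, 6))
            x[y == 1] += 1.0
            x += shift
            return _feature_dataset(x, y)

        spec = MethodSpec(preprocess=[], representation="identity", classifier="KNN")
        table = transfer_matrix(
            spec,
            {"domain0": make(0.0, 1), "domain5": make(5.0, 2)},
            {"domain0": make(0.0, 3), "domain5": make(5.0, 4)},
            repeats=1,
        )
        assert table["domain0"]["domain0"] > table["domain0"]["domain5"]
        assert table["domain5"]["domain5"] > table["domain5"]["domain0"]


class TestConfusionReport:
    def test_perfect_predictions_identity_matrix(self):
        y = np.repeat(np.arange(4), 10)
        mat, recall = confusion_report(y, y)
        np.testing.assert_array_equal(mat, np.eye(4))
        assert all(v == 1.0 for v in recall.values())

    def test_rows_sum_to_one(self, rng):
        y = rng.integers(0, 5, 200)
        pred = rng.integers(0, 5, 200)
        mat, _ = confusion_report(y, pred)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-9)

    def test_uniform_random_predictions_near_uniform_rows(self, rng):
        y = np.repeat(np.arange(9), 400)
        pred = rng.integers(0, 9, y.size)
        mat, _ = confusion_report(y, pred)
        assert np.abs(mat - 1.0 / 9.0).max() < 0.06


class TestRealDataScore:
    def test_all_correct_is_plus_ten(self):
        labels = ["sphere"] * 6 + ["prolate_ellipsoid"] * 3 + ["core_shell_sphere"]
        assert real_data_score(labels, labels).total == 10

    def test_sphere_predicted_prolate_is_informative(self):
        score = real_data_score(["prolate_ellipsoid"], ["sphere"])
        assert score.contributions == [0]

    def test_sphere_predicted_core_shell_cylinder_is_wrong(self):
        assert real_data_score(["core_shell_cylinder"], ["sphere"]).contributions == [-1]

    def test_all_wrong_is_minus_ten(self):
        truth = ["sphere"] * 10
        assert real_data_score(["core_shell_cylinder"] * 10, truth).total == -10

    def test_informative_map_is_symmetric(self):
        for pair in INFORMATIVE_PAIRS:
            a, b = tuple(pair) if len(pair) == 2 else (next(iter(pair)),) * 2
            assert real_data_score([a], [b]).contributions == [0]
            assert real_data_score([b], [a]).contributions == [0]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            real_data_score(["pyramid"], ["sphere"])

    def test_session_frequencies_sum_to_one(self):
        sessions = [["sphere", "oblate_ellipsoid"], ["sphere", "sphere"], ["cylinder", "sphere"]]
        result = score_sessions(sessions, ["sphere", "sphere"])
        for freq in result["per_sample_frequencies"]:
            assert sum(freq.values()) == pytest.approx(1.0)
        assert result["session_scores"] == [1, 2, 0]
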