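import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gars.datamodel import ClassLabels, FeatureMatrix
from gars.evaluation import (
    ConfusionMetrics,
    auc_binary,
    confusion_metrics,
    cross_validate_selection,
    evaluate_on_test,
    pearson_trend,
    radar_area,
    robustness,
    scale_metrics_for_radar,
    select_best_model,
    stratified_kfold,
    train_classifier_and_predict,
)
from gars.ga import GAConfig
from gars.synthetic import SyntheticSpec, generate


def shoelace_radar_area(radii):
    """Oracle: shoelace formula on the polygon's Cartesian vertices."""
    r = np.asarray(radii, dtype=float)
    n = r.size
    ang = 2 * np.pi * np.arange(n) / n
    x, y = r * np.cos(ang), r * np.sin(ang)
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestStratifiedKFold:
    def test_balanced_fifty_samples(self):
        y = ClassLabels(("T",) * 25 + ("NT",) * 25)
        folds = stratified_kfold(y, folds=5, seed=0)
        assert len(folds) == 5
        labels = np.array(y.labels)
        for tr, va in folds:
            assert len(va) == 10
            assert (labels[va] == "T").sum() == 5
        all_val = np.sort(np.concatenate([va for _, va in folds]))
        assert np.array_equal(all_val, np.arange(50))

    def test_no_overlap_within_fold(self):
        y = ClassLabels(("A",) * 12 + ("B",) * 9)
        for tr, va in stratified_kfold(y, folds=3, seed=2):
            assert not set(tr) & set(va)

    def test_same_seed_identical(self):
        y = ClassLabels(("A",) * 10 + ("B",) * 10)
        a = stratified_kfold(y, folds=5, seed=9)
        b = stratified_kfold(y, folds=5, seed=9)
        for (t1, v1), (t2, v2) in zip(a, b):
            assert np.array_equal(v1, v2)

    def test_small_class_named_in_error(self):
        y = ClassLabels(("A",) * 10 + ("B",) * 4)
        with pytest.raises(ValueError, match="B"):
            stratified_kfold(y, folds=5, seed=0)


class TestClassifier:
    def test_separable_data_perfect_validation(self, separated_dataset):
        X, y, truth = separated_dataset
        pred, proba = train_classifier_and_predict(X, y, X, truth.planted_indices, seed=0)
        assert np.all(pred == np.array(y.labels))
        assert proba.shape == (X.n_samples, 2)

    def test_deterministic_given_seed(self, separated_dataset):
        X, y, truth = separated_dataset
        a = train_classifier_and_predict(X, y, X, truth.planted_indices, seed=5)
        b = train_classifier_and_predict(X, y, X, truth.planted_indices, seed=5)
        assert np.array_equal(a[0], b[0])
        assert np.allclose(a[1], b[1])

    def test_permuted_labels_near_chance(self, separated_dataset):
        X, y, truth = separated_dataset
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(3):
            perm = tuple(rng.permutation(np.array(y.labels)))
            yp = ClassLabels(perm, classes=y.classes)
            tr, va = np.arange(0, X.n_samples, 2), np.arange(1, X.n_samples, 2)
            pred, _ = train_classifier_and_predict(
                X.take_samples(tr), yp.take(tr), X.take_samples(va),
                truth.planted_indices, seed=seed, n_estimators=100,
            )
            accs.append(np.mean(pred == np.array(yp.take(va).labels)))
        majority = max(np.mean(np.array(y.labels) == c) for c in y.classes)
        assert abs(np.mean(accs) - majority) < 0.25

    def test_missing_feature_errors(self, separated_dataset):
        X, y, _ = separated_dataset
        with pytest.raises(ValueError, match="absent"):
            train_classifier_and_predict(X, y, X, ["no_such_feature"])


class TestConfusionMetrics:
    def test_perfect_binary(self):
        m = confusion_metrics(
            ["T", "T", "NT", "NT"], ["T", "T", "NT", "NT"], positive_class="T"
        )
        assert (m.ACC, m.SEN, m.SPE, m.PPV, m.NPV) == (1, 1, 1, 1, 1)

    def test_unbalanced_binary_table(self):
        # TP=5 FN=1 TN=36 FP=14 on 6 positives / 50 negatives
        truth = ["AKI"] * 6 + ["non"] * 50
        pred = ["AKI"] * 5 + ["non"] + ["AKI"] * 14 + ["non"] * 36
        m = confusion_metrics(truth, pred, positive_class="AKI")
        assert m.SEN == pytest.approx(5 / 6, abs=1e-12)
        assert m.SPE == pytest.approx(36 / 50, abs=1e-12)
        assert m.PPV == pytest.approx(5 / 19, abs=1e-12)
        assert m.ACC == pytest.approx(41 / 56, abs=1e-12)

    def test_all_predicted_positive_flags_npv(self):
        m = confusion_metrics(["T", "NT"], ["T", "T"], positive_class="T")
        assert m.SEN == 1.0 and m.SPE == 0.0
        assert "NPV" in m.undefined_rates

    def test_macro_reduces_to_binary_on_symmetric_tables(self):
        truth = ["A"] * 4 + ["B"] * 4
        pred = ["A", "A", "A", "B", "B", "B", "B", "A"]
        macro = confusion_metrics(truth, pred, classes=("A", "B"), positive_class=None)
        binary = confusion_metrics(truth, pred, positive_class="A")
        # symmetric confusion table: per-class rates coincide with both
        # positive-class conventions, so the macro average equals either
        assert macro.SEN == pytest.approx(binary.SEN)
        assert macro.SPE == pytest.approx(binary.SPE)

    def test_multiclass_macro_hand_example(self):
        truth = ["A", "A", "B", "B", "C", "C"]
        pred = ["A", "B", "B", "B", "C", "A"]
        m = confusion_metrics(truth, pred, classes=("A", "B", "C"))
        # per-class SEN: A=1/2, B=1, C=1/2 -> macro 2/3
        assert m.SEN == pytest.approx(2 / 3, abs=1e-12)
        assert m.ACC == pytest.approx(4 / 6, abs=1e-12)

    def test_stray_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(["A", "B"], ["A", "Z"], classes=("A", "B"))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_binary(["+", "+", "-", "-"], [0.9, 0.8, 0.2, 0.1], "+") == 1.0

    def test_constant_scores_half(self):
        assert auc_binary(["+", "-", "+", "-"], [0.5] * 4, "+") == 0.5

    def test_enumerated_pairs(self):
        assert auc_binary(["+", "-", "+", "-"], [0.9, 0.8, 0.4, 0.3], "+") == 0.75

    def test_matches_pair_counting_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 21))
            labels = ["+"] * (n // 2) + ["-"] * (n - n // 2)
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            got = auc_binary(labels, scores, "+")
            pos = scores[: n // 2]
            neg = scores[n // 2 :]
            pairs = [
                1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
            ]
            assert got == pytest.approx(np.mean(pairs), abs=1e-12)
            expected = roc_auc_score([1] * (n // 2) + [0] * (n - n // 2), scores)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_binary(["+", "+"], [0.1, 0.2], "+")


class TestBestModel:
    @staticmethod
    def metrics(acc=0.9, auc=None, nfeat=10):
        return ConfusionMetrics(acc, acc, acc, acc, acc, AUC=auc, n_features=nfeat)

    def test_auc_tie_broken_by_fewest_features(self):
        folds = [
            self.metrics(auc=0.90, nfeat=10),
            self.metrics(auc=0.95, nfeat=12),
            self.metrics(auc=0.95, nfeat=8),
        ]
        assert select_best_model(folds, "binary") == 2

    def test_single_fold(self):
        assert select_best_model([self.metrics(auc=0.5)], "binary") == 0

    def test_full_tie_takes_first(self):
        folds = [self.metrics(auc=0.9, nfeat=5)] * 3
        assert select_best_model(folds, "binary") == 0

    def test_multiclass_uses_accuracy(self):
        folds = [self.metrics(acc=0.8), self.metrics(acc=0.9)]
        assert select_best_model(folds, "multiclass") == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_model([], "binary")


class TestRadar:
    def test_single_run_constant_columns_map_to_one(self):
        rows = [{"ACC": 0.8, "SEN": 0.7, "SPE": 0.9, "PPV": 0.6, "NPV": 0.95,
                 "AUC": 0.85, "Time": 240.0, "Nfeats": 14}]
        radii, axes = scale_metrics_for_radar(rows)
        lut = dict(zip(axes, radii[0]))
        assert lut["Time"] == 1.0 and lut["Nfeats"] == 1.0
        assert lut["ACC"] == 0.8

    def test_time_scaling_inverted(self):
        rows = [{"ACC": 1.0, "Time": t, "Nfeats": 5} for t in (1.0, 240.0, 10920.0)]
        radii, axes = scale_metrics_for_radar(rows)
        times = [dict(zip(axes, r))["Time"] for r in radii]
        assert times[0] == 1.0
        assert times[1] == pytest.approx(1 - 239 / 10919, abs=1e-9)
        assert times[2] == 0.0

    def test_unit_polygon_is_full_area(self):
        for n in range(3, 11):
            assert radar_area([1.0] * n).A_percent == pytest.approx(100.0, abs=1e-12)

    def test_zero_radii_zero_area(self):
        assert radar_area([0.0] * 6).A_percent == 0.0

    def test_worked_eight_axis_example(self):
        radii = (1, 1, 1, 1, 1, 1, 0.978, 0.886)
        score = radar_area(radii)
        expected_cov = 0.5 * np.sin(np.pi / 4) * (5 + 0.978 + 0.978 * 0.886 + 0.886)
        assert score.A_cov == pytest.approx(expected_cov, abs=1e-12)
        assert score.A_max == pytest.approx(4 * np.sin(np.pi / 4), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_shoelace_oracle(self, seed):
        rng = np.random.default_rng(seed)
        radii = rng.uniform(0, 1, int(rng.integers(3, 12)))
        assert radar_area(radii).A_cov == pytest.approx(
            shoelace_radar_area(radii), abs=1e-10
        )

    def test_monotone_in_each_radius(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(0.1, 0.9, 6)
        base = radar_area(r).A_percent
        for i in range(6):
            bumped = r.copy()
            bumped[i] += 0.05
            assert radar_area(bumped).A_percent >= base

    def test_too_few_radii(self):
        with pytest.raises(ValueError):
            radar_area([1.0, 1.0])


class TestRobustness:
    def test_identical_accuracies_zero_delta(self):
        r = robustness(train_acc=[0.9] * 5, val_acc=[0.9] * 5)
        assert r.delta_mean == 0.0 and r.ci95 == (0.0, 0.0)

    def test_constant_gap_zero_width_ci(self):
        r = robustness(train_acc=[0.9] * 5, val_acc=[0.8] * 5)
        assert r.delta_mean == pytest.approx(0.1)
        assert r.ci95[0] == pytest.approx(r.ci95[1])

    def test_t_interval_arithmetic(self):
        from scipy.stats import t

        r = robustness(train_acc=[1.0] * 5, val_acc=[1.0, 0.9, 0.8, 0.7, 0.6])
        half = t.ppf(0.975, 4) * np.std([0, 0.1, 0.2, 0.3, 0.4], ddof=1) / np.sqrt(5)
        assert r.delta_mean == pytest.approx(0.2)
        assert r.ci95 == pytest.approx((0.2 - half, 0.2 + half))

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            robustness(train_acc=[0.9], val_acc=[0.8])


class TestPearsonTrend:
    def test_exact_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_trend(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_trend([1, 2, 3], [5, 5, 5])


@pytest.fixture(scope="module")
def cv_result():
    spec = SyntheticSpec(
        n_per_class=15, n_classes=2, m_total=30, k_informative=3,
        effect_size=4.0, seed=11,
    )
    X, y, _ = generate(spec)
    cfg = GAConfig(l_min=3, l_max=3, k=16, iterations=6, seed=11)
    return X, y, cross_validate_selection(X, y, cfg, folds=5, cv_seed=1)


class TestHarness:
    def test_five_fold_records_with_metrics(self, cv_result):
        _, _, cv = cv_result
        assert len(cv.folds) == 5
        for rec in cv.folds:
            assert 0 <= rec.metrics.ACC <= 1
            assert rec.metrics.AUC is not None  # binary task
            assert len(rec.selected_features) == 3
            assert rec.metrics.learning_time > 0

    def test_best_fold_follows_rule(self, cv_result):
        _, _, cv = cv_result
        assert cv.best_index == select_best_model(list(cv.folds), cv.task)

    def test_separable_independent_test_perfect(self, cv_result):
        X, y, cv = cv_result
        best = cv.folds[cv.best_index]
        m = evaluate_on_test(X, y, X, y, list(best.selected_features))
        assert m.ACC == 1.0
        assert m.AUC == 1.0
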