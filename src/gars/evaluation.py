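"""Benchmarking harness: stratified CV around the selector, random-forest
classification, confusion metrics, AUC, best-model choice, radar-polygon
aggregate score, robustness gap, and trend correlations.

The harness mirrors the standard wrapper-method evaluation protocol: the
data are split into a learning set and an independent test set; the learning
set undergoes stratified 5-fold cross-validation in which each training
split selects features (here, via the GA) and fits a random-forest
classifier whose performance is measured on the validation split. The best
fold's model is finally re-fit on the whole learning set and scored once on
the independent test set.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .datamodel import ClassLabels, FeatureMatrix
from .fitness import subset_columns
from .ga import GAConfig, run_length_sweep

__all__ = [
    "ConfusionMetrics",
    "FoldRecord",
    "CVResult",
    "RadarScore",
    "RobustnessResult",
    "RADAR_METRIC_ORDER",
    "stratified_kfold",
    "train_classifier_and_predict",
    "confusion_metrics",
    "auc_binary",
    "select_best_model",
    "scale_metrics_for_radar",
    "radar_area",
    "robustness",
    "pearson_trend",
    "cross_validate_selection",
    "evaluate_on_test",
]

#: Fixed radar-axis ordering; polygon area depends on adjacency.
RADAR_METRIC_ORDER = ("ACC", "SEN", "SPE", "PPV", "NPV", "AUC", "Time", "Nfeats")

#: Axes scaled across runs and inverted (smaller raw value = larger radius).
_INVERTED_AXES = ("Time", "Nfeats")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Classification rates in [0, 1] plus bookkeeping for the radar axes.

    ``undefined_rates`` names rates whose denominator was zero; they are
    reported as 0 rather than dropped so every radar radius is defined.
    """

    ACC: float
    SEN: float
    SPE: float
    PPV: float
    NPV: float
    AUC: float | None = None
    n_features: int | None = None
    learning_time: float | None = None
    undefined_rates: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FoldRecord:
    """One CV fold: validation metrics, the features it selected, and the
    training-set accuracy used by the robustness analysis."""

    metrics: ConfusionMetrics
    selected_features: tuple[str, ...]
    genes: tuple[int, ...]
    train_accuracy: float
    fitness: float


@dataclass(frozen=True)
class CVResult:
    folds: tuple[FoldRecord, ...]
    task: str  # "binary" | "multiclass"
    best_index: int


@dataclass(frozen=True)
class RadarScore:
    radii: tuple[float, ...]
    gamma: float
    A_cov: float
    A_max: float
    A_percent: float


@dataclass(frozen=True)
class RobustnessResult:
    delta_mean: float
    ci95: tuple[float, float]
    per_fold_delta: tuple[float, ...] = ()


def stratified_kfold(
    labels: ClassLabels, folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified partition; per-class fold counts differ by <=1."""
    counts = labels.class_counts()
    too_small = [c for c, k in counts.items() if k < folds]
    if too_small:
        raise ValueError(
            f"classes smaller than {folds} folds: {too_small} "
            f"(sizes {[counts[c] for c in too_small]})"
        )
    y = np.array(labels.labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros((len(y), 1)), y)]


def train_classifier_and_predict(
    train_matrix: FeatureMatrix,
    train_labels: ClassLabels,
    eval_matrix: FeatureMatrix,
    selected_features,
    seed: int = 0,
    n_estimators: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a random forest on the selected feature columns and predict.

    ``selected_features`` is a sequence of 1-based feature indices (a
    chromosome) or of feature_id strings. Returns hard labels and per-class
    vote fractions (columns in ``train_labels.classes`` order) for the
    evaluation matrix.
    """
    genes = _resolve_features(train_matrix, selected_features)
    if len(train_labels.classes) < 2:
        raise ValueError("training labels must contain >=2 classes")
    X_train = subset_columns(train_matrix, genes).values
    X_eval = subset_columns(eval_matrix, genes).values
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X_train, np.array(train_labels.labels))
    pred = clf.predict(X_eval)
    proba = clf.predict_proba(X_eval)
    # reorder probability columns to the labels' class order
    order = [list(clf.classes_).index(c) for c in train_labels.classes if c in clf.classes_]
    return pred, proba[:, order]


def _resolve_features(matrix: FeatureMatrix, selected) -> tuple[int, ...]:
    selected = list(getattr(selected, "genes", selected))
    if not selected:
        raise ValueError("no features selected")
    if all(isinstance(s, str) for s in selected):
        lut = {f: j + 1 for j, f in enumerate(matrix.feature_ids)}
        missing = [s for s in selected if s not in lut]
        if missing:
            raise ValueError(f"features absent from matrix: {missing}")
        return tuple(lut[s] for s in selected)
    return tuple(int(s) for s in selected)


def _binary_rates(tp: int, fp: int, tn: int, fn: int) -> tuple[dict, list[str]]:
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    rates = {
        "SEN": ratio(tp, tp + fn, "SEN"),
        "SPE": ratio(tn, tn + fp, "SPE"),
        "PPV": ratio(tp, tp + fp, "PPV"),
        "NPV": ratio(tn, tn + fn, "NPV"),
    }
    return rates, undefined


def confusion_metrics(
    y_true,
    y_pred,
    positive_class: str | None = None,
    classes: tuple[str, ...] | None = None,
    AUC: float | None = None,
    n_features: int | None = None,
    learning_time: float | None = None,
) -> ConfusionMetrics:
    """Accuracy plus SEN/SPE/PPV/NPV from the confusion table.

    Binary tasks use the stated positive class. Multi-class tasks report the
    unweighted macro average of the one-vs-rest rates together with the
    overall accuracy. Zero-denominator rates are 0 and flagged.
    """
    y_true = np.array([str(v) for v in y_true])
    y_pred = np.array([str(v) for v in y_pred])
    if len(y_true) != len(y_pred):
        raise ValueError("true and predicted label vectors differ in length")
    if classes is None:
        classes = tuple(dict.fromkeys(y_true.tolist()))
    stray = set(y_pred) - set(classes)
    if stray or set(y_true) - set(classes):
        raise ValueError(f"labels outside the class set: {sorted(stray | (set(y_true) - set(classes)))}")
    acc = float((y_true == y_pred).mean())

    if positive_class is not None or len(classes) == 2:
        pos = positive_class if positive_class is not None else classes[0]
        tp = int(np.sum((y_true == pos) & (y_pred == pos)))
        fn = int(np.sum((y_true == pos) & (y_pred != pos)))
        fp = int(np.sum((y_true != pos) & (y_pred == pos)))
        tn = int(np.sum((y_true != pos) & (y_pred != pos)))
        rates, undefined = _binary_rates(tp, fp, tn, fn)
    else:
        per_class = []
        undefined = []
        for c in classes:
            tp = int(np.sum((y_true == c) & (y_pred == c)))
            fn = int(np.sum((y_true == c) & (y_pred != c)))
            fp = int(np.sum((y_true != c) & (y_pred == c)))
            tn = int(np.sum((y_true != c) & (y_pred != c)))
            r, u = _binary_rates(tp, fp, tn, fn)
            per_class.append(r)
            undefined.extend(f"{name}[{c}]" for name in u)
        rates = {
            name: float(np.mean([r[name] for r in per_class]))
            for name in ("SEN", "SPE", "PPV", "NPV")
        }
    return ConfusionMetrics(
        ACC=acc,
        **rates,
        AUC=AUC,
        n_features=n_features,
        learning_time=learning_time,
        undefined_rates=tuple(undefined),
    )


def auc_binary(y_true, scores, positive_class: str) -> float:
    """Rank-based AUC: probability a positive outranks a negative (ties 1/2).

    Equivalent to the Mann-Whitney U statistic normalised by the number of
    positive-negative pairs.
    """
    y_true = np.array([str(v) for v in y_true])
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def select_best_model(cv_folds, task: str) -> int:
    """Index of the best CV fold.

    Primary key: AUC for binary tasks, accuracy for multi-class; maximised.
    Ties go to the fold with fewest selected features, then lowest index.
    """
    folds = list(cv_folds)
    if not folds:
        raise ValueError("no folds to choose from")
    if task not in ("binary", "multiclass"):
        raise ValueError(f"unknown task {task!r}")

    def key(i: int):
        rec = folds[i]
        metrics = rec.metrics if isinstance(rec, FoldRecord) else rec
        primary = metrics.AUC if task == "binary" else metrics.ACC
        if primary is None:
            raise ValueError("binary best-model rule needs AUC on every fold")
        nfeat = metrics.n_features
        if nfeat is None and isinstance(rec, FoldRecord):
            nfeat = len(rec.selected_features)
        return (-primary, nfeat if nfeat is not None else 0, i)

    return min(range(len(folds)), key=key)


def scale_metrics_for_radar(rows: list[dict]) -> tuple[list[tuple[float, ...]], tuple[str, ...]]:
    """Turn metric records (one per compared run) into radar radii in [0, 1].

    Rate metrics pass through unchanged; ``Time`` and ``Nfeats`` are min-max
    scaled across the runs and inverted so 1 means fastest/fewest. A column
    that is constant across runs maps to 1.
    """
    if not rows:
        raise ValueError("no metric records given")
    axes = tuple(
        name
        for name in RADAR_METRIC_ORDER
        if all(row.get(name) is not None for row in rows)
    )
    out = []
    scaled: dict[str, list[float]] = {}
    for name in _INVERTED_AXES:
        if name not in axes:
            continue
        vals = np.array([float(row[name]) for row in rows])
        span = vals.max() - vals.min()
        if span == 0:
            scaled[name] = [1.0] * len(rows)
        else:
            scaled[name] = (1.0 - (vals - vals.min()) / span).tolist()
    for i, row in enumerate(rows):
        radii = tuple(
            scaled[name][i] if name in scaled else float(row[name]) for name in axes
        )
        out.append(radii)
    return out, axes


def radar_area(radii) -> RadarScore:
    """Polygon area spanned by the radii, as a share of the maximal area.

    With n radii at equal angles gamma = 2*pi/n, the covered area is the sum
    over consecutive (cyclic) pairs of triangle areas r_i * r_{i+1} * sin(gamma)/2;
    the maximum (all radii 1) is n*sin(gamma)/2.
    """
    r = np.asarray(radii, dtype=float)
    n = r.size
    if n < 3:
        raise ValueError("radar area needs at least 3 radii")
    if np.any(r < 0):
        raise ValueError("radii must be non-negative")
    gamma = 2.0 * np.pi / n
    a_cov = float(0.5 * np.sin(gamma) * np.sum(r * np.roll(r, -1)))
    a_max = float(n / 2.0 * np.sin(gamma))
    return RadarScore(
        radii=tuple(r.tolist()),
        gamma=gamma,
        A_cov=a_cov,
        A_max=a_max,
        A_percent=100.0 * a_cov / a_max,
    )


def robustness(cv: CVResult | None = None, *, train_acc=None, val_acc=None) -> RobustnessResult:
    """Mean train-minus-validation accuracy gap with a 95% Student-t CI.

    The CI uses folds-1 degrees of freedom on the per-fold differences; a
    zero-variance difference vector yields a zero-width interval.
    """
    if cv is not None:
        train_acc = [f.train_accuracy for f in cv.folds]
        val_acc = [f.metrics.ACC for f in cv.folds]
    train_acc = np.asarray(train_acc, dtype=float)
    val_acc = np.asarray(val_acc, dtype=float)
    if train_acc.shape != val_acc.shape:
        raise ValueError("train and validation accuracy vectors differ in length")
    if train_acc.size < 2:
        raise ValueError("robustness CI needs at least 2 folds")
    diff = train_acc - val_acc
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    half = float(stats.t.ppf(0.975, diff.size - 1) * sd / np.sqrt(diff.size))
    return RobustnessResult(
        delta_mean=mean, ci95=(mean - half, mean + half), per_fold_delta=tuple(diff)
    )


def pearson_trend(x, y) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with >=3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance series has no defined correlation")
    return float(stats.pearsonr(x, y).statistic)


def _task_of(labels: ClassLabels) -> str:
    return "binary" if len(labels.classes) == 2 else "multiclass"


def cross_validate_selection(
    matrix: FeatureMatrix,
    labels: ClassLabels,
    ga_config: GAConfig,
    folds: int = 5,
    cv_seed: int = 0,
    classifier_seed: int = 0,
    n_estimators: int = 300,
) -> CVResult:
    """Stratified k-fold CV with GA feature selection inside every fold.

    Each training split runs the chromosome-length sweep, keeps the
    highest-fitness chromosome (ties to the shorter one), fits a random
    forest on it, and is scored on the validation split. Returns per-fold
    records and the best-model index under the AUC/accuracy rule.
    """
    task = _task_of(labels)
    pos = labels.positive_class or (labels.classes[0] if task == "binary" else None)
    records = []
    for tr, va in stratified_kfold(labels, folds=folds, seed=cv_seed):
        t0 = time.perf_counter()
        train_m, train_y = matrix.take_samples(tr), labels.take(tr)
        sweep = run_length_sweep(train_m, train_y, ga_config)
        # highest fitness wins; ties go to the shorter chromosome
        best_l = max(sorted(sweep), key=lambda l: (max(sweep[l][1].best_fitness), -l))
        chrom, trace = sweep[best_l]
        elapsed = time.perf_counter() - t0

        val_m, val_y = matrix.take_samples(va), labels.take(va)
        pred, proba = train_classifier_and_predict(
            train_m, train_y, val_m, chrom.genes, seed=classifier_seed,
            n_estimators=n_estimators,
        )
        auc = None
        if task == "binary":
            pos_col = list(train_y.classes).index(pos)
            auc = auc_binary(val_y.labels, proba[:, pos_col], pos)
        metrics = confusion_metrics(
            val_y.labels, pred,
            positive_class=pos, classes=labels.classes,
            AUC=auc, n_features=len(chrom), learning_time=elapsed,
        )
        train_pred, _ = train_classifier_and_predict(
            train_m, train_y, train_m, chrom.genes, seed=classifier_seed,
            n_estimators=n_estimators,
        )
        train_acc = float(np.mean(np.array(train_pred) == np.array(train_y.labels)))
        records.append(
            FoldRecord(
                metrics=metrics,
                selected_features=tuple(matrix.feature_ids[g - 1] for g in chrom.genes),
                genes=chrom.genes,
                train_accuracy=train_acc,
                fitness=max(trace.best_fitness),
            )
        )
    best = select_best_model(records, task)
    return CVResult(folds=tuple(records), task=task, best_index=best)


def evaluate_on_test(
    learn_matrix: FeatureMatrix,
    learn_labels: ClassLabels,
    test_matrix: FeatureMatrix,
    test_labels: ClassLabels,
    selected_features,
    classifier_seed: int = 0,
    n_estimators: int = 300,
) -> ConfusionMetrics:
    """Refit on the whole learning set and score once on the held-out set."""
    task = _task_of(learn_labels)
    pos = learn_labels.positive_class or (
        learn_labels.classes[0] if task == "binary" else None
    )
    pred, proba = train_classifier_and_predict(
        learn_matrix, learn_labels, test_matrix, selected_features,
        seed=classifier_seed, n_estimators=n_estimators,
    )
    auc = None
    if task == "binary":
        pos_col = list(learn_labels.classes).index(pos)
        auc = auc_binary(test_labels.labels, proba[:, pos_col], pos)
    genes = _resolve_features(learn_matrix, selected_features)
    return confusion_metrics(
        test_labels.labels, pred,
        positive_class=pos, classes=learn_labels.classes,
        AUC=auc, n_features=len(genes),
    )
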