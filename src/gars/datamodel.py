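"""Feature-matrix and class-label containers, delimited-text I/O, and preprocessing.

The containers are deliberately thin wrappers around a numpy array plus
identifier lists: every downstream step (fitness scoring, the GA, the
evaluation harness) consumes the samples-by-features orientation produced
here, so orientation is resolved once at load time and never guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "ClassLabels",
    "SplitSpec",
    "read_matrix",
    "read_labels",
    "write_matrix",
    "low_count_filter",
    "log_transform",
    "split_learning_test",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """A samples x features numeric matrix with unique row/column identifiers.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float array; must be finite.
    sample_ids, feature_ids
        Unique string identifiers aligned to rows and columns of ``values``.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        n, m = values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.feature_ids) != m:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.feature_ids)) != m:
            raise ValueError("feature_ids are not unique")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def take_samples(self, indices: np.ndarray) -> "FeatureMatrix":
        """Row subset preserving the given order (0-based indices)."""
        indices = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            self.values[indices],
            tuple(self.sample_ids[i] for i in indices),
            self.feature_ids,
        )


@dataclass(frozen=True)
class ClassLabels:
    """Per-sample class assignments for a supervised selection task.

    ``classes`` is the ordered set of distinct class names (first-appearance
    order unless given explicitly); a binary task may name a
    ``positive_class`` used by the confusion metrics.
    """

    labels: tuple[str, ...]
    classes: tuple[str, ...] = ()
    positive_class: str | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if not self.classes:
            seen: dict[str, None] = {}
            for lab in labels:
                seen.setdefault(lab, None)
            object.__setattr__(self, "classes", tuple(seen))
        else:
            object.__setattr__(self, "classes", tuple(str(c) for c in self.classes))
        if len(self.classes) < 2:
            raise ValueError(f"need >=2 classes, got {list(self.classes)}")
        unknown = set(labels) - set(self.classes)
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")
        counts = self.class_counts()
        empty = [c for c, k in counts.items() if k == 0]
        if empty:
            raise ValueError(f"classes with no samples: {empty}")
        if self.positive_class is not None and self.positive_class not in self.classes:
            raise ValueError(f"positive_class {self.positive_class!r} not among classes")

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        return {c: sum(1 for lab in self.labels if lab == c) for c in self.classes}

    def codes(self) -> np.ndarray:
        """Integer codes aligned to ``classes`` order."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[lab] for lab in self.labels], dtype=int)

    def take(self, indices: np.ndarray) -> "ClassLabels":
        labels = tuple(self.labels[i] for i in np.asarray(indices, dtype=int))
        present = tuple(c for c in self.classes if c in labels)
        pos = self.positive_class if self.positive_class in present else None
        return ClassLabels(labels, present, pos)


@dataclass(frozen=True)
class SplitSpec:
    """Exact per-class learning-set sizes for the learning/test partition."""

    per_class_learning_count: dict[str, int] = field(default_factory=dict)
    seed: int = 0


def read_matrix(
    path,
    orientation: str = "samples-in-rows",
    delimiter: str = "\t",
) -> FeatureMatrix:
    """Read a delimited numeric table (header row + first-column ids).

    ``orientation`` states what the *file* rows are; the returned matrix is
    always samples x features. Non-numeric cells and duplicate identifiers
    are rejected with the offending row/column named.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column ids in {path}: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        i, j = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} "
            f"in {path}: {df.iat[i, j]!r}"
        )
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().values)[0]
        raise ValueError(
            f"missing value at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    if orientation == "features-in-rows":
        numeric = numeric.T
    return FeatureMatrix(
        numeric.values.astype(float),
        tuple(map(str, numeric.index)),
        tuple(map(str, numeric.columns)),
    )


def write_matrix(matrix: FeatureMatrix, path, delimiter: str = "\t") -> None:
    """Write samples-in-rows delimited text (full float precision)."""
    df = matrix.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_labels(
    path,
    matrix: FeatureMatrix,
    delimiter: str = "\t",
    positive_class: str | None = None,
) -> ClassLabels:
    """Read class labels and align them to the matrix sample order.

    Accepts a two-column table (sample_id, class) in any row order, or a
    single-column file giving one label per matrix row in matrix order.
    Every matrix sample must be labelled and every labelled sample known.
    """
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    df = df.dropna(how="all")
    if df.shape[1] == 1:
        if len(df) != matrix.n_samples:
            raise ValueError(
                f"label file {path} has {len(df)} rows for {matrix.n_samples} samples"
            )
        labels = tuple(df.iloc[:, 0].astype(str))
    elif df.shape[1] == 2:
        mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        unknown = set(mapping) - set(matrix.sample_ids)
        if unknown:
            raise ValueError(f"label file {path} names unknown samples: {sorted(unknown)}")
        missing = [s for s in matrix.sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"samples without a label in {path}: {missing}")
        labels = tuple(mapping[s] for s in matrix.sample_ids)
    else:
        raise ValueError(f"label file {path} must have 1 or 2 columns, got {df.shape[1]}")
    return ClassLabels(labels, positive_class=positive_class)


def low_count_filter(
    matrix: FeatureMatrix,
    min_count: float = 10,
    max_low_fraction: float = 0.5,
) -> FeatureMatrix:
    """Drop count features that are low in too many samples.

    A feature is kept iff the fraction of samples with count < ``min_count``
    is <= ``max_low_fraction`` (defaults: fewer than 10 counts in more than
    50% of samples means the feature is discarded). Samples are unchanged.
    """
    if np.any(matrix.values < 0):
        raise ValueError("low_count_filter expects non-negative counts")
    low_frac = (matrix.values < min_count).mean(axis=0)
    keep = np.flatnonzero(low_frac <= max_low_fraction)
    return FeatureMatrix(
        matrix.values[:, keep],
        matrix.sample_ids,
        tuple(matrix.feature_ids[j] for j in keep),
    )


def log_transform(matrix: FeatureMatrix, pseudocount: float = 1.0) -> FeatureMatrix:
    """Elementwise ``log2(x + pseudocount)`` variance-flattening transform."""
    if np.any(matrix.values < 0):
        raise ValueError("log_transform expects non-negative values")
    return FeatureMatrix(
        np.log2(matrix.values + pseudocount), matrix.sample_ids, matrix.feature_ids
    )


def split_learning_test(
    matrix: FeatureMatrix,
    labels: ClassLabels,
    spec: SplitSpec,
) -> tuple[tuple[FeatureMatrix, ClassLabels], tuple[FeatureMatrix, ClassLabels]]:
    """Partition samples into a learning set and an independent test set.

    Exactly ``spec.per_class_learning_count[c]`` samples of each class are
    drawn without replacement (seeded) into the learning set; the complement
    becomes the test set. Returns ``((learn_matrix, learn_labels),
    (test_matrix, test_labels))``.
    """
    counts = labels.class_counts()
    for c, want in spec.per_class_learning_count.items():
        if c not in counts:
            raise ValueError(f"split requests unknown class {c!r}")
        if want < 1 or want > counts[c]:
            raise ValueError(
                f"requested {want} learning samples for class {c!r} of size {counts[c]}"
            )
    missing = set(counts) - set(spec.per_class_learning_count)
    if missing:
        raise ValueError(f"no learning count given for classes: {sorted(missing)}")

    rng = np.random.default_rng(spec.seed)
    learn_idx: list[int] = []
    for c in labels.classes:
        members = np.flatnonzero(np.array(labels.labels) == c)
        chosen = rng.choice(members, size=spec.per_class_learning_count[c], replace=False)
        learn_idx.extend(sorted(chosen.tolist()))
    learn_idx = sorted(learn_idx)
    test_idx = sorted(set(range(matrix.n_samples)) - set(learn_idx))
    if not test_idx:
        warnings.warn("learning set uses every sample; independent test set is empty")
        empty = FeatureMatrix(
            np.empty((0, matrix.n_features)), (), matrix.feature_ids
        )
        return (matrix.take_samples(np.array(learn_idx)), labels), (empty, None)
    learn = (matrix.take_samples(np.array(learn_idx)), labels.take(np.array(learn_idx)))
    test = (matrix.take_samples(np.array(test_idx)), labels.take(np.array(test_idx)))
    return learn, test
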