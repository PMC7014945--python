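"""Chromosome fitness: distances -> classical MDS -> clipped average silhouette.

A chromosome (a set of feature indices) is scored by how well the class
labels cluster when the samples, restricted to those features, are embedded
in two dimensions by classical (Torgerson) multidimensional scaling. The
score is the average silhouette index of the labelling in that plane,

    aSI = (1/n) * sum_i (b(i) - a(i)) / max{a(i), b(i)},

clipped below at zero, so fitness lives in [0, 1]: 1 means every class
collapses to its own well-separated point, 0 means the labelling carries no
geometric structure (or is anti-clustered).

The silhouette is deliberately computed on the 2-D embedding rather than on
the raw feature-space distances: the embedding discards axes of variation
that do not dominate the pairwise distance structure, which is what makes
the score cheap and stable in very high dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .datamodel import ClassLabels, FeatureMatrix

__all__ = [
    "DistanceMatrix",
    "MDSCoordinates",
    "SilhouetteReport",
    "subset_columns",
    "pairwise_distances",
    "classical_mds",
    "average_silhouette",
    "fitness",
    "FitnessEvaluator",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric n x n dissimilarity matrix with zero diagonal."""

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"distance matrix must be square, got {d.shape}")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(d < 0):
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class MDSCoordinates:
    """Sample coordinates on the first `dims` principal axes plus eigenvalues."""

    coords: np.ndarray
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class SilhouetteReport:
    """Per-sample silhouette decomposition and its average (aSI)."""

    s: np.ndarray
    a: np.ndarray
    b: np.ndarray
    aSI: float


def subset_columns(matrix: FeatureMatrix, chromosome) -> FeatureMatrix:
    """Restrict the matrix to the chromosome's features (1-based indices),
    preserving sample order and the chromosome's gene order."""
    genes = np.asarray(
        getattr(chromosome, "genes", chromosome), dtype=int
    )
    if genes.size == 0:
        raise ValueError("chromosome is empty")
    if np.any(genes < 1) or np.any(genes > matrix.n_features):
        bad = genes[(genes < 1) | (genes > matrix.n_features)][0]
        raise ValueError(
            f"feature index {bad} outside 1..{matrix.n_features}"
        )
    cols = genes - 1
    return FeatureMatrix(
        matrix.values[:, cols],
        matrix.sample_ids,
        tuple(matrix.feature_ids[j] for j in cols),
    )


def pairwise_distances(matrix: FeatureMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """Sample-by-sample distances on the (already subset) feature columns."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    return DistanceMatrix(squareform(pdist(matrix.values, metric=metric)))


def classical_mds(D: DistanceMatrix, dims: int = 2) -> MDSCoordinates:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centres -D^2/2, takes the top ``dims`` eigenpairs, and scales each
    eigenvector by the square root of its eigenvalue. Axes with non-positive
    eigenvalues are zero columns, so the output always has ``dims`` columns.
    Eigenvector signs are arbitrary; every consumer here is sign-invariant.
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 samples for MDS")
    sq = D.d**2
    # B = -1/2 J D^2 J  with J = I - 11'/n, written without forming J
    row_mean = sq.mean(axis=1, keepdims=True)
    B = -0.5 * (sq - row_mean - row_mean.T + sq.mean())
    k = min(dims, n)
    vals, vecs = eigh(B, subset_by_index=(n - k, n - 1))
    vals, vecs = vals[::-1], vecs[:, ::-1]  # descending
    # rank-deficiency noise: eigenvalues tiny relative to the spread are zero
    tol = 1e-9 * max(np.abs(vals).max(), sq.max(), 1e-300)
    coords = np.zeros((n, dims))
    for j in range(k):
        if vals[j] > tol:
            coords[:, j] = vecs[:, j] * np.sqrt(vals[j])
    eigenvalues = np.zeros(dims)
    eigenvalues[:k] = vals
    return MDSCoordinates(coords, eigenvalues)


def _silhouette_from_coords(coords: np.ndarray, codes: np.ndarray, n_classes: int):
    """Vectorised per-sample silhouette on embedded coordinates.

    Conventions for degenerate cases: s(i) = 0 when max{a(i), b(i)} = 0
    (all relevant distances vanish) and s(i) = 0 for singleton-class members
    (a(i) undefined), so the average always exists.
    """
    n = coords.shape[0]
    d = squareform(pdist(coords))
    sums = np.zeros((n, n_classes))
    counts = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        mask = codes == c
        counts[c] = mask.sum()
        sums[:, c] = d[:, mask].sum(axis=1)
    own = counts[codes]
    a = np.zeros(n)
    multi = own > 1
    a[multi] = sums[np.arange(n), codes][multi] / (own[multi] - 1)

    mean_other = sums / np.maximum(counts, 1)[None, :]
    mean_other[:, counts == 0] = np.inf
    mean_other[np.arange(n), codes] = np.inf
    b = mean_other.min(axis=1)

    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = (denom > 0) & multi
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return s, a, b


def average_silhouette(coords: MDSCoordinates, labels: ClassLabels) -> SilhouetteReport:
    """Average silhouette index of the class labelling in the embedding."""
    if len(labels.classes) < 2:
        raise ValueError("silhouette needs at least 2 classes")
    codes = labels.codes()
    xy = np.asarray(coords.coords, dtype=float)
    if xy.shape[0] != len(labels):
        raise ValueError(
            f"{xy.shape[0]} embedded samples but {len(labels)} labels"
        )
    s, a, b = _silhouette_from_coords(xy, codes, len(labels.classes))
    return SilhouetteReport(s=s, a=a, b=b, aSI=float(s.mean()))


def fitness(
    chromosome,
    matrix: FeatureMatrix,
    labels: ClassLabels,
    dims: int = 2,
    metric: str = "euclidean",
) -> float:
    """Clipped average silhouette of the chromosome's feature subset.

    Composition: subset columns -> pairwise distances -> 2-D classical MDS
    -> average silhouette -> clip negatives to 0. Returns a float in [0, 1].
    """
    sub = subset_columns(matrix, chromosome)
    D = pairwise_distances(sub, metric=metric)
    coords = classical_mds(D, dims=dims)
    report = average_silhouette(coords, labels)
    return max(report.aSI, 0.0)


class FitnessEvaluator:
    """Memoising fitness evaluator for one GA run.

    Fitness is invariant to gene order, so results are cached by the sorted
    gene tuple; a GA run re-evaluates each distinct subset once.
    """

    def __init__(
        self,
        matrix: FeatureMatrix,
        labels: ClassLabels,
        dims: int = 2,
        metric: str = "euclidean",
    ) -> None:
        self._values = matrix.values
        self._codes = labels.codes()
        self._n_classes = len(labels.classes)
        if self._n_classes < 2:
            raise ValueError("fitness needs at least 2 classes")
        if len(labels) != matrix.n_samples:
            raise ValueError("labels and matrix disagree on sample count")
        self._m = matrix.n_features
        self._dims = dims
        self._metric = metric
        self._cache: dict[tuple[int, ...], float] = {}
        self.n_evaluations = 0

    def __call__(self, genes) -> float:
        genes = np.asarray(getattr(genes, "genes", genes), dtype=int)
        key = tuple(sorted(genes.tolist()))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if np.any(genes < 1) or np.any(genes > self._m):
            raise ValueError(f"gene index outside 1..{self._m}")
        sub = self._values[:, genes - 1]
        D = DistanceMatrix(squareform(pdist(sub, metric=self._metric)))
        coords = classical_mds(D, dims=self._dims)
        s, _, _ = _silhouette_from_coords(coords.coords, self._codes, self._n_classes)
        value = max(float(s.mean()), 0.0)
        self._cache[key] = value
        self.n_evaluations += 1
        return value
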