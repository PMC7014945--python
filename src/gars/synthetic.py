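"""Labelled synthetic feature matrices with known planted structure.

The generator emulates the three benchmark regimes the selector is aimed
at — a well-separated binary low-dimensional set, an overlapping unbalanced
binary mid-dimensional set, and subtle multi-class high-dimensional
expression data — using a Gaussian class-conditional model with equal
spherical covariance. A known subset of ``k_informative`` columns carries
class signal; all other columns are class-independent noise, so planted
ground truth is available for recovery experiments.

The effect size has per-column semantics: in a two-class design every
informative column separates the class means by ``effect_size * noise_sd``
(signs randomised per column). With more classes the informative columns
are partitioned into marker blocks, one per class, and each column shifts
its own class by ``effect_size * noise_sd`` — mutually orthogonal mean
directions, so every class pair is separated (a simplex-like arrangement),
and every informative column is a full-strength marker of exactly one class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .datamodel import ClassLabels, FeatureMatrix

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "preset"]

#: Brain-region sample sizes used to shape the multi-class regime.
_MULTI_CLASS_SIZES = (72, 84, 117, 114, 108, 94, 96, 113, 97, 71, 63)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the class-conditional Gaussian generator.

    ``effect_size`` is the per-informative-column between-class mean shift
    in units of ``noise_sd``; 0 gives a null dataset with no class signal. Unbalanced
    designs set ``class_sizes`` explicitly (overrides ``n_per_class``).
    ``counts_mode`` exponentiates and rounds the values (2**(x + log2_offset))
    to emulate raw sequencing counts for the low-count-filter path.
    """

    n_per_class: int = 30
    n_classes: int = 2
    m_total: int = 100
    k_informative: int = 5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0
    class_sizes: tuple[int, ...] | None = None
    counts_mode: bool = False
    log2_offset: float = 5.0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need >=2 classes")
        if self.k_informative > self.m_total:
            raise ValueError(
                f"k_informative {self.k_informative} exceeds m_total {self.m_total}"
            )
        if self.k_informative < 1:
            raise ValueError("need >=1 informative feature")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >=0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be >0")
        sizes = self.sizes()
        if len(sizes) != self.n_classes:
            raise ValueError(
                f"{len(sizes)} class_sizes for {self.n_classes} classes"
            )
        if any(s < 2 for s in sizes):
            raise ValueError("every class needs >=2 samples")
        if self.n_classes > 2 and self.k_informative < self.n_classes:
            raise ValueError(
                "marker-block placement needs k_informative >= n_classes"
            )

    def sizes(self) -> tuple[int, ...]:
        if self.class_sizes is not None:
            return tuple(int(s) for s in self.class_sizes)
        return (self.n_per_class,) * self.n_classes


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset: which columns carry signal."""

    planted_indices: tuple[int, ...]  # 1-based feature indices
    class_means: np.ndarray  # n_classes x k_informative

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_indices": list(self.planted_indices),
                "class_means": np.asarray(self.class_means).tolist(),
            },
            indent=2,
        )


def _class_means(n_classes: int, k: int, shift: float, rng) -> np.ndarray:
    """Class means in the informative subspace, per-column shift ``shift``.

    Two classes sit at -shift/2 and +shift/2 in every column, with a random
    sign per column. More classes get disjoint marker blocks (columns dealt
    round-robin): column j of class c's block shifts class c by ``shift`` and
    leaves the others at 0, so the mean directions are mutually orthogonal.
    """
    if shift == 0:
        return np.zeros((n_classes, k))
    if n_classes == 2:
        signs = rng.choice((-1.0, 1.0), size=k)
        return np.vstack([-signs * shift / 2.0, signs * shift / 2.0])
    means = np.zeros((n_classes, k))
    owner = np.arange(k) % n_classes  # round-robin block assignment
    means[owner, np.arange(k)] = shift
    return means


def generate(spec: SyntheticSpec) -> tuple[FeatureMatrix, ClassLabels, SyntheticTruth]:
    """Draw one seeded dataset from the spec's class-conditional model."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.sizes()
    n = sum(sizes)

    planted = np.sort(rng.choice(spec.m_total, size=spec.k_informative, replace=False)) + 1
    means = _class_means(
        spec.n_classes, spec.k_informative, spec.effect_size * spec.noise_sd, rng
    )

    values = rng.standard_normal((n, spec.m_total)) * spec.noise_sd
    class_names = tuple(f"C{c + 1}" for c in range(spec.n_classes))
    labels: list[str] = []
    row = 0
    for c, size in enumerate(sizes):
        values[row : row + size, planted - 1] += means[c]
        labels.extend([class_names[c]] * size)
        row += size

    if spec.counts_mode:
        values = np.rint(np.maximum(2.0 ** (values + spec.log2_offset), 0.0))

    matrix = FeatureMatrix(
        values,
        tuple(f"S{i + 1}" for i in range(n)),
        tuple(f"F{j + 1}" for j in range(spec.m_total)),
    )
    class_labels = ClassLabels(
        tuple(labels),
        classes=class_names,
        positive_class=class_names[-1] if spec.n_classes == 2 else None,
    )
    truth = SyntheticTruth(tuple(int(g) for g in planted), means)
    return matrix, class_labels, truth


def preset(regime: str, n_classes: int | None = None, seed: int = 0) -> SyntheticSpec:
    """Named specs for the three benchmark regimes.

    - ``binary_low``: 2 x 29 samples, 168 features, 10 informative, strong
      separation (well-separated clusters).
    - ``binary_mid``: unbalanced 26 vs 72 samples, 701 features, 8
      informative, weak separation (overlapping clusters).
    - ``multi_high``: 3-11 classes with realistic uneven sizes, 19162
      features, 25 informative, weak separation.
    """
    if regime == "binary_low":
        return SyntheticSpec(
            n_per_class=29, n_classes=2, m_total=168, k_informative=10,
            effect_size=6.0, noise_sd=1.0, seed=seed,
        )
    if regime == "binary_mid":
        return SyntheticSpec(
            n_classes=2, class_sizes=(72, 26), m_total=701, k_informative=8,
            effect_size=1.5, noise_sd=1.0, seed=seed,
        )
    if regime == "multi_high":
        k = 11 if n_classes is None else int(n_classes)
        if not 3 <= k <= 11:
            raise ValueError("multi_high supports 3..11 classes")
        return SyntheticSpec(
            n_classes=k, class_sizes=_MULTI_CLASS_SIZES[:k], m_total=19162,
            k_informative=25, effect_size=1.5, noise_sd=1.0, seed=seed,
        )
    raise ValueError(f"unknown regime {regime!r}")
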