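import numpy as np
import pytest

from gars.datamodel import ClassLabels, FeatureMatrix
from gars.synthetic import SyntheticSpec, generate


@pytest.fixture
def two_cluster_matrix():
    """4 samples in 2 features: class A at x=0, class B at x=4, unit y spread."""
    X = FeatureMatrix(
        np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [4.0, 1.0]]),
        ("s1", "s2", "s3", "s4"),
        ("f1", "f2"),
    )
    y = ClassLabels(("A", "A", "B", "B"))
    return X, y


@pytest.fixture
def collapsed_classes():
    """Each class is a single repeated point: maximal discrimination."""
    X = FeatureMatrix(
        np.array([[0.0] * 5] * 3 + [[3.0] * 5] * 3),
        tuple(f"s{i}" for i in range(6)),
        tuple(f"f{j}" for j in range(5)),
    )
    y = ClassLabels(("A",) * 3 + ("B",) * 3)
    return X, y


@pytest.fixture
def anti_clustered():
    """Two tight far-apart clusters whose labels are split across clusters."""
    rng = np.random.default_rng(11)
    pts = np.vstack(
        [rng.normal(0.0, 0.01, (5, 3)), rng.normal(100.0, 0.01, (5, 3))]
    )
    X = FeatureMatrix(
        pts, tuple(f"s{i}" for i in range(10)), ("f1", "f2", "f3")
    )
    # half of each spatial cluster labelled A, half B
    y = ClassLabels(("A", "A", "A", "B", "B", "A", "A", "B", "B", "B"))
    return X, y


@pytest.fixture(scope="session")
def separated_dataset():
    """Small planted two-class dataset with clear separation (session cache)."""
    spec = SyntheticSpec(
        n_per_class=15, n_classes=2, m_total=40, k_informative=4,
        effect_size=4.0, seed=3,
    )
    return generate(spec)


def write_tsv(path, rows):
    path.write_text("\n".join("\t".join(str(v) for v in row) for row in rows) + "\n")
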