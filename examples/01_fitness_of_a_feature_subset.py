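"""Score candidate feature subsets with the silhouette fitness function.

Builds a tiny two-class dataset, then scores three chromosomes: the planted
informative features, a random noise subset, and a deliberately anti-grouped
labelling. The score is the average silhouette index of the class labels on
the 2-D classical-MDS embedding of the samples restricted to the subset,
clipped to [0, 1] — 1 means perfectly separated classes, 0 means no (or
inverted) class structure.
"""

import numpy as np

from gars import ClassLabels, FeatureMatrix, fitness
from gars.synthetic import SyntheticSpec, generate

spec = SyntheticSpec(
    n_per_class=20, n_classes=2, m_total=50, k_informative=4,
    effect_size=3.0, seed=7,
)
matrix, labels, truth = generate(spec)

planted = truth.planted_indices
noise = tuple(g for g in range(1, 51) if g not in planted)[:4]

print(f"planted subset {planted}: fitness = {fitness(planted, matrix, labels):.3f}")
print(f"noise subset   {noise}: fitness = {fitness(noise, matrix, labels):.3f}")

# anti-clustered labels: two tight clusters, labels split across them
rng = np.random.default_rng(0)
pts = np.vstack([rng.normal(0, 0.01, (4, 3)), rng.normal(50, 0.01, (4, 3))])
X = FeatureMatrix(pts, tuple(f"s{i}" for i in range(8)), ("a", "b", "c"))
y = ClassLabels(("A", "B", "A", "B", "A", "B", "A", "B"))
print(f"anti-clustered labelling: fitness = {fitness((1, 2, 3), X, y):.3f}")

print(
    "\nThe planted subset scores near its class separability, the noise subset"
    "\nnear 0, and the anti-clustered case clips a negative silhouette to 0."
)
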