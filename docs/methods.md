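# Methods

## Model

The selector treats feature selection as a combinatorial search over
fixed-size subsets of the *m* features of an *n* × *m* samples-by-features
matrix with known class labels (≥2 classes). A subset is represented as a
chromosome of *l* unique 1-based feature indices and scored by a geometric
class-separability criterion rather than by a classifier:

1. **Distances.** Euclidean distances between sample rows restricted to the
   subset. The metric is configurable but Euclidean is the tested contract;
   it is the conventional default both for classical scaling and for
   silhouettes.
2. **Embedding.** Classical (Torgerson) multidimensional scaling to 2
   dimensions: double-centre −½D², eigendecompose, scale the top two
   eigenvectors by the square roots of their eigenvalues. Axes with
   non-positive eigenvalues become zero columns so downstream code always
   sees two columns. Eigenvalues below 1e-9 relative to the spectrum and to
   the squared-distance scale are treated as zero: rank-deficient inputs
   (e.g. classes collapsed to single points) otherwise leak O(√ε) spurious
   coordinates from the eigensolver and the analytic maximum score of 1
   would be missed by ~1e-5. Eigenvector signs are left unresolved; the
   silhouette is invariant to them.
3. **Score.** The average silhouette index of the labelling on the 2-D
   coordinates, aSI = mean over samples of (b−a)/max(a,b), clipped below at
   0, giving a fitness in [0, 1]. Degenerate conventions: s(i)=0 when
   max(a,b)=0 and s(i)=0 for members of singleton classes, so the average
   always exists. Computing the silhouette on the embedding (not on the raw
   feature-space distances) follows the method's pipeline ordering and is
   what keeps the score cheap and stable at tens of thousands of features.

Fitness is order-invariant in the genes, so one GA run memoises scores by
the sorted gene tuple; typical runs evaluate ~3–5k distinct subsets for
10,000 nominal evaluations.

## Evolutionary engine

Defaults: population k=100, 100 generations, per-gene mutation probability
0.1, crossover rate 0.8, elitism 2, binary tournament selection, one-point
crossover. Roulette-wheel selection and two-point crossover are available.
Choices made where the protocol leaves room:

- **Mutation granularity.** "Mutation probability 0.1" is read per-gene
  (expected mutations proportional to l), the common GA convention; a
  per-chromosome mode is provided. Replacements are drawn uniformly from
  the indices absent from the chromosome at that moment, preserving
  uniqueness by construction.
- **Crossover repair.** One- and two-point crossover can duplicate genes;
  every duplicated occurrence after the first is replaced by a uniform draw
  from the absent indices. Parents are drawn independently by the selection
  operator; with probability 1 − crossover_rate the pair is cloned.
- **Tie-breaking.** Elitism resolves fitness ties by first-index order
  (stable sort); tournaments break ties uniformly at random under the run's
  seeded generator. Runs are bit-reproducible from the seed.
- **Length range.** Chromosomes are fixed-length; the requested range
  l_min..l_max is swept with one independent GA per length (seed = run seed
  + l, distinct and deterministic), and the evaluation layer picks among
  the winners (highest fitness, ties to the shorter subset). This
  reproduces range-of-lengths behaviour without variable-length genomes.
- **Stopping.** Fixed iteration count by default; an optional plateau
  window stops a run whose best fitness has not improved over that many
  generations.

## Evaluation harness

Stratified 5-fold CV (seeded scikit-learn folds; per-class counts per fold
differ by ≤1) runs the full length sweep inside every training split and
fits a random forest (300 trees, seeded) on the selected columns. Per-fold
validation metrics: overall accuracy; SEN/SPE/PPV/NPV from the confusion
table with respect to the stated positive class for binary tasks, or as
unweighted macro averages of the one-vs-rest tables for multi-class (the
averaging scheme is this package's choice; zero-denominator rates are
reported as 0 and flagged, so radar radii are always defined); rank-based
AUC (Mann-Whitney, ties ½) for binary tasks. Best model: highest AUC
(binary) or accuracy (multi-class), then fewest features, then lowest fold
index; it is refit on the whole learning set for the single independent-test
evaluation.

Robustness is Δ = mean over folds of (training accuracy − validation
accuracy) with a 95% Student-t interval on folds−1 degrees of freedom (the
interval construction is this package's choice).

The radar aggregate uses the fixed axis order ACC, SEN, SPE, PPV, NPV,
AUC, Time, Nfeats (area depends on adjacency). Rates pass through; time and
feature count are min–max scaled across the compared runs and inverted so 1
means fastest/fewest; a constant column maps to 1. With γ = 2π/n, the
covered area is Σ cyclic pairs ½·rᵢ·rᵢ₊₁·sin γ, the maximum is (n/2)·sin γ,
and the score is their percentage ratio.

## Synthetic data

The generator draws class-conditional Gaussians with equal spherical
covariance: `k_informative` planted columns carry class signal, all others
are N(0, noise_sd²) noise. `effect_size` has per-column semantics — in a
two-class design the class means in every informative column are
`effect_size·noise_sd` apart (random sign per column); with more classes
the informative columns are dealt round-robin into marker blocks, each
column shifting exactly one class by `effect_size·noise_sd`. The resulting
mean directions are mutually orthogonal, so all class pairs are separated
and every informative column is a full-strength marker of one class — the
structure of marker genes in expression panels. A random-direction simplex
was considered and rejected: it concentrates the same total separation
unevenly, leaving some planted columns with almost no signal, which
contradicts the generator's per-column contract and makes "planted truth"
ill-defined as a recovery target.

A counts mode (round(2^(x + offset))) produces non-negative integers so the
low-count filter path (drop features with fewer than `min_count` counts in
more than `max_low_fraction` of samples) can be exercised end to end. The
normalisation stand-in is log2(x+1); the selector itself is
transformation-agnostic and users may pre-transform with any
variance-stabilising method.

Three presets mirror the benchmark regimes the method targets: a
well-separated binary set (2×29 samples, 168 features, 10 informative,
effect 6), an overlapping unbalanced binary set (72 vs 26 samples, 701
features, 8 informative, effect 1.5), and a subtle multi-class set (3–11
classes with uneven sizes between 63 and 117, 19,162 features, 25
informative, effect 1.5). Preset effect sizes are fixed choices calibrated
to the qualitative descriptions "well separated" / "overlapping": planted
fitness is >0.8 in the first regime and substantially lower in the second.

What the generator does **not** emulate: negative-binomial count dispersion,
gene–gene correlation, batch effects, or heavy-tailed metabolite intensities.
Passing tests therefore demonstrate correctness of the algorithmics and
recoverability under the stated Gaussian conditions, not performance claims
on real sequencing data.

## Problem sizes in the test suite

Tests run the GA on deliberately small instances (tens of features,
populations of 10–20, a handful of generations) except for the planted
recovery experiment, which uses the full defaults (60×200, population 100,
100 generations, 5 seeds) as the method's reference recovery setting. The
suite completes in well under a minute on one CPU.

## Known limitations

- The 2-D embedding can under-represent class structure needing more than
  two geometric axes; dimensionality is configurable but only dims=2 is the
  tested contract.
- Fitness ≈ silhouette rewards compact, far-apart classes; elongated or
  multi-modal classes can be separable for a classifier yet score modestly.
- The GA is stochastic; different seeds can return different, equally fit
  subsets when features are redundant. The length sweep multiplies runtime
  by the number of candidate lengths.
- Macro averaging weights all classes equally regardless of size; with
  heavy imbalance PPV/NPV macro values can be dominated by small classes.
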