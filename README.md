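# gars-select

Genetic-algorithm feature selection for high-dimensional, multi-class omics
data, with a fitness function built from classical multidimensional scaling
and the average silhouette index.

## The problem

Omics experiments (RNA-seq, miRNA-seq, metabolomics) routinely measure
thousands to tens of thousands of features on a few dozen to a few hundred
samples. Building a classifier on all of them overfits; most filter methods
score features one at a time and miss interacting sets; classical wrapper
methods wrap a full classifier inside the search and become prohibitively
slow above ~15,000 features. This package implements a wrapper selector
whose inner score is *not* a classifier: a candidate feature subset is
scored by how well the known class labels cluster geometrically, which is
fast enough to search the full feature space directly.

## The method

A **chromosome** is a fixed-length vector of *l* unique integers, each the
index (1..*m*) of a feature. Its **fitness** is computed by:

1. restricting the data matrix to the chromosome's features,
2. computing Euclidean distances between samples,
3. embedding the samples in 2-D by classical (Torgerson) MDS,
4. scoring the class labelling with the average silhouette index

   aSI = (1/n) Σᵢ (b(i) − a(i)) / max{a(i), b(i)},

   where a(i) is sample i's mean distance to its own class and b(i) the
   smallest mean distance to any other class,
5. clipping negatives: Fitness = max(aSI, 0) ∈ [0, 1].

A population of k = 100 chromosomes evolves for 100 generations with
elitism (2), tournament or roulette-wheel selection, one- or two-point
crossover with uniqueness repair, and index-replacement mutation (per-gene
probability 0.1, drawing replacements from indices absent from the
chromosome). The desired subset-size *range* is handled by one GA run per
length, the best length winning on fitness.

The evaluation harness reproduces the standard wrapper-benchmark protocol:
learning/independent-test split, stratified 5-fold CV with selection inside
each training fold, a random-forest classifier on the selected features,
ACC/SEN/SPE/PPV/NPV (+ rank-based AUC for binary tasks), best-model choice
by highest AUC (binary) or accuracy (multi-class) then fewest features, a
robustness gap Δ = mean(train ACC − validation ACC) with a 95% t-interval,
and a radar-polygon aggregate score A_% = 100·A_cov/A_max over the scaled
metric axes.

## Worked example

`examples/02_select_features_with_the_ga.py` plants 5 informative columns
among 200 (60 samples, two classes, per-column effect 3 SD) and runs the GA
at length 5:

```
data: 60 samples x 200 features
planted features: (7, 93, 101, 150, 190)
generations run: 100
distinct subsets evaluated: 3429
best fitness: 0.719
best chromosome: (7, 93, 101, 150, 190)
planted features recovered: 5/5
```

The winning chromosome is exactly the planted subset; its fitness (0.719)
is the clipped average silhouette of the two classes in the 2-D embedding —
well-separated but with overlapping noise, hence below the theoretical
maximum of 1. The other examples score individual subsets
(`01_fitness_of_a_feature_subset.py`), run the full CV harness with an
independent test set (`03_cross_validated_evaluation.py`), and compute
radar areas and class-count trend correlations (`04_radar_score_and_trends.py`).

## Command line

The same workflow is scriptable from a shell:

```sh
gars simulate --regime binary_low --seed 1 --out data/
gars select   --matrix data/matrix.tsv --labels data/labels.tsv \
              --l-min 5 --l-max 20 --seed 1 --out run/
gars evaluate --matrix data/matrix.tsv --labels data/labels.tsv \
              --l-min 5 --l-max 20 --folds 5 --seed 1 --out run/
gars report   run/reports/metrics.json --out run/radar.csv
```

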