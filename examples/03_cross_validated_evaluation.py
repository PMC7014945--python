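"""Evaluate the selector with the cross-validated random-forest harness.

Splits a synthetic dataset into a learning set and an independent test set,
runs stratified 5-fold CV on the learning set (GA selection inside every
training split, random forest scored on each validation split), picks the
best fold by the AUC-then-fewest-features rule, reports the robustness gap
(mean train-minus-validation accuracy with a 95% t-interval), and finally
scores the best fold's features once on the held-out test set.
"""

from gars import (
    GAConfig,
    SplitSpec,
    cross_validate_selection,
    evaluate_on_test,
    robustness,
    split_learning_test,
)
from gars.synthetic import SyntheticSpec, generate

spec = SyntheticSpec(
    n_per_class=29, n_classes=2, m_total=60, k_informative=4,
    effect_size=3.0, seed=2,
)
matrix, labels, _ = generate(spec)

(learn_m, learn_y), (test_m, test_y) = split_learning_test(
    matrix, labels, SplitSpec({"C1": 25, "C2": 25}, seed=2)
)
print(f"learning set {learn_m.n_samples} samples, test set {test_m.n_samples}")

config = GAConfig(l_min=3, l_max=4, k=30, iterations=15, seed=2)
cv = cross_validate_selection(learn_m, learn_y, config, folds=5, cv_seed=2)

for i, fold in enumerate(cv.folds):
    flag = " <- best" if i == cv.best_index else ""
    print(
        f"fold {i}: ACC={fold.metrics.ACC:.2f} AUC={fold.metrics.AUC:.2f} "
        f"nfeats={fold.metrics.n_features}{flag}"
    )

rob = robustness(cv)
print(f"robustness delta = {rob.delta_mean:.3f}, 95% CI {rob.ci95[0]:.3f}..{rob.ci95[1]:.3f}")

best = cv.folds[cv.best_index]
test_metrics = evaluate_on_test(learn_m, learn_y, test_m, test_y, list(best.selected_features))
print(
    f"independent test: ACC={test_metrics.ACC:.2f} SEN={test_metrics.SEN:.2f} "
    f"SPE={test_metrics.SPE:.2f} AUC={test_metrics.AUC:.2f}"
)
print("\nA small delta means the selected subset generalises: the classifier")
print("performs on unseen folds about as well as on its own training data.")
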