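"""OPLS-DA pattern analysis with permutation validation.

Fits the normal-vs-tumour model on the discovery cohort, then refits under
label permutations to estimate pQ2, the overfitting screen.
"""

import numpy as np

from metabopanel import (
    CohortSpec, ComparisonSpec, fit_oplsda, generate_study,
    permutation_test, preprocess_pipeline,
)

study = generate_study(CohortSpec(n_features=400, n_differential=30, seed=3))
processed, _ = preprocess_pipeline(study.table, study.meta)

comp = ComparisonSpec("normal", "benign+borderline+malignant", name="normal_vs_tumor")
ids_a, ids_b = comp.sample_ids(study.meta, cohort="discovery")
X = processed.intensities[ids_a.append(ids_b)].T.to_numpy()
y = np.r_[np.zeros(len(ids_a)), np.ones(len(ids_b))].astype(int)
keep = X.std(axis=0, ddof=1) > 0

model = fit_oplsda(X[:, keep], y, n_orthogonal=1, cv_folds=7, seed=1000)
perm = permutation_test(X[:, keep], y, n_orthogonal=1, folds=7,
                        n_permutations=199, seed=1000)

print(f"R2Y = {model.r2y:.3f}  (class variance explained on the training fit)")
print(f"Q2  = {model.q2:.3f}  (7-fold cross-validated predictive ability)")
print(f"pQ2 = {perm.p_q2:.4f}  ->  overfit: {perm.overfit}")
print(f"features with VIP > 1: {(model.vip > 1).sum()} of {keep.sum()}")
# R2Y and Q2 both above 0.5 with a small pQ2 indicate a real class
# difference; pQ2 >= 0.05 would mean permuted labels do as well and the
# model should not be trusted to nominate biomarkers.
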