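"""Cross-validated outcome prediction and the small-sample experiment.

Evaluates the selected biomarkers by stratified 10-fold random-forest
prediction (selection rerun inside every fold), then shows how accuracy
behaves when training is restricted to 10/20/30 samples per group.
"""

import g2vec as gv

data, _, edges, _ = gv.simulate_cohort(gv.SyntheticCohortConfig(seed=11))

cv = gv.cross_validate(data, edges, n_folds=10, seed=3)
print("per-fold AUC:", [round(a, 3) for a in cv.fold_aucs])
print(f"mean 10-fold AUC: {cv.mean_auc:.3f}")
# ~1.0: the planted effect (2x noise SD) makes the groups separable

for n in (10, 20, 30):
    out = gv.small_sample_experiment(data, edges, n_per_group=n,
                                     n_repeats=5, seed=7)
    print(f"{out['n_training_samples']} training samples: "
          f"mean AUC {out['mean_auc']:.3f}")
# accuracy stays high even at 20 training samples on this cohort
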