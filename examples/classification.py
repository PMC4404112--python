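"""Confirm cohort separability with leave-one-out cross-validation and a
label-permutation null.

Each held-out sample is predicted by a nearest-centroid classifier trained
on the rest; the misclassification rate is then compared to its distribution
under random label permutations (99 here), yielding the add-one-smoothed
Monte Carlo p-value.
"""

from traumadfr import (SimulationParams, loocv_misclassification,
                       monte_carlo_label_permutation, simulate_cohort)

params = SimulationParams(
    n_probes=100, n_controls=5, n_patients_per_cell=10,
    timepoints_days=(0.5,), dropout_hazard=0.0,
    amplitude={"young": {0.5: 4.0}, "aged": {0.5: 1.0}}, seed=19)
matrix, metadata, _ = simulate_cohort(params)
labels = {m.sample_id: m.age_group for m in metadata
          if m.age_group != "control"}

loo = loocv_misclassification(matrix, labels, control_group=None)
print(f"LOOCV: {loo.n_misclassified} of {loo.n_samples} samples misclassified "
      f"(rate {loo.misclassification_rate:.3f})")

null = monte_carlo_label_permutation(matrix, labels, n_perm=99, seed=19,
                                     control_group=None)
print(f"permutation null over {null.n_perm} label shuffles: "
      f"median permuted rate {float(sorted(null.permuted_rates)[49]):.2f}, "
      f"p = {null.p_value:.3f}")
print("\nA small p means the aged/young expression patterns separate far "
      "better than chance relabelings of the same profiles.")
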