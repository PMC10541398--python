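"""Fit the admixture model by EM and select K by cross-validation.

A cohort drawn from three ancestral populations: entry-masking CV over
K = 1..5 is minimized at the true K, and the fitted ancestry matrix Q
matches the generating one after resolving label switching.
"""

import numpy as np

from clonalpop import (GroupSpec, SimulationConfig, align_q, cross_validate,
                       em_fit, simulate_cohort)

cfg = SimulationConfig(
    n_sites=1500, K=3, drift=(0.2, 0.2, 0.2),
    group_specs=tuple(GroupSpec(f"P{k + 1}", 15, "outbred", population=k)
                      for k in range(3)),
    seed=2)
matrix, truth = simulate_cohort(cfg)

cv = cross_validate(matrix, [1, 2, 3, 4, 5], seed=2, n_folds=3)
print("cross-validation error per K:")
print(cv.errors.round(4).to_string(index=False))
print(f"selected K = {cv.selected_K} (the generating model used K = 3)")

fit = em_fit(matrix, cv.selected_K, n_starts=4, seed=2)
aligned, _ = align_q(fit.Q, truth.true_Q)
err = np.abs(aligned - truth.true_Q.to_numpy()).mean()
print(f"\nEM converged after {len(fit.loglik_trace)} iterations, "
      f"final log-likelihood {fit.final_loglik:.0f}")
print(f"mean |Q_hat - Q_true| after label alignment: {err:.4f}")

# The CV curve dips at the true K; the tiny Q error shows the EM fit
# recovers each sample's ancestry proportions almost exactly.
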