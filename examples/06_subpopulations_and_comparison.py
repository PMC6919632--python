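"""Gate a dominant subpopulation, then compare conditions two ways.

Real cytometry data mixes cell states; a Gaussian mixture in log-signal
space isolates the dominant component before covariance analysis.  Two
conditions are then compared by (i) the principal-angle metric
d = sqrt(sum of theta_i^2) between their ESS -- sensitive to changes in
reaction topology -- and (ii) the LDA-style Mahalanobis separation of
their dominant components -- sensitive to mean (equilibrium-constant)
shifts.
"""

import numpy as np

import esskit as ek

rng = np.random.default_rng(5)

# condition A: dominant cluster + 10% debris far away
logs_a = np.vstack([rng.normal([0, 0, 0], 1.0, (900, 3)), rng.normal([7, 7, 7], 1.0, (100, 3))])
# condition B: the same reaction structure (covariance) but shifted means
logs_b = logs_a[:900] + np.array([2.0, -1.0, 0.5])

cond_a = ek.EnsembleSnapshot(np.exp(logs_a), ["r", "g", "b"])
cond_b = ek.EnsembleSnapshot(np.exp(logs_b), ["r", "g", "b"])

k = ek.choose_k(cond_a, k_max=3, seed=0, n_init=3)
fit_a = ek.fit_gmm(cond_a, k, seed=0)
dom_a = ek.select_subpopulation(fit_a, cond_a)
print(f"condition A: chose k = {k}, dominant weight = {fit_a.weights[fit_a.dominant]:.2f}, "
      f"{dom_a.n_cells}/{cond_a.n_cells} cells kept")

fit_b = ek.fit_gmm(cond_b, 1, seed=0)
ess_a = ek.extract_ess(ek.fit_covariance_spectrum(dom_a), dimension=1)
ess_b = ek.extract_ess(ek.fit_covariance_spectrum(cond_b), dimension=1)

cmp_ = ek.compare_subspaces(ess_a.basis, ess_b.basis)
print(f"ESS angle metric d = {cmp_.metric_d:.4f} rad  (near 0: same covariance structure)")
print(f"LDA separation    = {ek.lda_separation(fit_a, fit_b):.2f}   (large: means shifted)")
print()
print("Dose-like perturbations shift means (large LDA separation) while")
print("leaving the ESS unchanged (d ~ 0); topology changes would tilt the ESS.")
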