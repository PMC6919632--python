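"""Is the integer structure of row-reduced entries more than chance?

Row-reduced ESS vectors from simulated reaction networks concentrate
their non-structural entries at small-integer ratios (-1, -1/2, ...).
The null model asks what entries would look like if the small eigenspace
were spanned by random sparse constraints instead: draw vectors uniform
on (-0.5, 0.5), sparsify, row-reduce, add noise calibrated to the data's
own near-zero window.  Percentile bootstrap CIs quantify the stability
of each recovered entry.
"""

import numpy as np

import esskit as ek

net = ek.toy_network("xyz_slow")
init = ek.sample_initial_conditions(net, 300, seed=9)
snapshot = ek.integrate_ensemble(net, init, [500.0]).final()

spectrum = ek.fit_covariance_spectrum(snapshot)
basis = ek.extract_ess(spectrum, dimension=2)
rrb = ek.row_reduce_complete_pivoting(basis)
dist = ek.entry_distribution([rrb])
print("row-reduced vectors:")
print(np.round(rrb.vectors, 4))
print("pooled non-structural entries:", np.round(dist.entries, 4))

cfg = ek.calibrate_null_from_data(dist.entries, s=2, dimension=3, n_sets=500, seed=10)
null = ek.null_entry_distribution(cfg)
print(f"calibrated null: sparsity = {cfg.sparsity:.2f}, noise variance = {cfg.noise_variance:.2e}")
peak = null.grid[np.argmax(null.density)] if null.entries.size else float("nan")
print(f"null density peak at {peak:+.3f}; data entries sit at -0.5 exactly")

ci = ek.bootstrap_row_reduced_cis(snapshot, rrb, basis, n_replicates=500, seed=11)
width = np.max(ci.upper - ci.lower)
print(f"bootstrap 95% CIs: max width {width:.2e} over all entries "
      f"({ci.n_dropped} replicates dropped)")
print()
print("Converged simulated data gives razor-thin CIs; the data's exact")
print("-1/2 entries have no counterpart under the random-constraint null.")
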