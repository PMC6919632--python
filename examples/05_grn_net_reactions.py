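"""A non-complex-balanced GRN still yields interpretable net reactions.

The two-gene toy (genes gA, gB, proteins pA, pB, bound gene gA:pB) is
irreversible in production/degradation, so it is not complex-balanced --
yet its steady state satisfies log-linear constraints: the reversible
binding equilibrium, and the production/degradation balance
kB*gB = delta*pB, which links gB and pB in a 1 : -1 log ratio even
though (0, 1, 0, -1, 0) is not a reaction vector.
"""

import numpy as np

import esskit as ek

net = ek.toy_grn2(seed=21)  # random lognormal rates, fixed structure
print("rates:", [f"{r.rate:.2f}" for r in net.reactions])

init = ek.sample_initial_conditions(net, 300, log_mean=5.0, log_variance=8.0, seed=22)
snapshot = ek.integrate_ensemble(net, init, [1e4]).final()
spectrum = ek.fit_covariance_spectrum(snapshot)
print("eigenvalues:", np.array2string(spectrum.eigenvalues, formatter={"float": lambda x: f"{x:.2e}"}))

ess = ek.extract_ess(spectrum, dimension=net.stoichiometric_dimension())
rrb = ek.row_reduce_complete_pivoting(ess)
print("channels:", spectrum.channel_names)
for i, row in enumerate(rrb.vectors):
    pivot = spectrum.channel_names[rrb.pivot_channels[i]]
    print(f"net reaction {i} (pivot {pivot}):", np.round(row, 3))

i_gb = spectrum.channel_names.index("gB")
i_pb = spectrum.channel_names.index("pB")
row = max(range(rrb.dimension), key=lambda i: abs(rrb.vectors[i, i_gb]))
print(f"pB : gB entry ratio = {rrb.vectors[row, i_pb] / rrb.vectors[row, i_gb]:.4f}  (expected -1)")
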