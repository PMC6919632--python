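# Methods

## Model and assumptions

Each cell is a deterministic trajectory `c(t)` of a mass-action reaction
network shared by the whole population; cell-to-cell variability enters
only through lognormal initial conditions. Measured signals are assumed
linear in concentration per channel (`I_i = k_i · c_i`, antibody excess /
linear detection regime), which in log space is a per-channel additive
offset and therefore invisible to the covariance — gain invariance of
the inferred subspace is asserted in the test suite at 1e-10.

For complex-balanced networks the steady-state set is toric: after an
element-wise natural log it is an affine subspace whose orthogonal
complement equals the stoichiometric subspace `S`. Deficiency zero plus
weak reversibility is used as the (sufficient) complex-balance
certificate throughout; no attempt is made to certify complex balancing
for arbitrary rate constants at positive deficiency. Trajectories are
assumed to reach the exponentially stable neighborhood of their coset's
steady state by the observation time — "late time" below — which is
weaker than being at steady state.

Logarithms are natural everywhere. A different base would rescale every
log-space quantity uniformly and shift intercepts; nothing inferred here
depends on the choice.

## Pipeline and numerical choices

**Covariance spectrum.** Snapshots are log-transformed (values clipped
at 1e-300 first; clipped cells are logged), mean-centered, and the
unbiased `1/(N-1)` covariance is eigendecomposed with a symmetric solver;
eigenvalues are reported ascending and clipped at zero against round-off.
Channels with exactly zero variance are rejected with an error naming
them.

**Gap detection.** A gap is flagged after position `i` when
`λ_{i+1}/λ_i ≥ min_ratio` (default 3, a documented knob; a ratio test is
scale-free, so geometric eigenvalue decay produces no gaps). The default
chosen gap is the rightmost flagged one — the largest consistent set of
small eigenvalues — with manual override everywhere. Gap choice is
heuristic by nature; no asymptotic random-matrix significance test is
attempted at these dimensions.

**ESS extraction and row reduction.** The ESS basis is the eigenvectors
of the `k` smallest eigenvalues. For interpretation the basis transpose
is Gauss–Jordan eliminated with complete pivoting: at each step the
largest-magnitude entry of the remaining submatrix is the pivot (ties
break to the lowest column, then lowest row index), rows are scaled to
unit pivots, and pivot columns are eliminated exactly (assigned 0/1, not
left as round-off). Row/column permutations are recorded so bootstrap
replicates can replay the identical elimination. Bases that are
numerically rank-deficient (pivot below 1e-10 times the largest entry)
raise with the effective rank. Rank decisions elsewhere (orth/null-space)
use the same 1e-10 relative singular-value threshold.

**Entry distribution.** Non-structural entries (everything except the
0s and 1s elimination forces) are pooled across conditions and smoothed
with a Gaussian kernel of bandwidth 0.04 on the grid [-1.5, 1.5] in
steps of 0.005; the fraction inside (-0.2, 0.2) summarizes the zero
peak. On data, "structural" is decided by magnitude (|e| < 1e-9 or
|e-1| < 1e-9); in the null model it is decided by pivot column so that
deliberately sparsified entries stay in the pool (see below).

**Null model.** Per set, `s` vectors with entries uniform on
(-0.5, 0.5) are sparsified entrywise at the calibrated rate, row-reduced
with complete pivoting, pooled excluding pivot columns, and perturbed
with Gaussian noise whose variance matches the data's (-0.2, 0.2)
window; sets whose sparsified matrix loses rank are redrawn (logged).
Sparsity equals the data's in-window entry fraction. 1000 sets by
default.

**Bootstrap.** Percentile bootstrap (1000 replicates by default) over
cells resampled with replacement; each replicate optionally re-gates
with a GMM at the original component count, recomputes the spectrum,
takes the ESS at the original dimension, is rotated onto the original
basis by orthogonal Procrustes (this removes arbitrary eigenvector sign
flips, which would otherwise scramble entry signs across replicates),
and is eliminated by replaying the original pivot order. Replicates
whose replay hits a zero pivot are dropped and counted; >5% drops
warn. Simple percentile bounds, not BCa: nothing in the entries'
distribution warranted the extra machinery.

**Subpopulations.** Full-covariance Gaussian mixtures in log-signal
space, best of `20·k` k-means++ initializations, EM tolerance 1e-8,
covariance regularization 1e-6 times the mean channel variance. The
dominant (highest-weight) component defines the analyzed subpopulation
via maximum posterior responsibility. Component count: incremental
log-likelihood gains are first discounted by the parameter count an
extra component adds (the expected chance-level gain of a richer model);
k = 1 wins if even the first discounted gain is nonpositive, otherwise
the chosen k is the first whose onward gain drops below a fraction
(default 0.2) of the previous gain. The separation statistic between two
dominant components is the Mahalanobis distance between their means
under the weight-averaged within-component covariance — zero for
identical components and invariant under invertible linear maps applied
to both populations; other axis-scaling conventions exist and would
change absolute values but not these two properties.

**Principal angles.** Computed from the singular values of `UᵀW`
(clipped into [0, 1]); angles below π/4 are evaluated through the sine
form (scipy's dual-formulation routine), since arccos alone cannot
resolve angles under ~1e-8. The comparison metric `d = sqrt(Σ θ_i²)` is
only interpretable between equal-dimension subspaces, so unequal
dimensions raise unless explicitly allowed; for cross-condition
comparisons a common fixed dimension (default 10) is the intended usage.

**Integration.** Stiff-capable solvers (LSODA default) with analytic
Jacobians, rtol 1e-8 / atol 1e-10; failed cells are dropped from the
ensemble with a logged warning rather than aborting. Conservation-law
projections are monitored per trajectory; relative drift beyond 1e-6 is
reported. A convergence-based horizon is available (double `t` until the
largest log-variance along `S` improves by <1% per doubling, capped at
t = 1e4) alongside fixed timepoints.

## Synthetic data: what it emulates and what it does not

The generators reproduce the two families of study networks:

- **Random complex-balanced networks** (default 20 species): nodes are
  all complexes of one species or an unordered pair of distinct species
  (doubled complexes `2X` optional, off by default); 0.03% of ordered
  node pairs are sampled as edges and symmetrized; rate constants are
  lognormal with log-mean 2.5 or 3.0 (assigned per reversible pair at
  random — the two classes create mild timescale separation) and
  log-variance 0.05; candidates are redrawn until deficiency is zero
  (cap 10,000 attempts). Initial conditions lognormal(4, 4).
- **Random GRNs** (`n` genes): species are genes, proteins, and
  `round(0.7·n²)` protein-bound genes sampled without replacement;
  reactions are unbound production (rates LN(1,1)), reversible binding
  (LN(3,1) each direction), bound production (LN(3,3)), and degradation
  at the fixed rate e³. Initial conditions lognormal(5, 8). These
  networks are deliberately non-complex-balanced (irreversible
  production/degradation, large deficiency).

A fixed catalog of small named networks (`toy_network`) covers the
worked examples: `xyz`, `xyz_slow` (adds X<->Y at 0.2/0.1), the
three-species cycle `cycle3`, the kinase/phosphatase pair, its
two-enzyme and open (2X→E, Y→E, E→0) variants, and the two-gene GRN
`grn2`; unprinted rates default to 1. `toy_grn2(seed)` draws grn2's
rates from the GRN distributions with fixed structure.

What passing on these ensembles does **not** show about real data: cells
here are i.i.d. trajectories of one network with no measurement noise,
no autofluorescence/background, no cell-cycle or volume confounders, no
compartment mixing, and detection is exactly linear. Gap detection on
real spectra is correspondingly harder (the reason the gap threshold is
a knob and manual override is first-class). The per-cell tables the
readers ingest are CSV exports; binary FCS parsing, spillover
compensation and arcsinh transforms are out of scope.

## Problem sizes and degenerate inputs

Simulation-backed checks use 300-cell ensembles (the study convention).
Toy-network checks integrate to t = 100; the two-gene GRN ratio check
uses the convergence cap t = 1e4, because cells with a large bound-gene
pool buffer free protein and approach the production/degradation balance
slowly; the n = 7 GRN structure check uses t = 1000 with rtol 1e-6,
where the tilted directions have reached their plateau (their
eigenvalues are time-stable between t = 1e3 and 1e4). Degenerate inputs
fail loudly: empty tables, duplicate or zero-variance channels,
nonpositive linear-space values (with the offending cell named), rank
collapse under elimination or replay.

## Known limitations

- Deficiency-zero + weak reversibility is sufficient, not necessary;
  complex-balanced networks at positive deficiency with tuned rates are
  treated as out of scope.
- The tilt of production/degradation eigenvectors in GRNs is instance
  dependent (each extra bound variant adds an ε-order term); the
  regenerated-network check bounds it loosely rather than reproducing
  one instance's range.
- Gap choice remains heuristic; multistability and limit cycles are not
  handled.
- Bit-reproducibility holds per platform/BLAS; eigenvector signs are
  fixed only up to the solver's convention, which is why bootstrap
  alignment is explicit.
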