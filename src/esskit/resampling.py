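"""Null model for row-reduced entries and bootstrap confidence intervals.

The null asks: if the small-eigenvalue subspace were spanned by
*random* sparse constraints rather than stoichiometric ones, what would
the row-reduced entry distribution look like?  Each null set draws
``s`` vectors with entries uniform on (-0.5, 0.5), zeroes a random
fraction of entries, row-reduces with complete pivoting, pools the
non-structural entries, and adds Gaussian noise; the sparsity and the
noise variance are calibrated from the data's own near-zero window
(-0.2, 0.2).  Data mass piling up at integer ratios like -1, -1/2,
-1/3 beyond this null is the stoichiometric signal.

Bootstrap confidence intervals resample cells with replacement and
re-run the pipeline (optional GMM gating at the original component
count, spectrum, ESS at the original dimension) but *replay* the
original row/column pivot order instead of re-running complete
pivoting, so entries stay comparable across replicates.  Each
replicate's basis is first rotated (orthogonal Procrustes) onto the
original basis, which removes arbitrary eigenvector sign flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .inference import (
    ESSBasis,
    EntryDistribution,
    RowReducedBasis,
    extract_ess,
    fit_covariance_spectrum,
    pooled_entries,
    replay_row_reduction,
    row_reduce_complete_pivoting,
)
from .simulate import EnsembleSnapshot

__all__ = [
    "NullConfig",
    "BootstrapCI",
    "null_entry_distribution",
    "calibrate_null_from_data",
    "bootstrap_row_reduced_cis",
]

logger = logging.getLogger(__name__)


@dataclass
class NullConfig:
    s: int  # number of random constraint vectors per set
    dimension: int  # ambient (channel) dimension
    sparsity: float = 0.0  # fraction of entries zeroed before reduction
    noise_variance: float = 0.0
    n_sets: int = 1000
    bandwidth: float = 0.04
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.sparsity <= 1.0):
            raise ValueError("sparsity must be in [0, 1]")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.s >= self.dimension:
            raise ValueError("need fewer constraints than ambient dimensions")


def null_entry_distribution(config: NullConfig) -> EntryDistribution:
    """Monte-Carlo entry distribution under random sparse constraints."""
    rng = np.random.default_rng(config.seed)
    pool: list[np.ndarray] = []
    redraws = 0
    for _ in range(config.n_sets):
        for _attempt in range(100):
            M = rng.uniform(-0.5, 0.5, size=(config.s, config.dimension))
            M[rng.random(M.shape) < config.sparsity] = 0.0
            basis = ESSBasis(basis=M.T, channel_names=[f"c{j}" for j in range(config.dimension)])
            try:
                rrb = row_reduce_complete_pivoting(basis)
            except np.linalg.LinAlgError:
                redraws += 1
                continue
            entries = pooled_entries([rrb], structural=True)
            if entries.size and config.noise_variance > 0:
                entries = entries + rng.normal(0.0, np.sqrt(config.noise_variance), size=entries.size)
            pool.append(entries)
            break
        else:
            # fully sparse configurations can make every draw rank collapse
            pool.append(np.array([]))
    if redraws:
        logger.info("redrew %d rank-collapsed null sets", redraws)
    entries = np.concatenate(pool) if pool else np.array([])

    from .inference import DENSITY_GRID, gaussian_kernel_density

    density = gaussian_kernel_density(entries, config.bandwidth, DENSITY_GRID)
    frac = float(np.mean(np.abs(entries) < 0.2)) if entries.size else None
    return EntryDistribution(
        entries=entries,
        grid=DENSITY_GRID.copy(),
        density=density,
        bandwidth=config.bandwidth,
        fraction_near_zero=frac,
    )


def calibrate_null_from_data(
    entries: np.ndarray,
    s: int,
    dimension: int,
    window: float = 0.2,
    n_sets: int = 1000,
    bandwidth: float = 0.04,
    seed: int | None = None,
) -> NullConfig:
    """Match the null's sparsity and noise to the data's near-zero window."""
    entries = np.asarray(entries, dtype=float)
    if entries.size == 0:
        raise ValueError("cannot calibrate from an empty entry list")
    in_window = entries[np.abs(entries) < window]
    sparsity = float(in_window.size / entries.size)
    if in_window.size == 0:
        noise_var = 0.0
    elif in_window.size == 1:
        noise_var = 0.0
    else:
        noise_var = float(np.var(in_window, ddof=1))
    return NullConfig(
        s=s,
        dimension=dimension,
        sparsity=sparsity,
        noise_variance=noise_var,
        n_sets=n_sets,
        bandwidth=bandwidth,
        seed=seed,
    )


@dataclass
class BootstrapCI:
    """Percentile 95% bounds per row-reduced vector entry."""

    lower: np.ndarray  # dimension x channels
    upper: np.ndarray
    point: np.ndarray  # original-run estimate
    channel_names: list[str]
    n_replicates: int
    n_dropped: int


def _procrustes_align(basis: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate ``basis`` (orthonormal columns) to best match ``target``."""
    u, _, vt = np.linalg.svd(basis.T @ target)
    return basis @ (u @ vt)


def bootstrap_row_reduced_cis(
    snapshot: EnsembleSnapshot,
    template: RowReducedBasis,
    original_basis: ESSBasis,
    n_replicates: int = 1000,
    seed: int | None = None,
    gmm_k: int | None = None,
    gmm_n_init: int | None = None,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Percentile bootstrap for the row-reduced vector entries.

    ``snapshot`` is the original (pre-gating) data; if ``gmm_k`` is
    given, each replicate is re-gated with a GMM of that many components
    and its dominant cells kept, mirroring the original pipeline.
    Replicates whose elimination replay fails (rank collapse under the
    fixed pivot order) are dropped and counted; more than 5% drops
    triggers a warning.
    """
    rng = np.random.default_rng(seed)
    dim = template.dimension
    reps = []
    dropped = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, snapshot.n_cells, size=snapshot.n_cells)
        boot = snapshot.select_cells(idx)
        try:
            if gmm_k is not None and gmm_k > 1:
                from .mixtures import fit_gmm, select_subpopulation

                fit = fit_gmm(
                    boot,
                    gmm_k,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    n_init=gmm_n_init or 1,
                )
                boot = select_subpopulation(fit, boot)
            spec = fit_covariance_spectrum(boot)
            ess = extract_ess(spec, dimension=dim)
            aligned = _procrustes_align(ess.basis, original_basis.basis)
            rrb = replay_row_reduction(
                ESSBasis(aligned, ess.channel_names), template
            )
            reps.append(rrb.vectors)
        except (np.linalg.LinAlgError, ValueError):
            dropped += 1
    if not reps:
        raise RuntimeError("all bootstrap replicates failed")
    if dropped > 0.05 * n_replicates:
        logger.warning("%d/%d bootstrap replicates dropped", dropped, n_replicates)
    stack = np.stack(reps)
    lower = np.percentile(stack, 100 * alpha / 2, axis=0)
    upper = np.percentile(stack, 100 * (1 - alpha / 2), axis=0)
    return BootstrapCI(
        lower=lower,
        upper=upper,
        point=template.vectors.copy(),
        channel_names=list(template.channel_names),
        n_replicates=n_replicates,
        n_dropped=dropped,
    )
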