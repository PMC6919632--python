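"""Effective Stoichiometric Space (ESS) inference from snapshot covariance.

The pipeline implemented here:

1. ``fit_covariance_spectrum`` — natural-log transform, mean-center, and
   eigendecompose the unbiased sample covariance of a snapshot; the
   eigenvalues are reported ascending, so the "small" end of the
   spectrum corresponds to directions of vanishing variance — the
   candidate log-linear constraints.
2. ``detect_gaps`` — flag every position where consecutive eigenvalues
   jump by at least a configurable ratio.  Multiple gaps encode
   timescale separation: faster subnetworks equilibrate first, pushing
   their constraint directions to smaller eigenvalues and producing
   nested subspaces.
3. ``extract_ess`` — the ESS basis: the eigenvectors of the smallest
   ``k`` eigenvalues, for ``k`` chosen from a gap (or fixed).
4. ``row_reduce_complete_pivoting`` — Gauss-Jordan elimination on the
   transposed basis with complete pivoting, which rewrites the same
   subspace as sparse vectors with a unit "pivot" channel each; these
   read as net reactions.  The pivot row/column order is recorded so
   bootstrap replicates can replay the identical elimination.
5. ``entry_distribution`` — pool non-pivot entries across conditions and
   kernel-smooth them; mass at small-integer ratios (-1, -1/2, -1/3 ...)
   is the stoichiometric signature of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import EnsembleSnapshot

__all__ = [
    "EigenSpectrum",
    "GapReport",
    "ESSBasis",
    "RowReducedBasis",
    "fit_covariance_spectrum",
    "detect_gaps",
    "extract_ess",
    "extract_nested_ess",
    "row_reduce_complete_pivoting",
    "replay_row_reduction",
    "entry_distribution",
    "EntryDistribution",
]

#: tolerance for the exact-0/exact-1 exclusion in entry pooling
PIVOT_TOL = 1e-9

#: grid for kernel-smoothed entry densities
DENSITY_GRID = np.arange(-1.5, 1.5 + 1e-12, 0.005)


@dataclass
class EigenSpectrum:
    """Ascending eigenvalues/eigenvectors of a log-space sample covariance."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns aligned with eigenvalues
    n_cells: int
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(np.diff(self.eigenvalues) < 0):
            raise ValueError("eigenvalues must be ascending")


@dataclass
class GapReport:
    """Positions (1-based, counting from the small end) after which gaps occur."""

    indices: list[int]
    scores: list[float]
    chosen: int | None
    policy: str


@dataclass
class ESSBasis:
    """Orthonormal basis (columns) of the small-eigenvalue eigenspace."""

    basis: np.ndarray
    channel_names: list[str]
    source_gap: int | None = None

    @property
    def dimension(self) -> int:
        return self.basis.shape[1]


@dataclass
class RowReducedBasis:
    """Sparse recombination of an ESS basis; rows are net-reaction vectors.

    ``vectors`` is (dimension x n_channels) in the original channel
    order; ``pivot_channels[i]`` is the channel whose entry in row i is
    exactly 1 (and exactly 0 in every other row).  ``row_order`` and
    ``col_order`` record the complete-pivoting permutations so the
    elimination can be replayed on bootstrap replicates.
    """

    vectors: np.ndarray
    channel_names: list[str]
    pivot_channels: list[int]
    row_order: list[int]
    col_order: list[int]

    @property
    def dimension(self) -> int:
        return self.vectors.shape[0]


def fit_covariance_spectrum(snapshot: EnsembleSnapshot) -> EigenSpectrum:
    """Eigendecomposition of the log-space sample covariance (ascending)."""
    logs = snapshot.log().values
    n = logs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    var = np.var(logs, axis=0, ddof=1)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        names = [snapshot.channel_names[i] for i in dead]
        raise ValueError(f"channels with zero variance: {names}")
    centered = logs - logs.mean(axis=0, keepdims=True)
    cov = (centered.T @ centered) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending by contract
    evals = np.clip(evals, 0.0, None)  # round-off can push tiny eigenvalues negative
    return EigenSpectrum(evals, evecs, n_cells=n, channel_names=list(snapshot.channel_names))


def detect_gaps(spectrum: EigenSpectrum, min_ratio: float = 3.0) -> GapReport:
    """Flag every index i (1-based) with lambda_{i+1}/lambda_i >= min_ratio.

    The default chosen gap is the rightmost flagged one, matching the
    convention of taking the largest consistent set of small
    eigenvalues; callers may override by passing an explicit dimension
    to :func:`extract_ess`.  An empty report (no gaps) is not an error.
    """
    lam = spectrum.eigenvalues
    if lam.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    eps = 1e-15 * max(lam[-1], np.finfo(float).tiny)
    ratios = lam[1:] / np.maximum(lam[:-1], eps)
    indices = [int(i + 1) for i in np.flatnonzero(ratios >= min_ratio)]
    scores = [float(ratios[i - 1]) for i in indices]
    chosen = indices[-1] if indices else None
    return GapReport(indices=indices, scores=scores, chosen=chosen, policy=f"ratio>={min_ratio}")


def extract_ess(
    spectrum: EigenSpectrum,
    dimension: int | None = None,
    gaps: GapReport | None = None,
) -> ESSBasis:
    """Basis of the ``dimension`` smallest-eigenvalue eigenvectors.

    If ``dimension`` is None the chosen gap of ``gaps`` (or of a fresh
    :func:`detect_gaps` call) sets it.
    """
    if dimension is None:
        gaps = gaps or detect_gaps(spectrum)
        if gaps.chosen is None:
            raise ValueError("no gap detected and no dimension given")
        dimension = gaps.chosen
    if not (1 <= dimension <= len(spectrum.eigenvalues)):
        raise ValueError(f"dimension {dimension} out of range")
    return ESSBasis(
        basis=spectrum.eigenvectors[:, :dimension].copy(),
        channel_names=list(spectrum.channel_names),
        source_gap=dimension,
    )


def extract_nested_ess(spectrum: EigenSpectrum, gaps: GapReport | None = None) -> list[ESSBasis]:
    """One basis per detected gap, each nested in the next (timescale ladder)."""
    gaps = gaps or detect_gaps(spectrum)
    return [extract_ess(spectrum, dimension=i) for i in gaps.indices]


def _complete_pivot(A: np.ndarray, step: int) -> tuple[int, int]:
    """Largest-|entry| pivot in A[step:, step:]; ties to lowest column then row."""
    sub = np.abs(A[step:, step:])
    best = sub.max()
    # scan columns first so ties resolve to the lowest column index
    for j in range(sub.shape[1]):
        for i in range(sub.shape[0]):
            if sub[i, j] == best:
                return step + i, step + j
    raise AssertionError("unreachable")


def row_reduce_complete_pivoting(
    basis: ESSBasis, rank_tol: float = 1e-10
) -> RowReducedBasis:
    """Gauss-Jordan elimination with complete pivoting on the basis transpose.

    Rows of the result span exactly the input subspace; each row has a
    pivot entry of exactly 1 and zeros in every other row's pivot
    column.  Raises on numerically rank-deficient input, reporting the
    effective rank.
    """
    if basis.dimension == 0:
        raise ValueError("basis is empty")
    A = basis.basis.T.astype(float).copy()  # k rows x d channels
    k, d = A.shape
    row_perm = list(range(k))
    col_perm = list(range(d))
    scale = np.abs(A).max()
    for step in range(k):
        r, c = _complete_pivot(A, step)
        if np.abs(A[r, c]) <= rank_tol * scale:
            raise np.linalg.LinAlgError(
                f"basis numerically rank-deficient: effective rank {step} < {k}"
            )
        A[[step, r], :] = A[[r, step], :]
        row_perm[step], row_perm[r] = row_perm[r], row_perm[step]
        A[:, [step, c]] = A[:, [c, step]]
        col_perm[step], col_perm[c] = col_perm[c], col_perm[step]
        A[step, :] = A[step, :] / A[step, step]
        A[step, step] = 1.0
        for i in range(k):
            if i != step and A[i, step] != 0.0:
                A[i, :] -= A[i, step] * A[step, :]
                A[i, step] = 0.0
    return _assemble_rrb(A, basis.channel_names, row_perm, col_perm)


def _assemble_rrb(A: np.ndarray, channel_names, row_perm, col_perm) -> RowReducedBasis:
    k, d = A.shape
    # undo the column permutation so rows read in original channel order
    out = np.empty_like(A)
    for permuted_j, original_j in enumerate(col_perm):
        out[:, original_j] = A[:, permuted_j]
    pivots = [col_perm[i] for i in range(k)]
    for i, p in enumerate(pivots):  # exact 0/1 pivot structure
        out[:, p] = 0.0
        out[i, p] = 1.0
    return RowReducedBasis(
        vectors=out,
        channel_names=list(channel_names),
        pivot_channels=pivots,
        row_order=list(row_perm),
        col_order=list(col_perm),
    )


def replay_row_reduction(basis: ESSBasis, template: RowReducedBasis) -> RowReducedBasis:
    """Eliminate with the pivot order recorded in ``template`` (no pivot search).

    Used by the bootstrap: every replicate is reduced with the original
    run's row/column rearrangements so entries stay comparable.
    """
    A = basis.basis.T.astype(float).copy()
    k, d = A.shape
    if (k, d) != template.vectors.shape:
        raise ValueError("basis shape does not match template")
    # apply the recorded permutations up front
    A = A[template.row_order, :][:, template.col_order]
    for step in range(k):
        piv = A[step, step]
        if piv == 0.0:
            raise np.linalg.LinAlgError(f"zero pivot at replay step {step}")
        A[step, :] = A[step, :] / piv
        A[step, step] = 1.0
        for i in range(k):
            if i != step and A[i, step] != 0.0:
                A[i, :] -= A[i, step] * A[step, :]
                A[i, step] = 0.0
    return _assemble_rrb(A, template.channel_names, list(template.row_order), list(template.col_order))


@dataclass
class EntryDistribution:
    """Pooled row-reduced entries with a Gaussian-kernel smoothed density."""

    entries: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    fraction_near_zero: float | None  # mass in (-0.2, 0.2); None if no entries


def gaussian_kernel_density(entries: np.ndarray, bandwidth: float, grid: np.ndarray) -> np.ndarray:
    entries = np.asarray(entries, dtype=float)
    if entries.size == 0:
        return np.zeros_like(grid)
    z = (grid[:, None] - entries[None, :]) / bandwidth
    return np.exp(-0.5 * z**2).sum(axis=1) / (entries.size * bandwidth * np.sqrt(2 * np.pi))


def pooled_entries(bases: list[RowReducedBasis], structural: bool = False) -> np.ndarray:
    """All entries except the 0s and 1s that elimination necessarily produces.

    With ``structural=False`` (the data-side convention) exclusion is by
    magnitude: |entry| or |entry - 1| below ``PIVOT_TOL``.  With
    ``structural=True`` only the pivot *columns* are dropped, keeping
    incidental zeros — the convention the null model needs so that
    sparsified entries stay in the pool (as a zero-centered peak once
    noise is added).  The two agree on data, where exact zeros arise
    only from elimination.
    """
    pool = []
    for rrb in bases:
        if structural:
            keep_cols = [j for j in range(rrb.vectors.shape[1]) if j not in rrb.pivot_channels]
            pool.append(rrb.vectors[:, keep_cols].ravel())
        else:
            e = rrb.vectors.ravel()
            keep = (np.abs(e) > PIVOT_TOL) & (np.abs(e - 1.0) > PIVOT_TOL)
            pool.append(e[keep])
    return np.concatenate(pool) if pool else np.array([])


def entry_distribution(
    bases: list[RowReducedBasis], bandwidth: float = 0.04, window: float = 0.2
) -> EntryDistribution:
    """Pool non-structural entries across bases and kernel-smooth them."""
    if not bases:
        raise ValueError("need at least one row-reduced basis")
    entries = pooled_entries(bases)
    density = gaussian_kernel_density(entries, bandwidth, DENSITY_GRID)
    frac = (
        float(np.mean(np.abs(entries) < window)) if entries.size else None
    )
    return EntryDistribution(
        entries=entries,
        grid=DENSITY_GRID.copy(),
        density=density,
        bandwidth=bandwidth,
        fraction_near_zero=frac,
    )
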