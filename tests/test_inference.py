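"""Covariance spectra, eigenvalue gaps, ESS extraction, row reduction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import esskit as ek
from esskit.inference import (
    ESSBasis,
    EigenSpectrum,
    entry_distribution,
    gaussian_kernel_density,
    pooled_entries,
    replay_row_reduction,
)


def _spectrum(eigenvalues, d=None):
    lam = np.asarray(eigenvalues, float)
    d = d or lam.size
    return EigenSpectrum(lam, np.eye(d)[:, : lam.size], n_cells=100, channel_names=[f"c{i}" for i in range(d)])


class TestSpectrum:
    def test_hyperplane_data_has_zero_eigenvalue_with_normal_eigenvector(self):
        rng = np.random.default_rng(0)
        normal = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        X = rng.normal(size=(500, 3))
        X -= np.outer(X @ normal, normal)  # project onto the hyperplane
        spec = ek.fit_covariance_spectrum(ek.EnsembleSnapshot(X, list("abc"), log_space=True))
        assert spec.eigenvalues[0] == pytest.approx(0.0, abs=1e-12)
        assert abs(spec.eigenvectors[:, 0] @ normal) == pytest.approx(1.0, abs=1e-8)

    def test_xyz_late_time_recovers_reaction_vector(self, xyz_snapshot):
        spec = ek.fit_covariance_spectrum(xyz_snapshot)
        v = spec.eigenvectors[:, 0]
        target = np.array([-1.0, -1.0, 1.0]) / np.sqrt(3)
        assert min(np.linalg.norm(v - target), np.linalg.norm(v + target)) < 1e-4
        assert spec.eigenvalues[0] < 1e-10 * spec.eigenvalues[-1]

    def test_isotropic_gaussian_has_no_spurious_gap(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5000, 6))
        spec = ek.fit_covariance_spectrum(ek.EnsembleSnapshot(X, list("abcdef"), log_space=True))
        # eigenvalue spread consistent with sampling noise only: ratios stay small
        assert spec.eigenvalues[-1] / spec.eigenvalues[0] < 1.5
        assert not ek.detect_gaps(spec).indices

    def test_orthonormal_eigenvectors(self, kp_snapshot):
        spec = ek.fit_covariance_spectrum(kp_snapshot)
        assert np.allclose(spec.eigenvectors.T @ spec.eigenvectors, np.eye(4), atol=1e-8)

    def test_zero_variance_channel_rejected(self):
        X = np.ones((50, 2))
        X[:, 1] = np.random.default_rng(2).normal(size=50)
        with pytest.raises(ValueError, match="zero variance"):
            ek.fit_covariance_spectrum(ek.EnsembleSnapshot(X, ["dead", "ok"], log_space=True))


class TestGaps:
    def test_single_clear_gap(self):
        rep = ek.detect_gaps(_spectrum([1e-8, 1e-8, 1.0, 2.0]))
        assert rep.indices == [2] and rep.chosen == 2

    def test_geometric_sequence_has_no_gap(self):
        rep = ek.detect_gaps(_spectrum([2.0**i for i in range(8)]))
        assert rep.indices == [] and rep.chosen is None

    def test_rightmost_gap_chosen(self):
        rep = ek.detect_gaps(_spectrum([1e-9, 1e-4, 1e-4, 1.0, 2.0]))
        assert rep.indices == [1, 3] and rep.chosen == 3

    def test_timescale_separation_gives_two_gaps(self):
        # fast X+Y<->Z converged, slow X<->Y still relaxing at t=0.3
        net = ek.toy_network("xyz_slow")
        init = ek.sample_initial_conditions(net, 300, seed=105)
        snap = ek.integrate_ensemble(net, init, [0.3]).final()
        rep = ek.detect_gaps(ek.fit_covariance_spectrum(snap))
        assert rep.indices == [1, 2]


class TestExtractESS:
    def test_dimension_from_gap(self, xyz_snapshot):
        spec = ek.fit_covariance_spectrum(xyz_snapshot)
        basis = ek.extract_ess(spec, dimension=1)
        target = np.array([-1.0, -1.0, 1.0]) / np.sqrt(3)
        assert ek.principal_angles(basis.basis, target[:, None]).max() < 1e-4

    def test_full_dimension_is_whole_space(self, kp_snapshot):
        spec = ek.fit_covariance_spectrum(kp_snapshot)
        basis = ek.extract_ess(spec, dimension=4)
        assert basis.dimension == 4

    def test_dimension_out_of_range(self, kp_snapshot):
        spec = ek.fit_covariance_spectrum(kp_snapshot)
        with pytest.raises(ValueError):
            ek.extract_ess(spec, dimension=5)

    def test_nested_bases_are_nested(self):
        spec = _spectrum([1e-9, 1e-4, 1e-4, 1.0, 2.0], d=5)
        nested = ek.extract_nested_ess(spec)
        assert [b.dimension for b in nested] == [1, 3]
        small, large = nested
        assert ek.principal_angles(small.basis, large.basis).max() < 1e-10

    def test_ess_invariant_under_gains(self, kp_snapshot):
        spec0 = ek.fit_covariance_spectrum(kp_snapshot)
        spec1 = ek.fit_covariance_spectrum(ek.apply_gains(kp_snapshot, [3.0, 0.2, 5.0, 1.0]))
        b0 = ek.extract_ess(spec0, dimension=1).basis
        b1 = ek.extract_ess(spec1, dimension=1).basis
        assert ek.principal_angles(b0, b1).max() < 1e-10


class TestRowReduction:
    def test_single_row_scaled_to_pivot(self):
        v = np.array([1.0, 1.0, -1.0, -1.0])
        rrb = ek.row_reduce_complete_pivoting(ESSBasis(v[:, None] / 2.0, list("ESFP")))
        assert rrb.pivot_channels == [0]  # tie broken to lowest column
        assert np.array_equal(rrb.vectors[0], [1.0, 1.0, -1.0, -1.0])

    def test_identity_rows_unchanged(self):
        rrb = ek.row_reduce_complete_pivoting(ESSBasis(np.eye(4)[:, :2], list("abcd")))
        assert np.array_equal(rrb.vectors, np.eye(4)[:2])

    def test_two_row_rref_by_hand(self):
        # rows span {(1,-1,0), (0,1,-1)}; complete pivoting yields unit pivots
        M = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]).T
        rrb = ek.row_reduce_complete_pivoting(ESSBasis(M, list("abc")))
        # span preserved
        assert ek.principal_angles(
            ek.orthonormalize(rrb.vectors.T), ek.orthonormalize(M)
        ).max() < 1e-10
        # exact pivot structure
        for i, p in enumerate(rrb.pivot_channels):
            col = rrb.vectors[:, p]
            assert col[i] == 1.0 and np.all(col[np.arange(2) != i] == 0.0)

    def test_rank_deficient_basis_reports_effective_rank(self):
        M = np.array([[1.0, 2.0], [2.0, 4.0], [0.0, 0.0]])  # rank 1
        with pytest.raises(np.linalg.LinAlgError, match="rank 1"):
            ek.row_reduce_complete_pivoting(ESSBasis(M, list("abc")))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_span_preserved_on_random_bases(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(3, 8))
        k = int(rng.integers(1, d))
        B = np.linalg.qr(rng.normal(size=(d, k)))[0]
        rrb = ek.row_reduce_complete_pivoting(ESSBasis(B, [f"c{i}" for i in range(d)]))
        angles = ek.principal_angles(ek.orthonormalize(rrb.vectors.T), B)
        assert angles.max() < 1e-8

    def test_replay_reproduces_original(self):
        rng = np.random.default_rng(3)
        B = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        basis = ESSBasis(B, [f"c{i}" for i in range(6)])
        rrb = ek.row_reduce_complete_pivoting(basis)
        replayed = replay_row_reduction(basis, rrb)
        assert np.allclose(replayed.vectors, rrb.vectors, atol=1e-12)
        assert replayed.pivot_channels == rrb.pivot_channels


class TestEntryDistribution:
    def _rrb(self, vectors, pivots):
        vectors = np.asarray(vectors, float)
        return ek.RowReducedBasis(vectors, [f"c{i}" for i in range(vectors.shape[1])],
                                  pivots, list(range(vectors.shape[0])), list(range(vectors.shape[1])))

    def test_structural_zeros_and_ones_excluded(self):
        rrb = self._rrb([[1.0, 0.0, -0.5, 0.25]], [0])
        dist = entry_distribution([rrb])
        assert sorted(dist.entries) == [-0.5, 0.25]
        assert dist.fraction_near_zero == 0.0

    def test_all_structural_gives_empty_density(self):
        rrb = self._rrb([[1.0, 0.0, 0.0, 0.0]], [0])
        dist = entry_distribution([rrb])
        assert dist.entries.size == 0
        assert dist.fraction_near_zero is None
        assert np.all(dist.density == 0.0)

    def test_kernel_peak_location_and_width(self):
        rrb = self._rrb([[1.0, -1.0 + 1e-6, -1.0, -1.0]], [0])
        dist = entry_distribution([rrb], bandwidth=0.04)
        peak = dist.grid[np.argmax(dist.density)]
        assert peak == pytest.approx(-1.0, abs=0.01)
        # gaussian kernel: density at peak ~ 1/(bw*sqrt(2pi))
        assert dist.density.max() == pytest.approx(1 / (0.04 * np.sqrt(2 * np.pi)), rel=0.01)

    def test_kernel_density_normalizes(self):
        entries = np.array([-0.6, -0.3, 0.1])
        grid = np.arange(-3, 3, 0.005)
        dens = gaussian_kernel_density(entries, 0.04, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)
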