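"""Reaction-network structure: vectors, subspaces, deficiency, dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import esskit as ek
from esskit.networks import Reaction, ReactionNetwork, constraint_residual, LogLinearConstraint


@pytest.fixture
def xyz():
    return ek.toy_network("xyz")


class TestReactionVector:
    @pytest.mark.parametrize(
        "species,reactant,product,expected",
        [
            (["X", "Y", "Z"], {"X": 1, "Y": 1}, {"Z": 1}, [-1, -1, 1]),
            (["G", "P"], {"G": 1}, {"G": 1, "P": 1}, [0, 1]),  # catalyst cancels
            (["X", "E"], {"X": 2}, {"E": 1}, [-2, 1]),
        ],
    )
    def test_examples(self, species, reactant, product, expected):
        net = ReactionNetwork(species, [Reaction(reactant, product)])
        assert np.array_equal(net.reaction_vector(net.reactions[0]), expected)

    def test_undeclared_species_rejected(self, xyz):
        with pytest.raises(ValueError, match="species order"):
            xyz.reaction_vector(Reaction({"Q": 1}, {"Z": 1}))

    def test_reaction_invariants(self):
        with pytest.raises(ValueError):
            Reaction({"X": 1}, {"X": 1})  # reactant == product
        with pytest.raises(ValueError):
            Reaction({"X": 1}, {"Y": 1}, rate=0.0)
        with pytest.raises(ValueError):
            Reaction({"X": -1}, {"Y": 1})


class TestSubspaces:
    @pytest.mark.parametrize(
        "name,dim", [("xyz", 1), ("xyz_slow", 2), ("cycle3", 2), ("kinase_phosphatase", 1)]
    )
    def test_stoichiometric_dimension(self, name, dim):
        assert ek.toy_network(name).stoichiometric_dimension() == dim

    def test_conservation_xyz(self, xyz):
        W = xyz.conservation_basis()
        assert W.shape == (3, 2)
        # spans {(1,-1,0), (1,0,1)}: X-Y and X+Z are conserved
        for target in ([1, -1, 0], [1, 0, 1]):
            t = np.asarray(target, float)
            proj = W @ (W.T @ t)
            assert np.allclose(proj, t, atol=1e-10)

    def test_conservation_kinase_phosphatase(self):
        net = ek.toy_network("kinase_phosphatase")  # (E, S, F, P)
        W = net.conservation_basis()
        assert W.shape[1] == 3
        for target in ([1, 0, 0, 0], [0, 0, 1, 0], [0, 1, 0, 1]):  # E, F, S+P
            t = np.asarray(target, float)
            assert np.allclose(W @ (W.T @ t), t, atol=1e-10)

    def test_orthogonality_and_dimension_split(self):
        for name in ("xyz", "xyz_slow", "cycle3", "grn2", "kinase_phosphatase_open"):
            net = ek.toy_network(name)
            S = net.stoichiometric_subspace()
            W = net.conservation_basis()
            assert S.shape[1] + W.shape[1] == net.n_species
            if S.size and W.size:
                assert np.allclose(S.T @ W, 0.0, atol=1e-10)


class TestComplexDigraph:
    @pytest.mark.parametrize(
        "name,n_cplx,n_link,delta",
        [("xyz", 2, 1, 0), ("cycle3", 3, 1, 0)],
    )
    def test_deficiency_toys(self, name, n_cplx, n_link, delta):
        net = ek.toy_network(name)
        assert len(net.complexes()) == n_cplx
        assert net.n_linkage_classes() == n_link
        assert net.deficiency() == delta

    def test_single_irreversible_reaction(self):
        net = ReactionNetwork(["A", "B"], [Reaction({"A": 1}, {"B": 1})])
        assert net.deficiency() == 2 - 1 - 1 == 0

    def test_zero_complex_is_a_node(self):
        net = ReactionNetwork(["P"], [Reaction({"P": 1}, {})])
        assert len(net.complexes()) == 2

    def test_weak_reversibility(self):
        assert ek.toy_network("cycle3").is_weakly_reversible()
        assert ek.toy_network("xyz").is_weakly_reversible()
        assert not ek.toy_network("grn2").is_weakly_reversible()
        assert not ek.toy_network("kinase_phosphatase").is_weakly_reversible()

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_deficiency_nonnegative_on_random_networks(self, seed):
        cfg = ek.GeneratorConfig(n_species=6, edge_fraction=0.05, max_attempts=1)
        try:
            net = ek.random_complex_balanced_network(cfg, seed=seed)
        except RuntimeError:
            grn = ek.random_grn(ek.GeneratorConfig(n_genes=3), seed=seed)
            assert grn.deficiency() >= 0
            return
        assert net.deficiency() >= 0


class TestMassAction:
    def test_xyz_equilibrium_point(self, xyz):
        rhs = xyz.mass_action_rhs()
        assert np.allclose(rhs([1.0, 1.0, 1.0]), 0.0)  # k-1[Z] = k1[X][Y]

    def test_grn2_protein_b_rate(self):
        # dpB/dt = kB*gB - delta*pB + r*gAB - f*gA*pB
        net = ek.toy_network("grn2")
        c = {"gA": 2.0, "gB": 3.0, "pA": 5.0, "pB": 7.0, "gA:pB": 11.0}
        cv = np.array([c[s] for s in net.species])
        dpB = net.mass_action_rhs()(cv)[net.species.index("pB")]
        kB, f, r, delta = 1.0, 1.0, 1.0, 1.0
        assert dpB == pytest.approx(kB * 3.0 - delta * 7.0 + r * 11.0 - f * 2.0 * 7.0)

    def test_degradation_contribution(self):
        net = ReactionNetwork(["P"], [Reaction({"P": 1}, {}, rate=2.5)])
        assert net.mass_action_rhs()(np.array([4.0]))[0] == pytest.approx(-10.0)

    def test_negative_concentration_rejected(self, xyz):
        with pytest.raises(ValueError, match="nonnegative"):
            xyz.mass_action_rhs()(np.array([-1.0, 1.0, 1.0]))

    def test_jacobian_matches_finite_differences(self):
        net = ek.toy_network("grn2")
        rhs, jac = net.ode_rhs(), net.ode_jacobian()
        rng = np.random.default_rng(0)
        c = rng.uniform(0.5, 2.0, net.n_species)
        J = jac(0.0, c)
        eps = 1e-7
        for j in range(net.n_species):
            dc = np.zeros_like(c)
            dc[j] = eps
            fd = (rhs(0.0, c + dc) - rhs(0.0, c - dc)) / (2 * eps)
            assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-6)


class TestConstraintResidual:
    def test_data_on_hyperplane(self):
        rng = np.random.default_rng(1)
        v = np.array([1.0, -1.0, 0.5])
        X = rng.normal(size=(200, 3))
        X -= np.outer((X @ v - 2.0) / (v @ v), v)  # force v.x = 2
        var, intercept = constraint_residual(X, LogLinearConstraint(v))
        assert var == pytest.approx(0.0, abs=1e-20)
        assert intercept == pytest.approx(2.0)

    def test_orthogonal_direction_has_zero_variance(self):
        rng = np.random.default_rng(2)
        X = np.zeros((100, 3))
        X[:, :2] = rng.normal(size=(100, 2))  # support in first two coords
        var, _ = constraint_residual(X, LogLinearConstraint([0.0, 0.0, 1.0]))
        assert var == 0.0

    def test_isotropic_unit_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100_000, 4))
        v = np.array([0.5, 0.5, 0.5, 0.5])  # unit norm
        var, _ = constraint_residual(X, LogLinearConstraint(v))
        assert var == pytest.approx(1.0, abs=0.03)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            constraint_residual(np.empty((0, 3)), LogLinearConstraint([1.0, 0, 0]))
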