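"""Chemical reaction networks under mass-action kinetics.

A :class:`ReactionNetwork` is a list of species names plus a list of
:class:`Reaction` objects, each mapping a reactant complex to a product
complex with a positive rate constant.  From it we derive the quantities
that chemical reaction network theory (CRNT) attaches to a network:

* reaction vectors (product minus reactant stoichiometry),
* the stoichiometric subspace ``S`` (span of all reaction vectors) and
  its orthogonal complement (the conservation-law space),
* the complex digraph, its linkage classes, and the deficiency
  ``delta = n_complexes - n_linkage_classes - dim(S)``,
* weak reversibility (every complex lies on a directed cycle),
* the mass-action ODE right-hand side and its Jacobian.

Deficiency zero together with weak reversibility is the sufficient
condition used throughout this package for a network to be
complex-balanced, in which case the steady-state set is log-linear
(toric): every vector ``v`` in ``S`` satisfies ``v . log(c) = log(K)``
at steady state, for a constant ``K`` determined by the rate constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import linalg

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "LogLinearConstraint",
    "constraint_residual",
    "observable_intersection",
]

#: singular values below RANK_RTOL * largest are treated as zero
RANK_RTOL = 1e-10


def _as_complex(coeffs: Mapping[str, int]) -> dict[str, int]:
    """Validate and canonicalize a complex given as species -> coefficient."""
    out: dict[str, int] = {}
    for sp, c in coeffs.items():
        if c < 0 or int(c) != c:
            raise ValueError(f"complex coefficient for {sp!r} must be a nonnegative integer, got {c}")
        if c > 0:
            out[str(sp)] = int(c)
    return out


@dataclass(frozen=True)
class Reaction:
    """A single directed reaction ``reactant -> product`` with rate constant ``rate``.

    Complexes are mappings species -> nonnegative integer coefficient; the
    empty mapping is the zero complex (used for degradation ``P -> 0`` and
    inflow ``0 -> P``).
    """

    reactant: Mapping[str, int]
    product: Mapping[str, int]
    rate: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactant", _as_complex(self.reactant))
        object.__setattr__(self, "product", _as_complex(self.product))
        if not self.rate > 0:
            raise ValueError(f"rate constant must be positive, got {self.rate}")
        if self.reactant == self.product:
            raise ValueError("reactant and product complexes must differ")

    def species(self) -> set[str]:
        return set(self.reactant) | set(self.product)


@dataclass
class LogLinearConstraint:
    """A log-linear steady-state constraint ``vector . log(c) = intercept``."""

    vector: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.any(self.vector != 0):
            raise ValueError("constraint vector must have a nonzero entry")


class ReactionNetwork:
    """An ordered list of species plus mass-action reactions.

    Species order is fixed at construction; every vector this class
    returns is expressed in that order.
    """

    def __init__(self, species: Sequence[str], reactions: Iterable[Reaction]):
        self.species = list(species)
        if len(set(self.species)) != len(self.species):
            raise ValueError("species names must be unique")
        self.reactions = list(reactions)
        if not self.reactions:
            raise ValueError("network must contain at least one reaction")
        known = set(self.species)
        for r in self.reactions:
            missing = r.species() - known
            if missing:
                raise ValueError(f"reaction references undeclared species: {sorted(missing)}")
        self._index = {sp: i for i, sp in enumerate(self.species)}

    # -- basic structure -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    def _complex_vector(self, cplx: Mapping[str, int]) -> np.ndarray:
        v = np.zeros(self.n_species)
        for sp, c in cplx.items():
            v[self._index[sp]] = c
        return v

    def reaction_vector(self, reaction: Reaction) -> np.ndarray:
        """Product-minus-reactant stoichiometric vector over the species order."""
        missing = reaction.species() - set(self._index)
        if missing:
            raise ValueError(f"reaction species {sorted(missing)} not in network species order")
        return self._complex_vector(reaction.product) - self._complex_vector(reaction.reactant)

    def reaction_matrix(self) -> np.ndarray:
        """(n_reactions, n_species) matrix of reaction vectors."""
        return np.array([self.reaction_vector(r) for r in self.reactions])

    def reactant_matrix(self) -> np.ndarray:
        """(n_reactions, n_species) matrix of reactant stoichiometric coefficients."""
        return np.array([self._complex_vector(r.reactant) for r in self.reactions])

    def rates(self) -> np.ndarray:
        return np.array([r.rate for r in self.reactions])

    # -- subspaces -------------------------------------------------------

    def stoichiometric_subspace(self) -> np.ndarray:
        """Orthonormal basis (columns) of the span of all reaction vectors."""
        M = self.reaction_matrix().T  # species x reactions
        return linalg.orth(M, rcond=RANK_RTOL)

    def stoichiometric_dimension(self) -> int:
        return self.stoichiometric_subspace().shape[1]

    def conservation_basis(self) -> np.ndarray:
        """Orthonormal basis (columns) of the orthogonal complement of S.

        Each column ``w`` satisfies ``w . v = 0`` for every reaction vector
        ``v``; the linear quantity ``w . c(t)`` is conserved along every
        trajectory (forward invariance of stoichiometric cosets).
        """
        ns = linalg.null_space(self.reaction_matrix(), rcond=RANK_RTOL)
        if ns.size == 0:
            return np.zeros((self.n_species, 0))
        return ns

    # -- complex digraph and CRNT indices --------------------------------

    def complexes(self) -> list[tuple[tuple[str, int], ...]]:
        """Distinct complexes, as canonical sorted coefficient tuples."""
        seen: dict[tuple[tuple[str, int], ...], None] = {}
        for r in self.reactions:
            for c in (r.reactant, r.product):
                seen.setdefault(tuple(sorted(c.items())), None)
        return list(seen)

    def complex_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.complexes())
        for r in self.reactions:
            g.add_edge(tuple(sorted(r.reactant.items())), tuple(sorted(r.product.items())))
        return g

    def n_linkage_classes(self) -> int:
        return nx.number_weakly_connected_components(self.complex_digraph())

    def deficiency(self) -> int:
        """delta = n_complexes - n_linkage_classes - dim(S); always >= 0."""
        g = self.complex_digraph()
        return g.number_of_nodes() - nx.number_weakly_connected_components(g) - self.stoichiometric_dimension()

    def is_weakly_reversible(self) -> bool:
        """True iff every linkage class is a single strongly connected component."""
        g = self.complex_digraph()
        strong = {frozenset(c) for c in nx.strongly_connected_components(g)}
        weak = {frozenset(c) for c in nx.weakly_connected_components(g)}
        return strong == weak

    def is_complex_balanced_sufficient(self) -> bool:
        """Sufficient check: deficiency zero and weakly reversible."""
        return self.deficiency() == 0 and self.is_weakly_reversible()

    # -- dynamics --------------------------------------------------------

    def mass_action_rhs(self) -> Callable[[np.ndarray], np.ndarray]:
        """Return f with f(c) = dc/dt under mass-action kinetics.

        Raises ValueError on negative concentrations; use
        :meth:`ode_rhs` for an integrator-safe variant.
        """
        f = self.ode_rhs()

        def rhs(c: np.ndarray) -> np.ndarray:
            c = np.asarray(c, dtype=float)
            if np.any(c < 0):
                raise ValueError("concentrations must be nonnegative")
            return f(0.0, c)

        return rhs

    def ode_rhs(self) -> Callable[[float, np.ndarray], np.ndarray]:
        """Right-hand side f(t, c) for scipy.integrate; clips tiny negatives."""
        R = self.reactant_matrix()
        V = self.reaction_matrix()
        k = self.rates()

        def rhs(t: float, c: np.ndarray) -> np.ndarray:
            cc = np.clip(np.asarray(c, dtype=float), 0.0, None)
            fluxes = k * np.prod(cc[None, :] ** R, axis=1)
            return V.T @ fluxes

        return rhs

    def ode_jacobian(self) -> Callable[[float, np.ndarray], np.ndarray]:
        """Analytic Jacobian of the mass-action right-hand side."""
        R = self.reactant_matrix()
        V = self.reaction_matrix()
        k = self.rates()
        n = self.n_species

        def jac(t: float, c: np.ndarray) -> np.ndarray:
            cc = np.clip(np.asarray(c, dtype=float), 0.0, None)
            J = np.empty((n, n))
            for j in range(n):
                E = R.copy()
                E[:, j] = np.maximum(R[:, j] - 1, 0)
                dflux = k * R[:, j] * np.prod(cc[None, :] ** E, axis=1)
                J[:, j] = V.T @ dflux
            return J

        return jac

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "reactions": [
                {"reactants": dict(r.reactant), "products": dict(r.product), "rate": r.rate}
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReactionNetwork":
        reactions = [
            Reaction(r["reactants"], r["products"], float(r.get("rate", 1.0)))
            for r in d["reactions"]
        ]
        return cls(d["species"], reactions)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReactionNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ReactionNetwork({self.n_species} species, {len(self.reactions)} reactions, "
            f"s={self.stoichiometric_dimension()}, delta={self.deficiency()})"
        )


def constraint_residual(log_data: np.ndarray, constraint: LogLinearConstraint) -> tuple[float, float]:
    """Sample variance and mean of ``v . x`` across cells, for log-space data.

    Under an exact log-linear constraint the variance is zero and the mean
    estimates the intercept ``log K``.

    Returns ``(variance, intercept_estimate)``.
    """
    X = np.asarray(log_data, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("log_data must be a nonempty cells x channels matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("log_data must be finite")
    proj = X @ constraint.vector
    var = float(np.var(proj, ddof=1)) if proj.size > 1 else 0.0
    return var, float(np.mean(proj))


def observable_intersection(subspace: np.ndarray, observed: Sequence[int], n_total: int) -> np.ndarray:
    """Basis of ``S cap (R^obs + 0)``, restricted to the observed coordinates.

    ``subspace`` has orthonormal columns in the full n_total-dimensional
    species space; ``observed`` lists the observed coordinate indices.
    The returned orthonormal basis lives in the observed coordinates and
    equals the orthogonal complement of the projected log steady-state
    set: the marginal of a log-linear set is log-linear, and its
    complement is exactly this intersection.
    """
    B = np.asarray(subspace, dtype=float)
    observed = list(observed)
    hidden = [i for i in range(n_total) if i not in observed]
    if not hidden:
        return B[observed, :]
    # v = B a lies in the observed plane iff its hidden coordinates vanish
    A = B[hidden, :]
    coeffs = linalg.null_space(A, rcond=RANK_RTOL)
    if coeffs.size == 0:
        return np.zeros((len(observed), 0))
    vecs = B @ coeffs
    return linalg.orth(vecs[observed, :], rcond=RANK_RTOL)
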