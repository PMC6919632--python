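"""Random reaction-network generators and the catalog of toy networks.

Two random families are provided:

``random_complex_balanced_network``
    Complexes are single species or unordered pairs of distinct species;
    a small fraction of the possible directed edges between complexes is
    sampled and then symmetrized (every reaction gets its reverse), which
    makes the network weakly reversible.  Candidates are rejected until
    the deficiency is zero, so every accepted network is complex-balanced
    for all rate constants.  Rate constants are lognormal, drawn from two
    classes of log-mean (2.5 and 3.0, log-variance 0.05) assigned per
    reversible pair, which builds in a mild timescale separation.

``random_grn``
    A gene-regulatory network with n genes G_i, n proteins P_i, and a
    random ~70% of the n^2 possible protein-bound genes G_i:P_j.  The
    reaction classes are: unbound production G_i -> G_i + P_i, reversible
    binding G_i + P_j <-> G_i:P_j, bound production G_i:P_j -> G_i:P_j + P_i,
    and degradation P_i -> 0 with a single fixed rate.  These networks are
    never weakly reversible (production and degradation are irreversible)
    and have large deficiency; they are the non-complex-balanced stress
    test for the inference method.

Default rate and initial-condition distributions (natural-log
parameterization of the lognormal):

====================================  ========  ============
parameter                             log-mean  log-variance
====================================  ========  ============
concentration at t=0 (CB)             4         4
kinetic constants (CB)                2.5, 3    0.05
concentration at t=0 (GRN)            5         8
unbound production constants (GRN)    1         1
bound production constants (GRN)      3         3
protein binding/unbinding (GRN)       3         1
protein degradation rate (GRN)        3         fixed
====================================  ========  ============
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .networks import Reaction, ReactionNetwork

__all__ = [
    "GeneratorConfig",
    "random_complex_balanced_network",
    "random_grn",
    "grn_binding_subnetwork",
    "toy_network",
    "toy_grn2",
    "TOY_NETWORKS",
]


@dataclass
class GeneratorConfig:
    """Knobs for both random-network families; unused fields are ignored."""

    n_species: int = 20
    n_genes: int = 7
    edge_fraction: float = 0.0003
    bound_fraction: float = 0.7
    allow_doubled_complexes: bool = False
    cb_rate_log_means: tuple[float, float] = (2.5, 3.0)
    cb_rate_log_variance: float = 0.05
    grn_unbound_production: tuple[float, float] = (1.0, 1.0)  # (log-mean, log-var)
    grn_bound_production: tuple[float, float] = (3.0, 3.0)
    grn_binding: tuple[float, float] = (3.0, 1.0)
    grn_degradation_log_rate: float = 3.0
    max_attempts: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.edge_fraction <= 1):
            raise ValueError("edge_fraction must be in (0, 1]")
        if not (0 < self.bound_fraction <= 1):
            raise ValueError("bound_fraction must be in (0, 1]")


def _lognormal(rng: np.random.Generator, log_mean: float, log_var: float, size=None):
    return np.exp(rng.normal(log_mean, np.sqrt(log_var), size=size))


def random_complex_balanced_network(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> ReactionNetwork:
    """Draw a deficiency-zero, weakly reversible network by rejection.

    Raises RuntimeError (naming the attempt count) if no deficiency-zero
    candidate appears within ``config.max_attempts`` draws.
    """
    config = config or GeneratorConfig()
    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    species = [f"X{i+1}" for i in range(config.n_species)]
    nodes: list[dict[str, int]] = [{sp: 1} for sp in species]
    nodes += [{a: 1, b: 1} for a, b in combinations(species, 2)]
    if config.allow_doubled_complexes:
        nodes += [{sp: 2} for sp in species]
    n_nodes = len(nodes)
    n_possible = n_nodes * (n_nodes - 1)  # ordered distinct pairs, no self-loops

    lo, hi = config.cb_rate_log_means
    for attempt in range(1, config.max_attempts + 1):
        n_edges = rng.binomial(n_possible, config.edge_fraction)
        if n_edges == 0:
            continue
        # sample ordered node pairs without replacement
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < n_edges:
            i, j = rng.integers(0, n_nodes, size=2)
            if i != j:
                chosen.add((int(i), int(j)))
        # symmetrize into unordered reversible pairs
        pairs = {tuple(sorted(e)) for e in chosen}
        reactions = []
        for i, j in sorted(pairs):
            log_mean = lo if rng.random() < 0.5 else hi
            kf, kr = _lognormal(rng, log_mean, config.cb_rate_log_variance, size=2)
            reactions.append(Reaction(nodes[i], nodes[j], float(kf)))
            reactions.append(Reaction(nodes[j], nodes[i], float(kr)))
        net = ReactionNetwork(species, reactions)
        if net.deficiency() == 0:
            return net
    raise RuntimeError(
        f"no deficiency-zero network found in {config.max_attempts} attempts"
    )


def random_grn(config: GeneratorConfig | None = None, seed: int | None = None) -> ReactionNetwork:
    """Draw a random gene-regulatory network with the four printed reaction classes."""
    config = config or GeneratorConfig()
    n = config.n_genes
    if n < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genes = [f"G{i+1}" for i in range(n)]
    proteins = [f"P{i+1}" for i in range(n)]
    all_pairs = [(i, j) for i in range(n) for j in range(n)]
    m = int(round(config.bound_fraction * n * n))
    idx = rng.choice(len(all_pairs), size=m, replace=False)
    bound_pairs = [all_pairs[k] for k in sorted(idx)]
    bound = [f"G{i+1}:P{j+1}" for i, j in bound_pairs]

    species = genes + proteins + bound
    reactions: list[Reaction] = []
    for i in range(n):  # unbound production G_i -> G_i + P_i
        k = float(_lognormal(rng, *config.grn_unbound_production))
        reactions.append(Reaction({genes[i]: 1}, {genes[i]: 1, proteins[i]: 1}, k))
    for (i, j), b in zip(bound_pairs, bound):
        f = float(_lognormal(rng, *config.grn_binding))
        r = float(_lognormal(rng, *config.grn_binding))
        kij = float(_lognormal(rng, *config.grn_bound_production))
        reactions.append(Reaction({genes[i]: 1, proteins[j]: 1}, {b: 1}, f))
        reactions.append(Reaction({b: 1}, {genes[i]: 1, proteins[j]: 1}, r))
        reactions.append(Reaction({b: 1}, {b: 1, proteins[i]: 1}, kij))
    delta = float(np.exp(config.grn_degradation_log_rate))
    for p in proteins:  # degradation P_i -> 0
        reactions.append(Reaction({p: 1}, {}, delta))
    return ReactionNetwork(species, reactions)


def grn_binding_subnetwork(net: ReactionNetwork) -> ReactionNetwork:
    """The reversible-binding subnetwork of a GRN (reactions with a bound-gene species)."""
    # binding/unbinding reactions are exactly the ones converting
    # {gene, protein} <-> {bound gene}
    keep = [
        r
        for r in net.reactions
        if (any(":" in sp for sp in r.product) and not any(":" in sp for sp in r.reactant))
        or (any(":" in sp for sp in r.reactant) and not any(":" in sp for sp in r.product) and len(r.product) == 2)
    ]
    return ReactionNetwork(net.species, keep)


# ---------------------------------------------------------------------------
# toy-network catalog


def _xyz() -> ReactionNetwork:
    # X + Y <-> Z with k1 = k-1 = 1
    return ReactionNetwork(
        ["X", "Y", "Z"],
        [Reaction({"X": 1, "Y": 1}, {"Z": 1}, 1.0), Reaction({"Z": 1}, {"X": 1, "Y": 1}, 1.0)],
    )


def _xyz_slow() -> ReactionNetwork:
    # adds the slow X <-> Y with kf = 0.2, kr = 0.1
    base = _xyz()
    return ReactionNetwork(
        base.species,
        base.reactions
        + [Reaction({"X": 1}, {"Y": 1}, 0.2), Reaction({"Y": 1}, {"X": 1}, 0.1)],
    )


def _cycle3() -> ReactionNetwork:
    # A -> B <-> C -> A, all rates 1; steady state [A]/[B] = 2, [B]/[C] = 1/2
    return ReactionNetwork(
        ["A", "B", "C"],
        [
            Reaction({"A": 1}, {"B": 1}, 1.0),
            Reaction({"B": 1}, {"C": 1}, 1.0),
            Reaction({"C": 1}, {"B": 1}, 1.0),
            Reaction({"C": 1}, {"A": 1}, 1.0),
        ],
    )


def _kinase_phosphatase() -> ReactionNetwork:
    # E + S -> E + P, F + P -> F + S: toric but not complex-balanced
    return ReactionNetwork(
        ["E", "S", "F", "P"],
        [
            Reaction({"E": 1, "S": 1}, {"E": 1, "P": 1}, 1.0),
            Reaction({"F": 1, "P": 1}, {"F": 1, "S": 1}, 1.0),
        ],
    )


def _kinase_phosphatase_2enz() -> ReactionNetwork:
    # two kinases with a shared substrate; the drug-comparison toy
    return ReactionNetwork(
        ["E1", "E2", "S", "F", "P"],
        [
            Reaction({"E1": 1, "S": 1}, {"E1": 1, "P": 1}, 1.0),
            Reaction({"E2": 1, "S": 1}, {"E2": 1, "P": 1}, 1.0),
            Reaction({"F": 1, "P": 1}, {"F": 1, "S": 1}, 1.0),
        ],
    )


def _kinase_phosphatase_open() -> ReactionNetwork:
    # augmentation 2X -> E, Y -> E, E -> 0: adds a non-log-linear constraint
    base = _kinase_phosphatase()
    return ReactionNetwork(
        base.species + ["X", "Y"],
        base.reactions
        + [
            Reaction({"X": 2}, {"E": 1}, 1.0),
            Reaction({"Y": 1}, {"E": 1}, 1.0),
            Reaction({"E": 1}, {}, 1.0),
        ],
    )


def _grn2() -> ReactionNetwork:
    # two genes, one bound gene gA:pB; protein B activates/represses gene A
    return ReactionNetwork(
        ["gA", "gB", "pA", "pB", "gA:pB"],
        [
            Reaction({"gA": 1}, {"gA": 1, "pA": 1}, 1.0),
            Reaction({"gB": 1}, {"gB": 1, "pB": 1}, 1.0),
            Reaction({"gA": 1, "pB": 1}, {"gA:pB": 1}, 1.0),
            Reaction({"gA:pB": 1}, {"gA": 1, "pB": 1}, 1.0),
            Reaction({"gA:pB": 1}, {"gA:pB": 1, "pA": 1}, 1.0),
            Reaction({"pA": 1}, {}, 1.0),
            Reaction({"pB": 1}, {}, 1.0),
        ],
    )


TOY_NETWORKS = {
    "xyz": _xyz,
    "xyz_slow": _xyz_slow,
    "cycle3": _cycle3,
    "kinase_phosphatase": _kinase_phosphatase,
    "kinase_phosphatase_2enz": _kinase_phosphatase_2enz,
    "kinase_phosphatase_open": _kinase_phosphatase_open,
    "grn2": _grn2,
}


def toy_network(name: str) -> ReactionNetwork:
    """Fetch a toy network by name; rates default to 1 where not stated."""
    try:
        return TOY_NETWORKS[name]()
    except KeyError:
        raise KeyError(
            f"unknown toy network {name!r}; available: {sorted(TOY_NETWORKS)}"
        ) from None


def toy_grn2(seed: int | None = None, config: GeneratorConfig | None = None) -> ReactionNetwork:
    """The two-gene toy GRN with rate constants drawn from the GRN distributions.

    Structure is fixed (genes gA, gB; proteins pA, pB; bound gene gA:pB);
    only the rate constants are random.  With seed None all rates are 1.
    """
    net = _grn2()
    if seed is None:
        return net
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    kA = float(_lognormal(rng, *config.grn_unbound_production))
    kB = float(_lognormal(rng, *config.grn_unbound_production))
    f = float(_lognormal(rng, *config.grn_binding))
    r = float(_lognormal(rng, *config.grn_binding))
    kAB = float(_lognormal(rng, *config.grn_bound_production))
    delta = float(np.exp(config.grn_degradation_log_rate))
    rates = [kA, kB, f, r, kAB, delta, delta]
    reactions = [
        Reaction(rx.reactant, rx.product, k) for rx, k in zip(net.reactions, rates)
    ]
    return ReactionNetwork(net.species, reactions)
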