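"""Fixture networks with known ground truth.

Three hand-wired motifs cover the structures that make seed detection and
precursor enumeration non-trivial:

* the *cycle motif* — a target reachable only by borrowing a cycle
  metabolite that the expansion itself regenerates (six metabolites, four
  reactions; the canonical realisation of the borrowing-and-regenerating
  semantics, not a claim about any particular published drawing);
* the *reversible pair* — two metabolites interconverted by one reversible
  reaction, neither otherwise produced: a two-member source component whose
  members are alternative seeds;
* the *triple* — three metabolites joined into one source component by two
  reversible reactions.

A parameterised random generator produces small structurally valid networks
(designated nutrients are guaranteed seeds by construction: no reaction
produces them, and reactions consuming them are forced irreversible so no
backward orientation produces them either). Planted regeneration cycles
follow the cycle-motif template embedded at fresh positions. A two-organism
fixture plants a known seed overlap and known cross-feeding links. All
sampling is driven by a single integer seed; identical spec + seed yields an
identical network, down to the SBML bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_model import MetabolicNetwork, Metabolite, Reaction

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "make_cycle_motif",
    "make_reversible_pair_motif",
    "make_triple_motif",
    "random_network",
    "make_symbiosis_fixture",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random network generator.

    ``n_reactions`` counts the randomly sampled reactions; each planted
    regeneration cycle adds its own four template reactions on six fresh
    metabolites. Arities are inclusive bounds on the number of distinct
    metabolites per reaction side.
    """

    n_metabolites: int = 12
    n_reactions: int = 12
    min_arity: int = 1
    max_arity: int = 2
    frac_reversible: float = 0.2
    frac_nutrients: float = 0.25
    n_planted_cycles: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites <= 0 or self.n_reactions < 0:
            raise ValueError("counts must be positive")
        if not (1 <= self.min_arity <= self.max_arity):
            raise ValueError("arity bounds must satisfy 1 <= min <= max")
        for frac in (self.frac_reversible, self.frac_nutrients):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.max_arity > self.n_metabolites:
            raise ValueError("max_arity exceeds the number of metabolites")
        n_nutrients = int(round(self.frac_nutrients * self.n_metabolites))
        if self.n_metabolites - n_nutrients < self.max_arity:
            raise ValueError(
                "too few non-nutrient metabolites to sample product sides"
            )


@dataclass
class GroundTruth:
    """What the generator guarantees about its output, by construction."""

    seed_sets: list[frozenset[str]] = field(default_factory=list)
    targets: dict[str, list[frozenset[str]]] = field(default_factory=dict)
    common_seeds: frozenset[str] = frozenset()
    partner_produced: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def seeds(self) -> frozenset[str]:
        out: set[str] = set()
        for comp in self.seed_sets:
            out |= comp
        return frozenset(out)


def _network(mets: list[str], reactions: list[Reaction], provenance: str) -> MetabolicNetwork:
    return MetabolicNetwork(
        metabolites={m: Metabolite(id=m) for m in mets},
        reactions=reactions,
        provenance=provenance,
    )


def make_cycle_motif() -> tuple[MetabolicNetwork, GroundTruth]:
    """Six metabolites, four reactions; target needs a regenerated borrow.

    Wiring: R1: s1 + c1 -> c2 + i; R2: c2 -> c1; R3: i + s2 -> t;
    R4: i -> c2. Seeds {s1, s2}. The plain scope of {s1, s2} excludes t
    (nothing fires without c1), but borrowing c1 lets R1 fire, R2 (via R4)
    regenerates c1, and R3 reaches t: {s1, s2} is the unique minimal
    precursor set of t, with c1 among the self-generating witnesses.
    """
    reactions = [
        Reaction("R1", {"s1": 1.0, "c1": 1.0}, {"c2": 1.0, "i": 1.0}),
        Reaction("R2", {"c2": 1.0}, {"c1": 1.0}),
        Reaction("R3", {"i": 1.0, "s2": 1.0}, {"t": 1.0}),
        Reaction("R4", {"i": 1.0}, {"c2": 1.0}),
    ]
    net = _network(["s1", "s2", "c1", "c2", "i", "t"], reactions, "cycle motif")
    truth = GroundTruth(
        seed_sets=[frozenset({"s1"}), frozenset({"s2"})],
        targets={"t": [frozenset({"s1", "s2"})]},
    )
    return net, truth


def make_reversible_pair_motif() -> tuple[MetabolicNetwork, GroundTruth]:
    """Two alternative seeds interconverted by one reversible reaction.

    R1: a <-> b; R2: b -> x; R3: x -> t. Neither a nor b is otherwise
    produced, so {a, b} is a two-member source component and both are seeds;
    the downstream target t has the two alternative minimal precursor sets
    {a} and {b}.
    """
    reactions = [
        Reaction("R1", {"a": 1.0}, {"b": 1.0}, reversible=True),
        Reaction("R2", {"b": 1.0}, {"x": 1.0}),
        Reaction("R3", {"x": 1.0}, {"t": 1.0}),
    ]
    net = _network(["a", "b", "x", "t"], reactions, "reversible pair motif")
    truth = GroundTruth(
        seed_sets=[frozenset({"a", "b"})],
        targets={"t": [frozenset({"a"}), frozenset({"b"})]},
    )
    return net, truth


def make_triple_motif() -> tuple[MetabolicNetwork, GroundTruth]:
    """Three alternative seeds joined by two reversible reactions.

    R1: g <-> s; R2: g <-> h; R3: s -> t. The component {g, s, h} has no
    incoming arc, so all three are (alternative) seeds; any one of them
    suffices to reach the downstream target.
    """
    reactions = [
        Reaction("R1", {"g": 1.0}, {"s": 1.0}, reversible=True),
        Reaction("R2", {"g": 1.0}, {"h": 1.0}, reversible=True),
        Reaction("R3", {"s": 1.0}, {"t": 1.0}),
    ]
    net = _network(["g", "s", "h", "t"], reactions, "triple motif")
    truth = GroundTruth(
        seed_sets=[frozenset({"g", "s", "h"})],
        targets={"t": [frozenset({"g"}), frozenset({"s"}), frozenset({"h"})]},
    )
    return net, truth


def random_network(spec: GeneratorSpec) -> tuple[MetabolicNetwork, GroundTruth]:
    """Sample a structurally valid network per the spec (deterministic).

    Nutrients (a ``frac_nutrients`` share of the metabolites) appear only as
    substrates, never as products, and never in a reversible reaction's
    substrate side — so each is guaranteed a singleton source component.
    The randomly sampled reactions respect a fixed topological order on the
    metabolites (substrates strictly precede products, nutrients first), so
    directed cycles other than the reversible two-cycles only come from the
    explicitly planted regeneration templates. Sides are disjoint metabolite
    sets with unit coefficients.
    """
    rng = np.random.default_rng(spec.seed)
    mets = [f"m{i:02d}" for i in range(spec.n_metabolites)]
    n_nutrients = int(round(spec.frac_nutrients * spec.n_metabolites))
    nutrients = sorted(rng.choice(mets, size=n_nutrients, replace=False).tolist())
    internal = [m for m in mets if m not in nutrients]
    order = nutrients + internal  # topological order for random reactions

    reactions: list[Reaction] = []
    for r in range(spec.n_reactions):
        ns = int(rng.integers(spec.min_arity, spec.max_arity + 1))
        np_ = int(rng.integers(spec.min_arity, spec.max_arity + 1))
        # products drawn from the internal tail, substrates from before them
        lowest = max(len(nutrients), 1)
        np_ = min(np_, len(internal))
        first_prod = int(rng.integers(lowest, len(order) - np_ + 1))
        prod_pool = [m for m in order[first_prod:] if m in internal]
        prods = sorted(rng.choice(prod_pool, size=np_, replace=False).tolist())
        sub_pool = order[: min(o for o, m in enumerate(order) if m in prods)]
        ns = min(ns, len(sub_pool))
        subs = sorted(rng.choice(sub_pool, size=max(ns, 1), replace=False).tolist())
        reversible = bool(rng.random() < spec.frac_reversible) and not any(
            s in nutrients for s in subs
        )
        reactions.append(
            Reaction(
                f"RND{r:03d}",
                {s: 1.0 for s in subs},
                {p: 1.0 for p in prods},
                reversible=reversible,
            )
        )

    all_mets = list(mets)
    for c in range(spec.n_planted_cycles):
        prefix = f"cyc{c}_"
        names = [prefix + n for n in ("s1", "s2", "c1", "c2", "i", "t")]
        all_mets.extend(names)
        s1, s2, c1, c2, i, t = names
        reactions.extend(
            [
                Reaction(f"CYC{c}R1", {s1: 1.0, c1: 1.0}, {c2: 1.0, i: 1.0}),
                Reaction(f"CYC{c}R2", {c2: 1.0}, {c1: 1.0}),
                Reaction(f"CYC{c}R3", {i: 1.0, s2: 1.0}, {t: 1.0}),
                Reaction(f"CYC{c}R4", {i: 1.0}, {c2: 1.0}),
            ]
        )
        nutrients.extend([s1, s2])

    net = _network(
        all_mets, reactions, f"random network (seed={spec.seed})"
    )
    truth = GroundTruth(seed_sets=[frozenset({n}) for n in sorted(nutrients)])
    return net, truth


def make_symbiosis_fixture(
    shared_seeds: bool = True,
) -> tuple[MetabolicNetwork, MetabolicNetwork, GroundTruth]:
    """Two small networks with planted seed overlap and cross-feeding.

    Network A resembles an amino-acid producer: seeds {e4p, pep, ser} plus
    the alternative pair {oxa, asp}; network B a sugar-fed partner with
    seeds {glc, asp, ser}. Planted truth (for ``shared_seeds=True``):
    common seeds {asp, ser}; A-seeds produced by B: {e4p, pep, oxa};
    B-seeds produced by A: {asp}. With ``shared_seeds=False`` network B's
    shared ids are renamed ``b_*`` and the overlap is empty.
    """
    a_reactions = [
        Reaction("A1", {"oxa": 1.0}, {"asp": 1.0}, reversible=True),
        Reaction("A2", {"e4p": 1.0, "pep": 1.0}, {"i1": 1.0}),
        Reaction("A3", {"i1": 1.0, "ser": 1.0}, {"trp": 1.0}),
        Reaction("A4", {"asp": 1.0, "pep": 1.0}, {"lys": 1.0}),
    ]
    net_a = _network(
        ["e4p", "pep", "oxa", "asp", "ser", "i1", "trp", "lys"],
        a_reactions,
        "symbiosis fixture, organism A",
    )

    asp_b = "asp" if shared_seeds else "b_asp"
    ser_b = "ser" if shared_seeds else "b_ser"
    b_reactions = [
        Reaction("B1", {"glc": 1.0}, {"g6p": 1.0}),
        Reaction("B2", {"g6p": 1.0}, {"e4p": 1.0}),
        Reaction("B3", {"g6p": 1.0}, {"pep": 1.0}),
        Reaction("B4", {asp_b: 1.0}, {"oxa": 1.0}),
        Reaction("B5", {ser_b: 1.0}, {"gly": 1.0}),
    ]
    net_b = _network(
        ["glc", "g6p", "e4p", "pep", asp_b, ser_b, "oxa", "gly"],
        b_reactions,
        "symbiosis fixture, organism B",
    )

    truth = GroundTruth(
        seed_sets=[
            frozenset({"e4p"}),
            frozenset({"pep"}),
            frozenset({"ser"}),
            frozenset({"oxa", "asp"}),
        ],
        common_seeds=frozenset({"asp", "ser"}) if shared_seeds else frozenset(),
        partner_produced={
            "A": frozenset({"e4p", "pep", "oxa"}),
            "B": frozenset({"asp"}) if shared_seeds else frozenset(),
        },
        targets={
            "lys": [frozenset({"asp", "pep"}), frozenset({"oxa", "pep"})],
            "trp": [frozenset({"e4p", "pep", "ser"})],
        },
    )
    return net_a, net_b, truth
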