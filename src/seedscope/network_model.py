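"""Core data model for small-molecule metabolic networks.

A :class:`MetabolicNetwork` is the shared substrate of every analysis stage:
a map of metabolites plus an ordered list of directed (possibly reversible)
reactions. Networks are read from and written to SBML (Level 2 or 3, single
model, no fbc extension). Species ids are taken as-is and are the sole
identity of a metabolite; display names are kept for reporting only.
Compartments are ignored: all species are treated as one pool, which is
appropriate for single-compartment bacterial small-molecule metabolism.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import libsbml

__all__ = [
    "DirectionEvidence",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "RemovalEntry",
    "RemovalLog",
    "SBMLFormatError",
    "NetworkValidationError",
    "read_sbml",
    "write_sbml",
    "validate",
]


class SBMLFormatError(ValueError):
    """Raised when an SBML file cannot be parsed into a single valid model."""


class NetworkValidationError(ValueError):
    """Raised when input data violates a structural invariant."""


class DirectionEvidence(str, enum.Enum):
    """Provenance of a reaction's direction assignment.

    ``metacyc_pathway``: direction consistent across reference pathways;
    ``topological``: direction forced by network topology during curation;
    ``unassigned``: no evidence recorded (the default for fresh reads).
    """

    METACYC_PATHWAY = "metacyc_pathway"
    TOPOLOGICAL = "topological"
    UNASSIGNED = "unassigned"


@dataclass
class Metabolite:
    """A compound node. Identity is the id string; ``name`` is cosmetic."""

    id: str
    name: str = ""
    is_inorganic: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("metabolite id must be nonempty")


@dataclass
class Reaction:
    """A directed reaction: ``left`` consumed, ``right`` produced.

    Sides map metabolite id -> positive stoichiometric coefficient, so a
    metabolite appears at most once per side by construction. Empty sides are
    representable (filtering passes produce them transiently) but are flagged
    by :func:`validate` and removed by the carbonless-reaction drop.
    """

    id: str
    left: dict[str, float]
    right: dict[str, float]
    reversible: bool = False
    direction_evidence: DirectionEvidence = DirectionEvidence.UNASSIGNED
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("reaction id must be nonempty")
        for side_name, side in (("left", self.left), ("right", self.right)):
            for met_id, coeff in side.items():
                if not (coeff > 0):
                    raise NetworkValidationError(
                        f"reaction {self.id}: non-positive coefficient "
                        f"{coeff!r} for {met_id} on {side_name} side"
                    )

    @property
    def substrates(self) -> frozenset[str]:
        return frozenset(self.left)

    @property
    def products(self) -> frozenset[str]:
        return frozenset(self.right)

    @property
    def participants(self) -> frozenset[str]:
        return frozenset(self.left) | frozenset(self.right)

    def copy(self) -> "Reaction":
        return replace(self, left=dict(self.left), right=dict(self.right))


@dataclass
class MetabolicNetwork:
    """Metabolites plus an ordered reaction list, with free-text provenance."""

    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    provenance: str = ""

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions=[r.copy() for r in self.reactions],
            provenance=self.provenance,
        )

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def metabolites_in_use(self) -> set[str]:
        used: set[str] = set()
        for r in self.reactions:
            used |= r.participants
        return used

    def n_occurrences(self) -> int:
        """Total number of (reaction side, metabolite) occurrences."""
        return sum(len(r.left) + len(r.right) for r in self.reactions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )


@dataclass(frozen=True)
class RemovalEntry:
    entity_id: str
    kind: str  # "reaction" or "metabolite-occurrence"
    reason: str
    rule_id: str = ""


@dataclass
class RemovalLog:
    """Append-only audit trail of filtering removals."""

    entries: list[RemovalEntry] = field(default_factory=list)

    def add(self, entity_id: str, kind: str, reason: str, rule_id: str = "") -> None:
        self.entries.append(RemovalEntry(entity_id, kind, reason, rule_id))

    def extend(self, other: "RemovalLog") -> None:
        self.entries.extend(other.entries)

    def occurrences(self) -> list[RemovalEntry]:
        return [e for e in self.entries if e.kind == "metabolite-occurrence"]

    def reactions(self) -> list[RemovalEntry]:
        return [e for e in self.entries if e.kind == "reaction"]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RemovalEntry]:
        return iter(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("entity_id\tkind\treason\trule_id\n")
            for e in self.entries:
                fh.write(f"{e.entity_id}\t{e.kind}\t{e.reason}\t{e.rule_id}\n")


# ---------------------------------------------------------------------------
# SBML I/O


def _format_sbml_errors(doc: libsbml.SBMLDocument) -> str:
    msgs = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            msgs.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    return "; ".join(msgs)


def read_sbml(path: str | Path) -> MetabolicNetwork:
    """Read a single-model SBML file (Level 2 or 3) into a network.

    One :class:`Metabolite` per species, one :class:`Reaction` per reaction,
    in file order. The ``reversible`` flag comes from the SBML attribute
    (default true, per the SBML specifications); omitted stoichiometry
    defaults to 1. A reaction referencing an undeclared species or a
    duplicated reaction id is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) or doc.getNumErrors(
        libsbml.LIBSBML_SEV_FATAL
    ):
        raise SBMLFormatError(f"{path}: {_format_sbml_errors(doc)}")
    model = doc.getModel()
    if model is None:
        raise SBMLFormatError(f"{path}: file contains no SBML model")

    network = MetabolicNetwork(provenance=str(path))
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        met = Metabolite(id=sp.getId(), name=sp.getName() or "")
        if met.id in network.metabolites:
            raise NetworkValidationError(f"{path}: duplicate species id {met.id}")
        network.metabolites[met.id] = met

    seen_rxn: set[str] = set()
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = rxn.getId()
        if rid in seen_rxn:
            raise NetworkValidationError(f"{path}: duplicate reaction id {rid}")
        seen_rxn.add(rid)
        sides: list[dict[str, float]] = [{}, {}]
        for side_idx, getter, count in (
            (0, rxn.getReactant, rxn.getNumReactants()),
            (1, rxn.getProduct, rxn.getNumProducts()),
        ):
            for j in range(count):
                ref = getter(j)
                sid = ref.getSpecies()
                if sid not in network.metabolites:
                    raise NetworkValidationError(
                        f"{path}: reaction {rid} references undeclared species {sid}"
                    )
                stoich = ref.getStoichiometry()
                if stoich is None or math.isnan(stoich):
                    stoich = 1.0
                # repeated species references on one side are summed
                sides[side_idx][sid] = sides[side_idx].get(sid, 0.0) + stoich
        reversible = rxn.getReversible() if rxn.isSetReversible() else True
        network.reactions.append(
            Reaction(id=rid, left=sides[0], right=sides[1], reversible=reversible)
        )
    return network


def write_sbml(network: MetabolicNetwork, path: str | Path) -> None:
    """Write a network as SBML Level 3 Version 1 (single compartment).

    The emitted file round-trips: ``read_sbml(write_sbml(n)) == n`` for ids,
    sides, coefficients and reversibility. Output is deterministic.
    """
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("model")
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)

    for met in network.metabolites.values():
        sp = model.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment("cell")
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    for r in network.reactions:
        rxn = model.createReaction()
        rxn.setId(r.id)
        rxn.setReversible(r.reversible)
        rxn.setFast(False)
        for mid, coeff in r.left.items():
            ref = rxn.createReactant()
            ref.setSpecies(mid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for mid, coeff in r.right.items():
            ref = rxn.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)

    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise OSError(f"could not write SBML to {path}")


def validate(network: MetabolicNetwork) -> list[str]:
    """Return a list of invariant violations (empty iff the network is sound).

    Violations are data, not exceptions; each names the offending entity.
    The check is pure and never mutates the network.
    """
    violations: list[str] = []
    for mid, met in network.metabolites.items():
        if not mid:
            violations.append("metabolite with empty id")
        if met.id != mid:
            violations.append(f"metabolite map key {mid!r} != metabolite id {met.id!r}")
    seen: set[str] = set()
    for r in network.reactions:
        if r.id in seen:
            violations.append(f"duplicate reaction id {r.id}")
        seen.add(r.id)
        if not r.left:
            violations.append(f"reaction {r.id}: empty left side")
        if not r.right:
            violations.append(f"reaction {r.id}: empty right side")
        for mid in sorted(r.participants):
            if mid not in network.metabolites:
                violations.append(f"reaction {r.id}: unknown metabolite {mid}")
        for side_name, side in (("left", r.left), ("right", r.right)):
            for mid, coeff in side.items():
                if not (coeff > 0):
                    violations.append(
                        f"reaction {r.id}: non-positive coefficient for {mid} "
                        f"({side_name})"
                    )
    return violations
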