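"""Seed identification and cross-network seed classification.

A *seed* is a metabolite the network cannot synthesise from other compounds
of the network, so it must be exogenously acquired. The naive reading —
"consumed but never produced" — breaks on reversible reactions: a nutrient
interconverted with an internal compound by a reversible reaction *is*
produced by that reaction, yet one member of the pair must still enter from
outside. The SCC-condensation definition handles this: condense the compound
graph by strongly connected components and call every member of a *source
component* (an SCC with no incoming arc from outside itself) a seed. A
multi-member source component is a group of *alternative seeds* — any of its
members could be the actually imported compound, and the group structure is
preserved so downstream precursor enumeration can treat them as alternatives.

Seeds are computed on the compound graph, not the hypergraph: strongly
connected components have no settled definition on hypergraphs.

For a symbiotic system, seeds of one partner are then classified against the
co-symbiont's network (can the partner produce them?) and against
user-supplied host/diet and transporter-annotation lists. The host/diet
knowledge enters only via those lists — the pipeline makes no claim of
deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .graphs import CompoundGraph, build_compound_graph, build_hypergraph
from .network_model import MetabolicNetwork

__all__ = [
    "SeedReport",
    "SeedFlags",
    "SeedClassification",
    "strongly_connected_components",
    "source_components",
    "identify_seeds",
    "classify_seeds",
    "compare_seed_sets",
]


def _canonical(components: list[set[str]]) -> list[frozenset[str]]:
    """Order components by size then lexicographically by sorted members."""
    return sorted(
        (frozenset(c) for c in components), key=lambda c: (len(c), sorted(c))
    )


@dataclass
class SeedReport:
    """Source components of the compound-graph condensation.

    ``seeds`` is the union of all source components; ``alternative_groups``
    are the source components with at least two members.
    """

    source_components: list[frozenset[str]] = field(default_factory=list)

    @property
    def seeds(self) -> frozenset[str]:
        out: set[str] = set()
        for comp in self.source_components:
            out |= comp
        return frozenset(out)

    @property
    def alternative_groups(self) -> list[frozenset[str]]:
        return [c for c in self.source_components if len(c) >= 2]

    def component_of(self, seed: str) -> frozenset[str]:
        for comp in self.source_components:
            if seed in comp:
                return comp
        raise KeyError(seed)

    def to_tsv(self, path: str | Path, classification: "SeedClassification | None" = None) -> None:
        with open(path, "w") as fh:
            fh.write(
                "seed\tcomponent_id\tcomponent_size\t"
                "partner_produced\thost_or_diet\ttransport_annotated\n"
            )
            for idx, comp in enumerate(self.source_components):
                for seed in sorted(comp):
                    flags = classification.flags[seed] if classification else None
                    fh.write(
                        f"{seed}\tC{idx}\t{len(comp)}\t"
                        f"{int(flags.partner_produced) if flags else ''}\t"
                        f"{int(flags.host_or_diet) if flags else ''}\t"
                        f"{int(flags.transport_annotated) if flags else ''}\n"
                    )


@dataclass(frozen=True)
class SeedFlags:
    partner_produced: bool
    host_or_diet: bool
    transport_annotated: bool


@dataclass
class SeedClassification:
    """Per-seed provenance flags; covers exactly the seeds of one report."""

    flags: dict[str, SeedFlags] = field(default_factory=dict)

    @property
    def partner_produced(self) -> frozenset[str]:
        return frozenset(s for s, f in self.flags.items() if f.partner_produced)


def strongly_connected_components(graph: CompoundGraph) -> list[frozenset[str]]:
    """Partition the nodes into maximal mutually-reachable sets.

    Singleton nodes, including isolated ones, are components of their own.
    """
    g = graph.to_networkx()
    return _canonical([set(c) for c in nx.strongly_connected_components(g)])


def source_components(graph: CompoundGraph) -> list[frozenset[str]]:
    """SCCs with no incoming arc from outside themselves.

    Self-loops and arcs internal to a component do not count as incoming
    (the condensation DAG drops them).
    """
    g = graph.to_networkx()
    cond = nx.condensation(g)
    out = []
    for node in cond.nodes:
        if cond.in_degree(node) == 0:
            out.append(set(cond.nodes[node]["members"]))
    return _canonical(out)


def identify_seeds(network: MetabolicNetwork) -> SeedReport:
    """Seed report of a network (assumed already filtered to carbon core).

    Builds the compound graph, condenses by SCC and returns the source
    components. Filtering is the caller's responsibility: on an unfiltered
    network the ubiquitous currency metabolites distort the components.
    """
    graph = build_compound_graph(network)
    return SeedReport(source_components=source_components(graph))


def classify_seeds(
    report: SeedReport,
    partner: MetabolicNetwork | None,
    host_list: frozenset[str] | set[str] = frozenset(),
    transport_list: frozenset[str] | set[str] = frozenset(),
) -> SeedClassification:
    """Flag each seed as partner-produced, host/diet-reported, transporter-annotated.

    A seed is partner-produced iff it is in the product set of at least one
    directed hyperarc of the partner's hypergraph (both orientations of
    reversible reactions count). The partner network should have been
    filtered the same way as the seed network.
    """
    produced: frozenset[str] = frozenset()
    if partner is not None and partner.reactions:
        produced = build_hypergraph(partner).producible()
    flags = {
        seed: SeedFlags(
            partner_produced=seed in produced,
            host_or_diet=seed in host_list,
            transport_annotated=seed in transport_list,
        )
        for seed in sorted(report.seeds)
    }
    return SeedClassification(flags=flags)


def compare_seed_sets(
    report_a: SeedReport,
    report_b: SeedReport,
    synonyms: Mapping[str, str] | None = None,
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Set algebra on two seed unions: (common, specific to A, specific to B).

    ``synonyms`` maps ids to canonical ids and is applied to both sides
    before comparing — cross-network id reconciliation is explicit, never
    fuzzy, because silent mismatches would corrupt the partition.
    """
    syn = dict(synonyms or {})

    def canon(ids: frozenset[str]) -> frozenset[str]:
        return frozenset(syn.get(i, i) for i in ids)

    a, b = canon(report_a.seeds), canon(report_b.seeds)
    return a & b, a - b, b - a
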