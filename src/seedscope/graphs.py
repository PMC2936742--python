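"""The two network views the analysis algorithms operate on.

Seed detection works on the *compound graph*: a directed simple graph on
metabolites with an arc whenever some reaction produces one compound from
the other (reversible reactions contribute both directions). Strongly
connected components are well defined there, which is exactly why seeds are
computed on this view.

Reachability and precursor enumeration work on the *reaction hypergraph*:
each reaction orientation is a hyperarc consuming its full substrate set and
yielding its full product set, which captures the need for all substrates
simultaneously — the property the compound graph deliberately throws away.

Stoichiometric coefficients are intentionally discarded in both views (set
semantics); feasibility under stoichiometric constraints is a different,
finer-grained question than the topological one asked here. A metabolite on
both sides of one reaction induces a self-loop arc in the compound graph and
appears in both sets of the hyperarc, which can affect SCC membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .network_model import MetabolicNetwork, NetworkValidationError

__all__ = [
    "CompoundGraph",
    "Hyperarc",
    "ReactionHypergraph",
    "build_compound_graph",
    "build_hypergraph",
    "export_edge_list",
    "export_graphml",
]


@dataclass
class CompoundGraph:
    """Directed simple graph on metabolite ids (set semantics, no parallels)."""

    nodes: set[str] = field(default_factory=set)
    arcs: set[tuple[str, str]] = field(default_factory=set)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.arcs))
        return g


@dataclass(frozen=True)
class Hyperarc:
    """One reaction orientation: substrate set -> product set."""

    id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reaction_id: str
    orientation: str  # "forward" or "backward"


@dataclass
class ReactionHypergraph:
    """Directed hypergraph on metabolite ids.

    Every irreversible reaction contributes exactly one (forward) hyperarc;
    every reversible reaction exactly two (forward + backward).
    """

    vertices: set[str] = field(default_factory=set)
    hyperarcs: list[Hyperarc] = field(default_factory=list)

    def arc_by_id(self) -> dict[str, Hyperarc]:
        return {h.id: h for h in self.hyperarcs}

    def producible(self) -> frozenset[str]:
        """Metabolites that are a product of at least one hyperarc."""
        out: set[str] = set()
        for h in self.hyperarcs:
            out |= h.products
        return frozenset(out)


def build_compound_graph(network: MetabolicNetwork) -> CompoundGraph:
    """Arcs from every substrate to every product of each reaction.

    Reversible reactions also contribute every product->substrate arc.
    Metabolites present in the map but in no reaction become isolated nodes.
    """
    g = CompoundGraph(nodes=set(network.metabolites))
    for rxn in network.reactions:
        g.nodes |= rxn.participants
        for a in rxn.left:
            for b in rxn.right:
                g.arcs.add((a, b))
                if rxn.reversible:
                    g.arcs.add((b, a))
    return g


def build_hypergraph(network: MetabolicNetwork) -> ReactionHypergraph:
    """One hyperarc per reaction orientation; coefficients are dropped."""
    hg = ReactionHypergraph(vertices=set(network.metabolites))
    for rxn in network.reactions:
        if not rxn.left or not rxn.right:
            raise NetworkValidationError(
                f"reaction {rxn.id} has an empty side; filter the network "
                "(drop_carbonless_reactions) before building the hypergraph"
            )
        hg.vertices |= rxn.participants
        hg.hyperarcs.append(
            Hyperarc(
                id=f"{rxn.id}__f",
                substrates=rxn.substrates,
                products=rxn.products,
                reaction_id=rxn.id,
                orientation="forward",
            )
        )
        if rxn.reversible:
            hg.hyperarcs.append(
                Hyperarc(
                    id=f"{rxn.id}__b",
                    substrates=rxn.products,
                    products=rxn.substrates,
                    reaction_id=rxn.id,
                    orientation="backward",
                )
            )
    return hg


def export_edge_list(graph: CompoundGraph, path: str | Path) -> None:
    """Write the compound graph as a two-column TSV (source, target)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(graph.arcs):
            fh.write(f"{a}\t{b}\n")


def export_graphml(graph: CompoundGraph, path: str | Path) -> None:
    nx.write_graphml(graph.to_networkx(), str(path))
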