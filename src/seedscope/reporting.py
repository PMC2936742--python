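"""Certificate sub-networks and summary tables.

Each minimal precursor set comes with a certifying expansion (the fired
hyperarcs). :func:`extract_subnetwork` reduces that expansion to the
bipartite metabolite/reaction sub-network actually supporting the target:
fired hyperarcs are backward-pruned, keeping those from which the target is
forward-reachable plus the machinery regenerating every borrowed
self-generating metabolite that remains in use — without the regeneration
loops the certificate would be invalid, even though they are not on a simple
path to the target. Exports (SIF and GraphML, loadable in standard network
viewers) are deterministic byte-for-byte given the same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

from .graphs import ReactionHypergraph
from .precursors import PrecursorSolution, PrecursorTable
from .seeds import SeedClassification, SeedReport

__all__ = [
    "SubNetwork",
    "extract_subnetwork",
    "export_subnetwork",
    "render_summary",
]


@dataclass
class SubNetwork:
    """Bipartite certificate graph: metabolite and reaction (hyperarc) nodes.

    ``roles`` maps each metabolite node to one of precursor /
    self-generating / intermediate / target; links run metabolite->reaction
    for substrates and reaction->metabolite for products only.
    """

    metabolite_roles: dict[str, str] = field(default_factory=dict)
    reaction_nodes: list[str] = field(default_factory=list)
    links: list[tuple[str, str, str]] = field(default_factory=list)


def extract_subnetwork(
    hg: ReactionHypergraph, solution: PrecursorSolution
) -> SubNetwork:
    """Prune a solution's fired hyperarcs down to its supporting sub-network.

    Fixpoint rule: keep a fired hyperarc if it produces the target, feeds a
    kept hyperarc, or regenerates a self-generating metabolite consumed by a
    kept hyperarc. Fired dead-end branches are thereby dropped.
    """
    arcs = hg.arc_by_id()
    fired = [arcs[hid] for hid in solution.fired]
    target = solution.target

    useful: set[str] = set()
    while True:
        needed_z = set()
        for h in fired:
            if h.id in useful:
                needed_z |= solution.self_generating & h.substrates
        changed = False
        for h in fired:
            if h.id in useful:
                continue
            feeds_useful = any(
                h.products & arcs[uid].substrates for uid in useful
            )
            if target in h.products or feeds_useful or (h.products & needed_z):
                useful.add(h.id)
                changed = True
        if not changed:
            break

    kept = [h for h in fired if h.id in useful]
    sub = SubNetwork()
    mets: set[str] = {target}
    for h in kept:
        mets |= h.substrates | h.products
    for m in sorted(mets):
        if m == target:
            role = "target"
        elif m in solution.precursors:
            role = "precursor"
        elif m in solution.self_generating:
            role = "self-generating"
        else:
            role = "intermediate"
        sub.metabolite_roles[m] = role
    for h in sorted(kept, key=lambda h: h.id):
        sub.reaction_nodes.append(h.id)
        for m in sorted(h.substrates):
            sub.links.append((m, h.id, "substrate-of"))
        for m in sorted(h.products):
            sub.links.append((h.id, m, "produces"))
    return sub


def _write_sif(sub: SubNetwork, path: Path) -> None:
    with open(path, "w") as fh:
        for src, dst, kind in sub.links:
            fh.write(f"{src}\t{kind}\t{dst}\n")


def _write_graphml(sub: SubNetwork, path: Path) -> None:
    # hand-rolled serialisation (not networkx) to guarantee stable attribute
    # ordering and byte-for-byte determinism across library versions
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '  <key id="kind" for="node" attr.name="kind" attr.type="string"/>',
        '  <key id="role" for="node" attr.name="role" attr.type="string"/>',
        '  <key id="interaction" for="edge" attr.name="interaction" attr.type="string"/>',
        '  <graph edgedefault="directed">',
    ]
    for m in sorted(sub.metabolite_roles):
        role = sub.metabolite_roles[m]
        lines.append(
            f"    <node id={quoteattr(m)}>"
            f'<data key="kind">metabolite</data>'
            f'<data key="role">{escape(role)}</data></node>'
        )
    for r in sub.reaction_nodes:
        lines.append(
            f"    <node id={quoteattr(r)}>"
            f'<data key="kind">reaction</data></node>'
        )
    for src, dst, kind in sub.links:
        lines.append(
            f"    <edge source={quoteattr(src)} target={quoteattr(dst)}>"
            f'<data key="interaction">{escape(kind)}</data></edge>'
        )
    lines += ["  </graph>", "</graphml>", ""]
    path.write_text("\n".join(lines))


def export_subnetwork(sub: SubNetwork, format: str, path: str | Path) -> None:
    """Write a sub-network as SIF or GraphML."""
    path = Path(path)
    if format.upper() == "SIF":
        _write_sif(sub, path)
    elif format.lower() == "graphml":
        _write_graphml(sub, path)
    else:
        raise ValueError(f"unknown export format {format!r} (use SIF or GraphML)")


def render_summary(
    outdir: str | Path,
    seed_reports: dict[str, SeedReport],
    classifications: dict[str, SeedClassification] | None = None,
    tables: dict[str, PrecursorTable] | None = None,
    comparison: tuple[frozenset[str], frozenset[str], frozenset[str]] | None = None,
    comparison_names: tuple[str, str] | None = None,
) -> list[Path]:
    """Emit the seed tables, the common/specific partition, the precursor
    matrices and a plain-text headline summary; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    classifications = classifications or {}
    tables = tables or {}
    written: list[Path] = []

    for org in sorted(seed_reports):
        path = outdir / f"seeds_{org}.tsv"
        seed_reports[org].to_tsv(path, classifications.get(org))
        written.append(path)

    if comparison is not None:
        name_a, name_b = comparison_names or ("A", "B")
        common, only_a, only_b = comparison
        path = outdir / "seed_comparison.tsv"
        with open(path, "w") as fh:
            fh.write("seed\tstatus\n")
            for s in sorted(common):
                fh.write(f"{s}\tcommon\n")
            for s in sorted(only_a):
                fh.write(f"{s}\tspecific_{name_a}\n")
            for s in sorted(only_b):
                fh.write(f"{s}\tspecific_{name_b}\n")
        written.append(path)

    for org in sorted(tables):
        path = outdir / f"precursors_{org}.tsv"
        tables[org].to_tsv(path, seed_reports[org].seeds if org in seed_reports else [])
        written.append(path)

    path = outdir / "summary.txt"
    with open(path, "w") as fh:
        for org in sorted(seed_reports):
            rep = seed_reports[org]
            fh.write(
                f"{org}: {len(rep.seeds)} seeds in "
                f"{len(rep.source_components)} source components "
                f"({len(rep.alternative_groups)} alternative groups)\n"
            )
            cls = classifications.get(org)
            if cls:
                fh.write(
                    f"{org}: {len(cls.partner_produced)} seeds producible "
                    "by the partner network\n"
                )
        if comparison is not None:
            common, only_a, only_b = comparison
            fh.write(
                f"seed overlap: {len(common)} common, "
                f"{len(only_a)} + {len(only_b)} specific\n"
            )
        for org in sorted(tables):
            table = tables[org]
            if table.rows:
                fh.write(
                    f"{org}: {len(table.rows)} targets, "
                    f"max solutions per target "
                    f"{max(r.n_solutions for r in table.rows)}, "
                    f"max precursors per target "
                    f"{max(r.n_precursors for r in table.rows)}\n"
                )
    written.append(path)
    return written
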