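"""Scope computation and exact enumeration of minimal precursor sets.

The *scope* of a metabolite set is everything the network can make from it:
the least fixpoint of the firing rule "a hyperarc fires once all of its
substrates are available, adding all of its products" (forward propagation /
network expansion). Plain scope is too strict in the presence of cycles: a
biosynthetic route may need to *borrow* an internal cycle metabolite that is
subsequently regenerated. Borrowing without regeneration, however, would use
the borrowed compound up and silently assume an infinite supply.

The resolution is the *self-generating set*: a set Z of non-seed metabolites
may be added to the initial set provided every member of Z is produced by
some hyperarc fired during the expansion — Z is regenerated, so only a
catalytic amount is ever borrowed. A subset P of the seeds is a *precursor
set* of a target t when some such Z makes t reachable in the expansion from
P ∪ Z; it is *minimal* when no strict subset of P has the property
(minimality is over P alone, not over (P, Z) pairs).

Valid self-generating sets are closed under union (scope is monotone in its
initial set), so a unique maximal valid Z* exists and t is reachable under
*some* valid Z iff it is reachable under Z*. The implementation computes Z*
as a greatest fixpoint, starting from all non-seed vertices and repeatedly
discarding members not regenerated in the current expansion. Correctness is
pinned by an exhaustive oracle that tries every Z subset on small instances.

Enumeration of all minimal precursor sets walks the subset lattice of the
candidate seeds in order of increasing cardinality, pruning supersets of
accepted sets (sound because the precursor property is closed under seed
supersets). Candidates are pre-filtered to compound-graph ancestors of the
target: a hyperarc producing an ancestor of t has all its substrates among
the ancestors of t, so no seed outside the ancestor cone can ever matter.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .graphs import Hyperarc, ReactionHypergraph

__all__ = [
    "ScopeResult",
    "PrecursorSolution",
    "PrecursorRow",
    "PrecursorTable",
    "BudgetExceededError",
    "scope",
    "maximal_self_generating_scope",
    "is_precursor_set",
    "enumerate_minimal_precursor_sets",
    "brute_force_minimal_precursor_sets",
    "precursor_table",
]


class BudgetExceededError(RuntimeError):
    """Raised when an enumeration exceeds its configured node budget."""


@dataclass(frozen=True)
class ScopeResult:
    """Result of one forward propagation: what was reached, and how."""

    initial: frozenset[str]
    reached: frozenset[str]
    fired: tuple[str, ...]


@dataclass(frozen=True)
class PrecursorSolution:
    """One certified precursor set for one target.

    ``precursors`` is the seed subset P; ``self_generating`` the witness set
    Z of borrowed-and-regenerated metabolites (disjoint from P, every member
    a product of a fired hyperarc); ``fired`` the hyperarc ids of the
    certifying expansion from P ∪ Z.
    """

    target: str
    precursors: frozenset[str]
    self_generating: frozenset[str]
    fired: tuple[str, ...]


def _solution_sort_key(sol: PrecursorSolution) -> tuple:
    return (len(sol.precursors), sorted(sol.precursors))


@dataclass
class PrecursorRow:
    """All minimal precursor sets of one target (an antichain)."""

    target: str
    solutions: list[PrecursorSolution] = field(default_factory=list)

    @property
    def n_solutions(self) -> int:
        """The S column: number of alternative minimal precursor sets."""
        return len(self.solutions)

    @property
    def n_precursors(self) -> int:
        """The P column: size of the union of precursors across solutions."""
        return len(self.precursor_union)

    @property
    def precursor_union(self) -> frozenset[str]:
        out: set[str] = set()
        for sol in self.solutions:
            out |= sol.precursors
        return frozenset(out)


@dataclass
class PrecursorTable:
    """Targets x seeds summary: one row per (singleton) target."""

    rows: list[PrecursorRow] = field(default_factory=list)

    def to_tsv(self, path: str | Path, seeds: Iterable[str]) -> None:
        """Presence/absence matrix with S and P columns, one row per target."""
        seed_order = sorted(seeds)
        with open(path, "w") as fh:
            fh.write("target\t" + "\t".join(seed_order) + "\tP\tS\n")
            for row in self.rows:
                used = row.precursor_union
                cells = ["X" if s in used else "." for s in seed_order]
                fh.write(
                    f"{row.target}\t" + "\t".join(cells)
                    + f"\t{row.n_precursors}\t{row.n_solutions}\n"
                )

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "target": row.target,
                "n_solutions": row.n_solutions,
                "n_precursors": row.n_precursors,
                "solutions": [
                    {
                        "precursors": sorted(sol.precursors),
                        "self_generating": sorted(sol.self_generating),
                        "fired": list(sol.fired),
                    }
                    for sol in row.solutions
                ],
            }
            for row in self.rows
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Scope


def _check_known(hg: ReactionHypergraph, ids: Iterable[str], what: str) -> None:
    unknown = sorted(set(ids) - hg.vertices)
    if unknown:
        raise KeyError(f"unknown {what} metabolite(s): {', '.join(unknown)}")


def scope(hg: ReactionHypergraph, initial: Iterable[str]) -> ScopeResult:
    """Least fixpoint of the all-substrates firing rule (network expansion).

    Pure and deterministic: hyperarcs are scanned in their list order, round
    after round, each firing at most once; the fired order records the scan.
    """
    initial = frozenset(initial)
    _check_known(hg, initial, "initial")
    reached: set[str] = set(initial)
    fired: list[str] = []
    fired_set: set[str] = set()
    changed = True
    while changed:
        changed = False
        for h in hg.hyperarcs:
            if h.id in fired_set:
                continue
            if h.substrates <= reached:
                fired.append(h.id)
                fired_set.add(h.id)
                if not h.products <= reached:
                    reached |= h.products
                    changed = True
    return ScopeResult(initial=initial, reached=frozenset(reached), fired=tuple(fired))


def maximal_self_generating_scope(
    hg: ReactionHypergraph,
    precursors: Iterable[str],
    exclude: Iterable[str] = (),
) -> tuple[ScopeResult, frozenset[str]]:
    """Expansion from P allowing the largest regenerated borrow set Z*.

    Greatest-fixpoint iteration: start from Z = vertices \\ (P ∪ exclude)
    and repeatedly keep only the members of Z that are a product of a
    hyperarc fired in scope(P ∪ Z). At the fixpoint every member of Z* is
    regenerated in the returned expansion, and Z* contains every valid
    self-generating set drawn from the same pool, so target reachability
    under Z* decides the precursor-set question.

    ``exclude`` removes metabolites from the borrowable pool. Precursor-set
    testing passes the declared seed set here: a seed held in infinite
    supply is by definition a seed, not a self-generating cycle metabolite,
    and without the exclusion any pair of seeds interconverted by a
    reversible reaction would count as mutually "regenerated" and could be
    borrowed for free, which is exactly the used-up-unless-in-infinite-
    supply situation the regeneration constraint exists to forbid.
    """
    p = frozenset(precursors)
    _check_known(hg, p, "precursor")
    arcs = hg.arc_by_id()
    z = frozenset(hg.vertices) - p - frozenset(exclude)
    while True:
        res = scope(hg, p | z)
        regenerated: set[str] = set()
        for hid in res.fired:
            regenerated |= arcs[hid].products
        z_next = z & regenerated
        if z_next == z:
            return res, z
        z = z_next


def is_precursor_set(
    hg: ReactionHypergraph,
    precursors: Iterable[str],
    target: str,
    seeds: Iterable[str] | None = None,
) -> tuple[bool, PrecursorSolution | None]:
    """Decide whether P is a precursor set of the target; certify if so.

    If the target is plainly reachable the witness uses Z = ∅ (no borrowing
    needed); otherwise the maximal self-generating fixpoint is consulted and
    reported as found, without minimisation. When the declared seed set is
    supplied, seeds outside P are excluded from the borrowable pool (see
    :func:`maximal_self_generating_scope`).
    """
    p = frozenset(precursors)
    _check_known(hg, [target], "target")
    plain = scope(hg, p)
    if target in plain.reached:
        return True, PrecursorSolution(
            target=target, precursors=p, self_generating=frozenset(), fired=plain.fired
        )
    res, z = maximal_self_generating_scope(
        hg, p, exclude=frozenset(seeds) if seeds is not None else frozenset()
    )
    if target in res.reached:
        return True, PrecursorSolution(
            target=target, precursors=p, self_generating=z, fired=res.fired
        )
    return False, None


# ---------------------------------------------------------------------------
# Enumeration


def _ancestors_of(hg: ReactionHypergraph, target: str) -> frozenset[str]:
    """Compound-graph ancestors of the target (including the target)."""
    feeds: dict[str, set[str]] = {}
    for h in hg.hyperarcs:
        for prod in h.products:
            feeds.setdefault(prod, set()).update(h.substrates)
    anc: set[str] = {target}
    stack = [target]
    while stack:
        node = stack.pop()
        for sub in feeds.get(node, ()):
            if sub not in anc:
                anc.add(sub)
                stack.append(sub)
    return frozenset(anc)


def enumerate_minimal_precursor_sets(
    hg: ReactionHypergraph,
    seeds: Iterable[str],
    target: str,
    budget: int | None = None,
) -> PrecursorRow:
    """All inclusion-minimal precursor sets of one target, exactly.

    Sound (every returned set is re-certified), complete (breadth-first over
    the candidate subset lattice with superset pruning misses nothing, by
    superset closure of the precursor property) and antichain by
    construction. Output is canonically ordered (size, then lexicographic).

    ``budget`` caps the number of candidate sets tested; exceeding it raises
    :class:`BudgetExceededError` rather than silently truncating. An
    unreachable target yields an empty row, not an error.
    """
    seeds = frozenset(seeds)
    _check_known(hg, seeds, "seed")
    _check_known(hg, [target], "target")
    candidates = sorted(seeds & _ancestors_of(hg, target))
    minimal: list[PrecursorSolution] = []
    tested = 0
    for k in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, k):
            p = frozenset(combo)
            if any(sol.precursors <= p for sol in minimal):
                continue
            if budget is not None and tested >= budget:
                raise BudgetExceededError(
                    f"target {target}: enumeration budget of {budget} "
                    f"candidate sets exhausted (incomplete)"
                )
            tested += 1
            ok, witness = is_precursor_set(hg, p, target, seeds=seeds)
            if ok:
                assert witness is not None
                minimal.append(witness)
    minimal.sort(key=_solution_sort_key)
    return PrecursorRow(target=target, solutions=minimal)


def brute_force_minimal_precursor_sets(
    hg: ReactionHypergraph, seeds: Iterable[str], target: str
) -> PrecursorRow:
    """Definition-level oracle: exhaust every (P, Z) pair on small instances.

    Accepts P iff some Z drawn from the non-seed vertices is fully
    regenerated in the expansion from P ∪ Z with the target reached, then
    keeps the inclusion-minimal accepted sets. Z candidates are further
    restricted to metabolites that are a product of at least one hyperarc
    (others can never satisfy regeneration), and scope results are memoised
    per initial set; neither changes the accepted collection. Guarded to
    |seeds| <= 15 and |vertices| <= 20.
    """
    seeds = frozenset(seeds)
    _check_known(hg, seeds, "seed")
    _check_known(hg, [target], "target")
    if len(seeds) > 15 or len(hg.vertices) > 20:
        raise ValueError(
            f"instance too large for the exhaustive oracle: "
            f"{len(seeds)} seeds, {len(hg.vertices)} vertices "
            "(guard: <= 15 seeds, <= 20 vertices)"
        )
    arcs = hg.arc_by_id()
    producible = hg.producible()
    cache: dict[frozenset[str], tuple[frozenset[str], frozenset[str]]] = {}

    def expand(initial: frozenset[str]) -> tuple[frozenset[str], frozenset[str]]:
        if initial not in cache:
            res = scope(hg, initial)
            regen: set[str] = set()
            for hid in res.fired:
                regen |= arcs[hid].products
            cache[initial] = (res.reached, frozenset(regen))
        return cache[initial]

    seed_list = sorted(seeds)
    accepted: list[frozenset[str]] = []
    for k in range(len(seed_list) + 1):
        for combo in itertools.combinations(seed_list, k):
            p = frozenset(combo)
            zpool = sorted(producible - seeds)
            # plain scope is monotone in its initial set, so if the target is
            # unreachable even with every candidate z available it is
            # unreachable for every Z subset (regeneration aside)
            reached_all, _ = expand(p | frozenset(zpool))
            if target not in reached_all:
                continue
            ok = False
            for zsize in range(len(zpool) + 1):
                for zc in itertools.combinations(zpool, zsize):
                    z = frozenset(zc)
                    reached, regen = expand(p | z)
                    if target in reached and z <= regen:
                        ok = True
                        break
                if ok:
                    break
            if ok:
                accepted.append(p)
    minimal_sets = [
        p for p in accepted if not any(q < p for q in accepted)
    ]
    solutions = []
    for p in minimal_sets:
        ok, witness = is_precursor_set(hg, p, target, seeds=seeds)
        assert ok and witness is not None  # accepted by definition above
        solutions.append(witness)
    solutions.sort(key=_solution_sort_key)
    return PrecursorRow(target=target, solutions=solutions)


def precursor_table(
    hg: ReactionHypergraph,
    seeds: Iterable[str],
    targets: Sequence[str],
    budget: int | None = None,
) -> PrecursorTable:
    """One row of minimal precursor sets per (singleton) target."""
    seeds = frozenset(seeds)
    return PrecursorTable(
        rows=[
            enumerate_minimal_precursor_sets(hg, seeds, t, budget=budget)
            for t in targets
        ]
    )
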