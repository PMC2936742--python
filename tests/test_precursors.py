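"""Scope, self-generation and minimal precursor set enumeration.

The exhaustive oracles here are deliberately definition-shaped (subset
enumeration, repeated random firing) and independent of the production
algorithms they check.
"""

import itertools
import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedscope.graphs import build_compound_graph, build_hypergraph
from seedscope.precursors import (
    BudgetExceededError,
    brute_force_minimal_precursor_sets,
    enumerate_minimal_precursor_sets,
    is_precursor_set,
    maximal_self_generating_scope,
    precursor_table,
    scope,
)
from seedscope.seeds import identify_seeds
from seedscope.synthetic_data import GeneratorSpec, random_network

from conftest import iter_guarded_instances


def _random_order_scope(hg, initial, rng):
    """Oracle: repeatedly try hyperarcs in random order until stable."""
    reached = set(initial)
    arcs = list(hg.hyperarcs)
    changed = True
    while changed:
        changed = False
        rng.shuffle(arcs)
        for h in arcs:
            if h.substrates <= reached and not h.products <= reached:
                reached |= h.products
                changed = True
    return frozenset(reached)


# ---------------------------------------------------------------------------
# scope


def test_scope_of_empty_set_is_empty(cycle_motif):
    net, _ = cycle_motif
    hg = build_hypergraph(net)
    res = scope(hg, frozenset())
    assert res.reached == frozenset() and res.fired == ()


def test_scope_rejects_unknown_metabolites(cycle_motif):
    net, _ = cycle_motif
    hg = build_hypergraph(net)
    with pytest.raises(KeyError, match="ghost"):
        scope(hg, {"s1", "ghost"})


def test_scope_result_invariants_hold(cycle_motif):
    net, _ = cycle_motif
    hg = build_hypergraph(net)
    arcs = hg.arc_by_id()
    res = scope(hg, {"s1", "s2", "c1"})
    assert res.initial <= res.reached
    produced = set()
    for hid in res.fired:
        assert arcs[hid].substrates <= res.reached
        produced |= arcs[hid].products
    assert res.reached - res.initial <= produced


@pytest.mark.parametrize("seed", range(20))
def test_scope_is_order_independent(seed):
    """Deterministic scan order agrees with many random firing orders."""
    net, _ = random_network(
        GeneratorSpec(n_metabolites=10, n_reactions=10, seed=seed,
                      frac_reversible=0.3, n_planted_cycles=seed % 2)
    )
    hg = build_hypergraph(net)
    rng = random.Random(seed)
    initial = frozenset(
        rng.sample(sorted(hg.vertices), k=min(3, len(hg.vertices)))
    )
    expected = scope(hg, initial).reached
    for _ in range(5):
        assert _random_order_scope(hg, initial, rng) == expected


@pytest.mark.parametrize("seed", range(100))
def test_scope_monotonicity_and_idempotence(seed):
    net, _ = random_network(
        GeneratorSpec(n_metabolites=10, n_reactions=9, seed=seed,
                      frac_reversible=0.25, n_planted_cycles=seed % 3 == 0)
    )
    hg = build_hypergraph(net)
    rng = random.Random(seed)
    verts = sorted(hg.vertices)
    small = frozenset(rng.sample(verts, k=min(2, len(verts))))
    big = small | frozenset(rng.sample(verts, k=min(3, len(verts))))
    r_small, r_big = scope(hg, small).reached, scope(hg, big).reached
    assert r_small <= r_big  # monotone in the initial set
    assert scope(hg, r_small).reached == r_small  # idempotent


_met_ids = st.sampled_from([f"v{i}" for i in range(8)])
_met_sets = st.frozensets(_met_ids, min_size=1, max_size=3)


@st.composite
def _tiny_hypergraphs(draw):
    from seedscope.graphs import Hyperarc, ReactionHypergraph

    n_arcs = draw(st.integers(1, 8))
    arcs = []
    for i in range(n_arcs):
        subs = draw(_met_sets)
        prods = draw(_met_sets)
        arcs.append(Hyperarc(f"H{i}", subs, prods, f"H{i}", "forward"))
    verts = set().union(*(h.substrates | h.products for h in arcs))
    return ReactionHypergraph(vertices=verts, hyperarcs=arcs)


@settings(max_examples=150, derandomize=True)
@given(hg=_tiny_hypergraphs(), extra=st.frozensets(_met_ids, max_size=4))
def test_scope_laws_on_arbitrary_hypergraphs(hg, extra):
    """Monotonicity, idempotence and initial-set containment hold for any
    hyperarc wiring, not just generator output."""
    verts = sorted(hg.vertices)
    small = frozenset(verts[: len(verts) // 2])
    big = small | (frozenset(extra) & hg.vertices)
    r_small = scope(hg, small).reached
    r_big = scope(hg, big).reached
    assert small <= r_small
    assert r_small <= r_big
    assert scope(hg, r_small).reached == r_small


# ---------------------------------------------------------------------------
# self-generation


def test_cycle_motif_scope_vs_self_generating_scope(cycle_motif):
    net, _ = cycle_motif
    hg = build_hypergraph(net)
    assert "t" not in scope(hg, {"s1", "s2"}).reached
    res, z = maximal_self_generating_scope(hg, {"s1", "s2"})
    assert "t" in res.reached and "c1" in z


def test_self_generation_adds_nothing_without_cycles():
    net, _ = random_network(
        GeneratorSpec(n_metabolites=9, n_reactions=8, seed=3, frac_reversible=0.0)
    )
    hg = build_hypergraph(net)
    g = nx.DiGraph(
        (a, b) for h in hg.hyperarcs for a in h.substrates for b in h.products
    )
    assert nx.is_directed_acyclic_graph(g)
    seeds = identify_seeds(net).seeds
    res, _ = maximal_self_generating_scope(hg, seeds, exclude=seeds)
    assert res.reached == scope(hg, seeds).reached


@pytest.mark.parametrize("seed", range(30))
def test_self_generating_reachability_matches_exhaustive_z_search(seed):
    """t reachable under the maximal fixpoint iff some regenerated Z works."""
    net, _ = random_network(
        GeneratorSpec(n_metabolites=6, n_reactions=6, seed=seed,
                      frac_reversible=0.3, n_planted_cycles=seed % 2)
    )
    hg = build_hypergraph(net)
    arcs = hg.arc_by_id()
    rng = random.Random(seed)
    verts = sorted(hg.vertices)
    p = frozenset(rng.sample(verts, k=min(2, len(verts))))
    pool = sorted(set(verts) - p)
    res, zstar = maximal_self_generating_scope(hg, p)
    for target in verts:
        exists = False
        for k in range(len(pool) + 1):
            for combo in itertools.combinations(pool, k):
                z = frozenset(combo)
                r = scope(hg, p | z)
                regen = set()
                for hid in r.fired:
                    regen |= arcs[hid].products
                if target in r.reached and z <= regen:
                    exists = True
                    break
            if exists:
                break
        assert exists == (target in res.reached), (seed, target)


def test_witness_invariants_reverified_independently(cycle_motif):
    net, _ = cycle_motif
    hg = build_hypergraph(net)
    arcs = hg.arc_by_id()
    ok, wit = is_precursor_set(hg, {"s1", "s2"}, "t", seeds={"s1", "s2"})
    assert ok
    assert wit.self_generating.isdisjoint(wit.precursors)
    replay = set(wit.precursors) | set(wit.self_generating)
    regen = set()
    for hid in wit.fired:
        assert arcs[hid].substrates <= replay
        replay |= arcs[hid].products
        regen |= arcs[hid].products
    assert wit.target in replay
    assert wit.self_generating <= regen  # every borrow is repaid


def test_target_in_precursor_set_is_trivially_true(cycle_motif):
    net, _ = cycle_motif
    hg = build_hypergraph(net)
    ok, wit = is_precursor_set(hg, {"t"}, "t")
    assert ok and wit.self_generating == frozenset()


def test_consumed_but_never_regenerated_borrow_is_rejected(cycle_motif):
    """Without the regeneration loop, borrowing does not certify a precursor
    set: the borrowed compound would be used up."""
    net, _ = cycle_motif
    net.reactions = [r for r in net.reactions if r.id not in {"R2", "R4"}]
    hg = build_hypergraph(net)
    ok, _ = is_precursor_set(hg, {"s1", "s2"}, "t", seeds={"s1", "s2"})
    assert not ok


def test_cycle_motif_precursor_answers(cycle_motif):
    net, _ = cycle_motif
    hg = build_hypergraph(net)
    assert is_precursor_set(hg, {"s1", "s2"}, "t", seeds={"s1", "s2"})[0]
    assert not is_precursor_set(hg, {"s1"}, "t", seeds={"s1", "s2"})[0]


# ---------------------------------------------------------------------------
# enumeration


def test_cycle_motif_unique_minimal_precursor_set(cycle_motif):
    net, truth = cycle_motif
    hg = build_hypergraph(net)
    row = enumerate_minimal_precursor_sets(hg, identify_seeds(net).seeds, "t")
    assert [s.precursors for s in row.solutions] == truth.targets["t"]


def test_pair_motif_alternative_singleton_solutions(pair_motif):
    net, truth = pair_motif
    hg = build_hypergraph(net)
    row = enumerate_minimal_precursor_sets(hg, identify_seeds(net).seeds, "t")
    assert sorted((s.precursors for s in row.solutions), key=sorted) == sorted(
        truth.targets["t"], key=sorted
    )


def test_unreachable_target_gives_empty_row_not_error():
    from seedscope.network_model import MetabolicNetwork, Metabolite, Reaction

    net = MetabolicNetwork(
        metabolites={m: Metabolite(m) for m in ("a", "b", "c")},
        reactions=[Reaction("R", {"a": 1.0}, {"b": 1.0})],
    )
    hg = build_hypergraph(net)
    row = enumerate_minimal_precursor_sets(hg, {"a"}, "c")
    assert row.solutions == [] and row.n_solutions == 0


def test_solutions_form_an_antichain_with_canonical_order(symbiosis_fixture):
    net_a, _, _ = symbiosis_fixture
    hg = build_hypergraph(net_a)
    seeds = identify_seeds(net_a).seeds
    row = enumerate_minimal_precursor_sets(hg, seeds, "lys")
    sols = [s.precursors for s in row.solutions]
    for p, q in itertools.permutations(sols, 2):
        assert not p < q
    assert sols == sorted(sols, key=lambda s: (len(s), sorted(s)))


def test_superset_closure_of_the_precursor_property():
    for hg, seeds, target in iter_guarded_instances(15, start_seed=300):
        for k in range(len(seeds) + 1):
            for combo in itertools.combinations(sorted(seeds), k):
                p = frozenset(combo)
                if is_precursor_set(hg, p, target, seeds=seeds)[0]:
                    for extra in sorted(seeds - p):
                        assert is_precursor_set(
                            hg, p | {extra}, target, seeds=seeds
                        )[0]


def test_enumeration_budget_aborts_loudly(symbiosis_fixture):
    net_a, _, _ = symbiosis_fixture
    hg = build_hypergraph(net_a)
    seeds = identify_seeds(net_a).seeds
    with pytest.raises(BudgetExceededError, match="incomplete"):
        enumerate_minimal_precursor_sets(hg, seeds, "lys", budget=1)


def test_oracle_guard_rejects_large_instances():
    net, _ = random_network(GeneratorSpec(n_metabolites=30, n_reactions=10, seed=1))
    hg = build_hypergraph(net)
    verts = sorted(hg.vertices)
    with pytest.raises(ValueError, match="guard"):
        brute_force_minimal_precursor_sets(hg, verts[:3], verts[-1])


@pytest.mark.parametrize("start", [1, 101])
def test_enumeration_matches_exhaustive_oracle(start):
    """Exact set-of-sets agreement on guarded random instances."""
    for hg, seeds, target in iter_guarded_instances(30, start_seed=start):
        fast = enumerate_minimal_precursor_sets(hg, seeds, target)
        slow = brute_force_minimal_precursor_sets(hg, seeds, target)
        assert {s.precursors for s in fast.solutions} == {
            s.precursors for s in slow.solutions
        }


def test_acyclic_instances_need_no_borrowing():
    """Without directed cycles, solutions equal plain-scope reachability."""
    checked = 0
    seed = 0
    while checked < 25:
        seed += 1
        net, _ = random_network(
            GeneratorSpec(n_metabolites=9, n_reactions=8, seed=seed,
                          frac_reversible=0.0)
        )
        hg = build_hypergraph(net)
        g = nx.DiGraph(
            (a, b) for h in hg.hyperarcs for a in h.substrates for b in h.products
        )
        if not nx.is_directed_acyclic_graph(g):
            continue
        seeds = identify_seeds(net).seeds
        targets = sorted(hg.vertices - seeds)
        if not targets or len(seeds) > 6:
            continue
        checked += 1
        target = targets[seed % len(targets)]
        row = enumerate_minimal_precursor_sets(hg, seeds, target)
        assert all(s.self_generating == frozenset() for s in row.solutions)
        # plain reachability oracle over the seed subsets
        plain = []
        for k in range(len(seeds) + 1):
            for combo in itertools.combinations(sorted(seeds), k):
                p = frozenset(combo)
                if any(q <= p for q in plain):
                    continue
                if target in scope(hg, p).reached:
                    plain.append(p)
        assert {s.precursors for s in row.solutions} == set(plain)


def test_precursor_table_s_and_p_columns(symbiosis_fixture):
    net_a, _, truth = symbiosis_fixture
    hg = build_hypergraph(net_a)
    seeds = identify_seeds(net_a).seeds
    table = precursor_table(hg, seeds, ["lys", "trp", "ser"])
    by_target = {row.target: row for row in table.rows}
    assert by_target["lys"].n_solutions == 2
    assert by_target["lys"].n_precursors == 3  # pep + {asp or oxa}
    assert by_target["trp"].n_solutions == 1
    assert by_target["trp"].n_precursors == 3
    assert by_target["ser"].n_solutions == 1  # a seed is its own precursor
    assert [s.precursors for s in by_target["ser"].solutions] == [frozenset({"ser"})]
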