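"""Shared fixtures: motif networks and guarded random instances."""

from __future__ import annotations

import pytest

from seedscope.graphs import ReactionHypergraph, build_hypergraph
from seedscope.seeds import identify_seeds
from seedscope.synthetic_data import (
    GeneratorSpec,
    make_cycle_motif,
    make_reversible_pair_motif,
    make_symbiosis_fixture,
    make_triple_motif,
    random_network,
)


@pytest.fixture
def cycle_motif():
    return make_cycle_motif()


@pytest.fixture
def pair_motif():
    return make_reversible_pair_motif()


@pytest.fixture
def triple_motif():
    return make_triple_motif()


@pytest.fixture
def symbiosis_fixture():
    return make_symbiosis_fixture()


def sample_guarded_instance(seed: int):
    """One random instance inside the exhaustive-oracle guard, or None.

    Alternates plain random networks (10 metabolites) with cycle-planted
    ones (6 random + 6 template metabolites = 12 total); rejects draws that
    exceed 12 metabolites, 14 hyperarcs or 6 identified seeds, or that have
    no non-seed target.
    """
    if seed % 2:
        spec = GeneratorSpec(
            n_metabolites=6, n_reactions=5, frac_reversible=0.2,
            frac_nutrients=0.3, n_planted_cycles=1, seed=seed,
        )
    else:
        spec = GeneratorSpec(
            n_metabolites=10, n_reactions=9, frac_reversible=0.25,
            frac_nutrients=0.3, n_planted_cycles=0, seed=seed,
        )
    net, _ = random_network(spec)
    hg = build_hypergraph(net)
    if len(hg.vertices) > 12 or len(hg.hyperarcs) > 14:
        return None
    seeds = identify_seeds(net).seeds
    if len(seeds) > 6:
        return None
    targets = sorted(hg.vertices - seeds)
    if not targets:
        return None
    target = targets[seed % len(targets)]
    return hg, seeds, target


def iter_guarded_instances(n: int, start_seed: int = 1):
    """Yield exactly n guarded instances, skipping rejected draws."""
    produced = 0
    seed = start_seed
    while produced < n:
        inst = sample_guarded_instance(seed)
        seed += 1
        if inst is not None:
            produced += 1
            yield inst
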