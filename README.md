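# seedscope

Graph-based analysis of metabolic exchange in multi-organism systems:
carbon-core filtering of metabolic networks, seed identification by
strongly-connected-component condensation, cross-network seed
classification, and exact enumeration of all minimal precursor sets of
target metabolites with explicit handling of cycles.

## The problem

Obligate endosymbioses — for example two bacteria co-resident inside the
cells of an insect host — run on metabolite exchange: each partner imports
compounds it cannot make and exports compounds the others need. Given the
reconstructed metabolic network of each organism, two questions define the
exchange topology:

1. **Which metabolites must each network import?** A *seed* is a compound a
   network cannot synthesise from other compounds of the network. The naive
   definition ("consumed but never produced") fails on reversible reactions,
   so seeds are computed on the directed *compound graph* (an arc whenever a
   reaction produces one compound from another): condense the graph by
   strongly connected components and take every member of a *source
   component* — an SCC with no incoming arc from outside itself. A
   multi-member source component is a group of *alternative seeds*: any of
   its members could be the compound actually imported.

2. **Which seed subsets suffice to build a given target?** On the reaction
   *hypergraph* (each reaction orientation consumes its full substrate set
   and yields its full product set), the *scope* of a set S is the least
   fixpoint of firing every reaction whose substrates are all available —
   everything producible from S. A subset P of the seeds is a *precursor
   set* of target t when t lies in the scope of P ∪ Z for some set Z of
   internal metabolites that are all **regenerated** (each is a product of a
   fired reaction) during that expansion — Z models cycle metabolites that
   may be borrowed in catalytic amounts but must be repaid. P is *minimal*
   when no strict subset works. The package enumerates **all** minimal
   precursor sets per target, exactly, and verifies itself against an
   exhaustive subset-lattice oracle on small instances.

Comparing seed sets across organisms (who can produce whose seeds?) then
separates compounds cross-fed between partners from compounds that must
come from the host or its diet.

## Worked example

The canonical cycle fixture has six metabolites and four reactions:
`R1: s1 + c1 -> c2 + i`, `R2: c2 -> c1`, `R3: i + s2 -> t`,
`R4: i -> c2`. Nothing produces `s1` or `s2`, so they are the seeds — and
the plain scope of the seeds is stuck, because `R1` also needs the cycle
metabolite `c1`:

```python
from seedscope import *
from seedscope.synthetic_data import make_cycle_motif

net, _ = make_cycle_motif()
rep = identify_seeds(net)
hg = build_hypergraph(net)
print("seeds:", sorted(rep.seeds))
print("plain scope:", sorted(scope(hg, rep.seeds).reached))
res, z = maximal_self_generating_scope(hg, rep.seeds, exclude=rep.seeds)
print("self-generating scope:", sorted(res.reached))
print("borrowed and regenerated:", sorted(z))
row = enumerate_minimal_precursor_sets(hg, rep.seeds, "t")
for s in row.solutions:
    print("minimal precursor set:", sorted(s.precursors),
          "| Z =", sorted(s.self_generating))
```

prints

```
seeds: ['s1', 's2']
plain scope: ['s1', 's2']
self-generating scope: ['c1', 'c2', 'i', 's1', 's2', 't']
borrowed and regenerated: ['c1', 'c2', 'i', 't']
minimal precursor set: ['s1', 's2'] | Z = ['c1', 'c2', 'i', 't']
```

Borrowing `c1` unlocks `R1`; the expansion then regenerates `c1` through
`R4` and `R2`, so the borrow is legitimate and `{s1, s2}` is certified as
the unique minimal precursor set of `t`. Without the regeneration reactions
the same borrow would be rejected — the cycle metabolite would be used up.

## Command line

The `seedscope` console script ties the stages into a pipeline:

```bash
seedscope simulate --kind symbiosis --out fixtures/
seedscope filter --network fixtures/network_A.sbml --out filtered/
seedscope seeds --network a.sbml --network b.sbml --name A --name B --out seeds/
seedscope precursors --network a.sbml --targets-file targets.txt \
    --export-subnetworks SIF --out precursors/
seedscope report --config pipeline.yaml
```

`filter` removes side-compound (currency) pairs per an editable rule table,
drops nine inorganic compounds, and eliminates reactions left without a
carbon transfer, writing a complete removal log. `seeds` emits per-organism
seed tables and, in two-organism mode, the common/specific partition and
partner-producibility flags. `precursors` writes the targets × seeds matrix
(with P = total precursors and S = number of alternative solutions per
target) plus certificate sub-networks in SIF/GraphML for network viewers.
Exit codes: 0 success, 2 validation failure, 3 enumeration budget exceeded.

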