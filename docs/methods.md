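# Methods

## Data model and I/O

A metabolic network is a map of metabolites plus an ordered list of
directed, possibly reversible reactions; each reaction side maps metabolite
id to a positive stoichiometric coefficient. Networks are exchanged as SBML
(Level 2 or 3, single model; written as Level 3 Version 1). Species ids are
taken as-is and are the only identity of a metabolite — display names are
cosmetic. Compartments are ignored: all species form one pool, which is
adequate for single-compartment bacterial small-molecule metabolism and
keeps ids stable across files. Omitted stoichiometry defaults to 1;
duplicate reaction ids and references to undeclared species are hard
errors, not silent fixes. SBML kinetic laws, rules, events and the fbc
extension are out of scope.

Construction permits a reaction with an empty side (this state arises
transiently between filtering passes) but `validate` reports it as a
violation, and the hypergraph builder refuses such reactions outright.

## Carbon-core filtering

Raw reaction lists are dominated by currency metabolites whose ubiquity
creates paths that carry no carbon. Filtering runs in a fixed, logged
order:

1. **Side-compound rules.** Each rule is a cofactor transformation with a
   trigger pair (e.g. ATP on one side, ADP on the other) and removal sets
   that may include subproducts (e.g. diphosphate released by an ATP→AMP
   step). A rule fires only when *all* trigger metabolites of each side are
   present, in either reaction orientation; matched occurrences are deleted
   per reaction. Matching runs against the already-edited sides, which
   makes the pass idempotent. The shipped 24-rule table is a starter
   configuration in a MetaCyc-style id namespace and is explicitly the
   source of truth — users analysing networks in another namespace must
   adapt it.
2. **Inorganic removal.** Every occurrence of nine carbon-free compounds
   (water, proton, phosphate, diphosphate, ammonia, hydrogen peroxide,
   sulfite, sulfate, oxygen) is deleted. Bicarbonate is deliberately not on
   the list: it carries carbon and can legitimately be a seed.
3. **Manual overrides** (optional): explicit per-reaction occurrence or
   reaction removals from configuration, applied last, with unknown ids
   treated as errors so the audit trail stays complete.
4. **Carbonless-reaction drop.** A reaction whose side was emptied no
   longer transfers carbon between organic compounds and is removed
   (reason code `NC`).

Every removal is one log entry (`reaction` or `metabolite-occurrence`
kind), so occurrences-removed + occurrences-kept equals the original count
for each pass. Metabolites orphaned by a pass (left in no reaction) are
dropped from the map: keeping them would create isolated compound-graph
nodes that masquerade as seeds. "Carbon transfer" is operationalised
entirely by the rule table plus the inorganic list; there is no
atom-mapping chemistry.

`detect_disconnected_reactions` flags reactions all of whose substrates are
produced by no other reaction and all of whose products are consumed by no
other reaction (both orientations considered for reversible partners). It
is advisory only: an apparent disconnection may equally signal an
annotation hole, so removal is a curation decision, not an automatic one.

## Graph views

Seed detection uses the **compound graph**: an arc from every substrate to
every product of each reaction, both directions for reversible reactions,
isolated metabolites as isolated nodes. Reachability uses the **reaction
hypergraph**: one hyperarc per reaction orientation, consuming the full
substrate set and yielding the full product set. Stoichiometric
coefficients are discarded in both views — feasibility under stoichiometry
is a strictly finer question (flux-level pruning and production-rate
ranking are known extensions and are deliberately not implemented). A
metabolite appearing on both sides of a reaction yields a compound-graph
self-loop and belongs to both hyperarc sets; self-loops never count as
incoming arcs for source-component detection.

## Seeds

Seeds are the members of the source components of the compound graph's SCC
condensation. All members of a multi-member source component are reported
as seeds, with the group structure preserved (alternative seeds). Seed
detection runs on the compound graph, not the hypergraph, because strongly
connected components have no settled hypergraph definition. In the
cycle-free limit this degenerates to the naive in-degree-zero definition
(property-tested).

Classification of seeds against a partner network asks whether the seed is
a product of at least one hyperarc of the partner (both orientations
count); host/diet and transporter knowledge enter only through
user-supplied lists, and cross-network id reconciliation uses an explicit
synonym map — never fuzzy name matching, because a silent mismatch would
corrupt the common/specific partition.

## Scope, borrowing, and regeneration

`scope(H, S)` is the least fixpoint of "fire every hyperarc whose
substrates are all present; add its products". The implementation scans
hyperarcs in list order, round after round, each hyperarc firing at most
once; the result is order-independent (checked against randomised firing
orders) and the recorded fired sequence is deterministic.

Cycles require more: a route may need to borrow an internal cycle
metabolite that the expansion itself regenerates. A borrow set Z is *valid*
for precursor candidate P when every z ∈ Z is a product of some hyperarc
fired in `scope(P ∪ Z)` — mere presence of z in the initial set does not
count, otherwise the condition would be vacuous. Because scope is monotone
in its initial set, valid borrow sets are closed under union, so a unique
maximal valid Z\* exists; `maximal_self_generating_scope` computes it by
greatest-fixpoint iteration (start from the whole borrowable pool, discard
members not regenerated in the current expansion, repeat). The target is
reachable under *some* valid Z iff it is reachable under Z\* — this
equivalence, and hence the algorithm, is pinned by an exhaustive test that
tries every Z subset on small instances.

**The borrowable pool excludes the declared seeds.** Two seeds
interconverted by a reversible reaction are each a product of the other
orientation's hyperarc; if seeds were borrowable, every such pair would
count as mutually "regenerated" and could be had for free, collapsing
precisely the alternative-seed structure (an oxaloacetate/aspartate-type
pair) the analysis exists to expose. A compound available in unlimited
supply is by definition a seed, not a self-generating cycle metabolite.
The same logic applied to *non-seed* reversible pairs is a known semantics
boundary: a reversible two-cycle between two internal metabolites whose
producers are unreachable is accepted as mutually regenerated under this
purely topological reading, although a token-level (stoichiometric)
reading would reject it. Resolving that edge requires flux accounting,
which is out of scope; the acyclic-limit guarantees below are therefore
stated for cycle-free instances.

Witness solutions report Z as found (the maximal fixpoint) without
minimisation, except that a target plainly reachable from P alone is
certified with Z = ∅. Every emitted witness is re-verified independently
of the search path (substrate availability of each fired arc, regeneration
of each borrow).

## Enumeration of minimal precursor sets

Minimality is over P alone: P is minimal when no strict subset of P is a
precursor set (Z is existential, not part of the order). The precursor
property is closed under seed supersets (monotonicity of scope), which
justifies the strategy: candidates are first restricted to compound-graph
ancestors of the target — a hyperarc producing an ancestor of t has all
its substrates among the ancestors of t, so no other seed can matter —
then the candidate subset lattice is walked breadth-first by cardinality
with superset pruning. Every accepted set is re-certified; the result is
an antichain in canonical order (size, then lexicographic). An optional
budget caps the number of candidate sets tested and aborts with an
explicit "incomplete" error rather than truncating silently.

The exhaustive oracle (`brute_force_minimal_precursor_sets`) re-derives
the same answer definition-first: every P ⊆ seeds, every Z subset of the
non-seed vertices, accept on reach-plus-regeneration, keep the
inclusion-minimal accepted sets. It is guarded to ≤ 15 seeds and ≤ 20
vertices. Two performance devices — restricting Z candidates to
metabolites that are a product of some hyperarc (anything else can never
be regenerated) and memoising scope per initial set — do not change the
accepted collection. Enumeration and oracle agree exactly on hundreds of
seeded random instances; that equivalence is the package's central
correctness argument.

## Certificate sub-networks

Each solution's fired hyperarcs are pruned to a bipartite
metabolite/reaction sub-network by a fixpoint rule: keep an arc if it
produces the target, feeds a kept arc, or regenerates a borrowed
metabolite consumed by a kept arc. Regeneration machinery is retained even
though it lies on no simple path to the target — without it the
certificate is invalid. Fired dead-end branches are dropped. The exact
pruning rule is this package's declared convention. Exports (SIF, GraphML
with `kind` and `role` attributes) are serialised with fully sorted node
and edge order and are byte-deterministic.

## Synthetic data

The generator exists to exercise every structure the algorithms must
handle, at sizes where exhaustive verification is possible — it makes no
attempt to mimic genome-scale networks or real metabolite chemistry.

* **Cycle motif** (6 metabolites, 4 reactions): the canonical
  borrow-and-regenerate instance; the plain scope of the seeds excludes
  the target, the self-generating scope includes it, and {s1, s2} is the
  unique minimal precursor set. The wiring realises the stated semantics
  of the classic cycle-processing illustration without claiming to be any
  literal published figure.
* **Reversible pair / triple motifs**: 2- and 3-member source components
  from reversible interconversions, with downstream targets whose minimal
  precursor sets are the alternative singletons.
* **Random networks** (`GeneratorSpec`): defaults of 12 metabolites, 12
  reactions, side arities 1–2, 20% reversible, 25% nutrients — small
  enough for the exhaustive oracle, dense enough to exercise branching.
  Designated nutrients are never products and reactions consuming them are
  forced irreversible, so nutrients are seeds by construction. Random
  reactions respect a fixed topological order on metabolites (substrates
  strictly precede products), so directed cycles beyond reversible
  two-cycles come only from explicitly planted copies of the cycle-motif
  template (four reactions on six fresh metabolites each). A single
  integer seed drives all sampling; identical spec + seed reproduces the
  network down to the SBML bytes.
* **Symbiosis fixture**: two small networks with a planted seed overlap
  ({asp, ser}), planted cross-feeding (three seeds of A producible by B,
  one of B by A), and an alternative-pair target (lysine reachable from
  {asp, pep} or {oxa, pep}).

What passing tests on these fixtures does **not** show: behaviour on
genome-scale networks (hundreds of reactions — the algorithms are
exponential in the seed count in the worst case, mitigated by the ancestor
pre-filter and superset pruning), robustness to id-namespace mismatches in
the side-compound table, or stoichiometric feasibility of any enumerated
precursor set.

## Numerical and reproducibility choices

No floating-point tolerances are involved anywhere — all computations are
set- and graph-valued; stoichiometric coefficients are only validated
(> 0) and round-tripped. All output collections are canonically ordered
(components by size then members; solutions by size then lexicographic
ids; export nodes/edges fully sorted), making every report byte-stable.
Test and acceptance problem sizes (200 oracle instances within the ≤ 12
metabolite / ≤ 14 hyperarc / ≤ 6 seed guard; 100 instances for each
property check) were chosen so the exhaustive oracles stay exact while the
whole suite runs in a few seconds.

## Known limitations

* Purely topological: no stoichiometric pruning, flux balance or
  production-rate ranking of alternative precursor sets.
* Precursor sets only, not the hyperpaths between precursors and targets.
* The regeneration reading accepts mutually-regenerating internal
  reversible pairs (see above); a token-level refinement would need flux
  accounting.
* The side-compound table must match the network's id namespace; no
  automatic compound-name normalisation is attempted.
* Curation steps (direction assignment, fake-reaction removal, generic
  reaction splitting) are supported as explicit, logged inputs — the
  package records them, it does not re-derive them.
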