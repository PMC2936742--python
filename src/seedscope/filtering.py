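"""Reduce a metabolic network to its carbon-transfer core.

Metabolic graphs built from raw reaction lists are dominated by currency
metabolites (ATP/ADP, NAD(P)H, ...) whose ubiquity creates paths that do not
correspond to any transfer of carbon atoms. This module removes them with a
complete, machine-readable audit trail, in three fixed passes:

1. side-compound transformation rules (per-reaction removal of cofactor
   pairs and their subproducts),
2. removal of a small list of inorganic compounds (the default list carries
   no carbon; note bicarbonate is deliberately *not* on it),
3. elimination of reactions left with an empty side, which by construction
   no longer transfer carbon (reason code ``NC``).

"Carbon transfer" is operationalised purely through the rule table and the
inorganic list — there is no atom-mapping chemistry here. The shipped rule
table is an editable starter configuration: the canonical 24-transformation
table used for the original endosymbiont networks lives in that study's
supplementary material, so the config file is the source of truth and should
be adapted to the id namespace of the networks being analysed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .network_model import (
    MetabolicNetwork,
    NetworkValidationError,
    Reaction,
    RemovalLog,
)

__all__ = [
    "SideCompoundRule",
    "DEFAULT_INORGANIC_IDS",
    "load_rules",
    "default_rules",
    "apply_side_compound_rules",
    "remove_inorganics",
    "drop_carbonless_reactions",
    "detect_disconnected_reactions",
    "split_generic_reaction",
    "apply_manual_overrides",
    "filter_network",
]

#: The nine carbon-free compounds removed by default, in a MetaCyc-style id
#: namespace: water, proton, phosphate, diphosphate, ammonia, hydrogen
#: peroxide, sulfite, sulfate, oxygen. Bicarbonate is intentionally absent —
#: it carries a carbon atom and can legitimately be a seed.
DEFAULT_INORGANIC_IDS: frozenset[str] = frozenset(
    {
        "WATER",
        "PROTON",
        "Pi",
        "PPI",
        "AMMONIA",
        "HYDROGEN-PEROXIDE",
        "SO3",
        "SULFATE",
        "OXYGEN-MOLECULE",
    }
)


@dataclass(frozen=True)
class SideCompoundRule:
    """One cofactor transformation: trigger pair plus removable subproducts.

    If every ``trigger_left`` metabolite occurs on one side of a reaction and
    every ``trigger_right`` metabolite on the other side (either orientation),
    the ``removed_left`` / ``removed_right`` metabolites are deleted from
    their respective sides. Removed sets contain their triggers.
    """

    rule_id: str
    trigger_left: frozenset[str]
    trigger_right: frozenset[str]
    removed_left: frozenset[str]
    removed_right: frozenset[str]

    def __post_init__(self) -> None:
        if not self.trigger_left or not self.trigger_right:
            raise NetworkValidationError(
                f"rule {self.rule_id}: trigger sets must be nonempty"
            )
        if not self.trigger_left <= self.removed_left:
            raise NetworkValidationError(
                f"rule {self.rule_id}: removed_left must contain trigger_left"
            )
        if not self.trigger_right <= self.removed_right:
            raise NetworkValidationError(
                f"rule {self.rule_id}: removed_right must contain trigger_right"
            )


def _split_ids(cell: str) -> frozenset[str]:
    return frozenset(x.strip() for x in str(cell).split(";") if x.strip())


def _rule_from_record(rec: dict) -> SideCompoundRule:
    return SideCompoundRule(
        rule_id=str(rec["rule_id"]),
        trigger_left=_split_ids(rec["trigger_left"]),
        trigger_right=_split_ids(rec["trigger_right"]),
        removed_left=_split_ids(rec.get("removed_left") or rec["trigger_left"]),
        removed_right=_split_ids(rec.get("removed_right") or rec["trigger_right"]),
    )


def load_rules(path: str | Path) -> list[SideCompoundRule]:
    """Load side-compound rules from CSV or YAML.

    CSV columns: rule_id, trigger_left, trigger_right, removed_left,
    removed_right — id lists are semicolon-separated. YAML: a list of
    mappings with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            records = yaml.safe_load(fh) or []
        return [_rule_from_record(rec) for rec in records]
    with open(path, newline="") as fh:
        return [_rule_from_record(rec) for rec in csv.DictReader(fh)]


def default_rules() -> list[SideCompoundRule]:
    """The packaged starter rule table (see module docstring for caveats)."""
    ref = resources.files("seedscope.data") / "side_compound_rules.csv"
    with resources.as_file(ref) as path:
        return load_rules(path)


def _drop_orphans(network: MetabolicNetwork, touched: set[str]) -> None:
    """Drop touched metabolites that no longer occur in any reaction."""
    in_use = network.metabolites_in_use()
    for mid in sorted(touched):
        if mid not in in_use and mid in network.metabolites:
            del network.metabolites[mid]


def apply_side_compound_rules(
    network: MetabolicNetwork, rules: Sequence[SideCompoundRule]
) -> tuple[MetabolicNetwork, RemovalLog]:
    """Delete currency-metabolite occurrences matched by the rule table.

    Matching requires *all* trigger metabolites of a rule side to be present
    on one side of the reaction (partial matches do nothing); both reaction
    orientations are tried. Rules are applied sequentially against the
    current (already edited) sides, which makes the pass idempotent. The
    input network is not modified.
    """
    result = network.copy()
    log = RemovalLog()
    touched: set[str] = set()
    for rxn in result.reactions:
        for rule in rules:
            for trig_a, trig_b, rem_a, rem_b, side_a, side_b in (
                (
                    rule.trigger_left,
                    rule.trigger_right,
                    rule.removed_left,
                    rule.removed_right,
                    rxn.left,
                    rxn.right,
                ),
                (
                    rule.trigger_left,
                    rule.trigger_right,
                    rule.removed_left,
                    rule.removed_right,
                    rxn.right,
                    rxn.left,
                ),
            ):
                if trig_a <= side_a.keys() and trig_b <= side_b.keys():
                    for mid in sorted(rem_a & side_a.keys()):
                        del side_a[mid]
                        touched.add(mid)
                        log.add(
                            f"{rxn.id}:{mid}",
                            "metabolite-occurrence",
                            "side-compound",
                            rule.rule_id,
                        )
                    for mid in sorted(rem_b & side_b.keys()):
                        del side_b[mid]
                        touched.add(mid)
                        log.add(
                            f"{rxn.id}:{mid}",
                            "metabolite-occurrence",
                            "side-compound",
                            rule.rule_id,
                        )
    _drop_orphans(result, touched)
    return result, log


def remove_inorganics(
    network: MetabolicNetwork,
    inorganic_ids: Iterable[str] | None = None,
) -> tuple[MetabolicNetwork, RemovalLog]:
    """Delete every occurrence of the listed inorganic compounds.

    Defaults to :data:`DEFAULT_INORGANIC_IDS`. Listed metabolites left
    participating in no reaction are dropped from the metabolite map.
    """
    listed = frozenset(DEFAULT_INORGANIC_IDS if inorganic_ids is None else inorganic_ids)
    result = network.copy()
    log = RemovalLog()
    touched: set[str] = set()
    for rxn in result.reactions:
        for side in (rxn.left, rxn.right):
            for mid in sorted(listed & side.keys()):
                del side[mid]
                touched.add(mid)
                log.add(f"{rxn.id}:{mid}", "metabolite-occurrence", "inorganic")
    _drop_orphans(result, touched)
    return result, log


def drop_carbonless_reactions(
    network: MetabolicNetwork,
) -> tuple[MetabolicNetwork, RemovalLog]:
    """Remove reactions whose left or right side is empty (reason ``NC``).

    After side-compound and inorganic filtering, a reaction with an emptied
    side no longer describes a transfer of carbon between organic compounds.
    """
    result = network.copy()
    log = RemovalLog()
    kept: list[Reaction] = []
    touched: set[str] = set()
    for rxn in result.reactions:
        if not rxn.left or not rxn.right:
            log.add(rxn.id, "reaction", "NC")
            touched |= rxn.participants
        else:
            kept.append(rxn)
    result.reactions = kept
    _drop_orphans(result, touched)
    return result, log


def detect_disconnected_reactions(network: MetabolicNetwork) -> list[str]:
    """Flag reactions disconnected from the rest of the network (advisory).

    A reaction is flagged when all its substrates are produced by no other
    reaction *and* all its products are consumed by no other reaction; such
    reactions are candidates for manual curation ("fake" reactions from
    over-permissive enzyme annotations) but nothing is removed here, since
    an apparent disconnection can also signal an annotation hole. Both
    orientations of reversible reactions are considered, on the flagged
    reaction and on its potential partners alike.
    """
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for rxn in network.reactions:
        for mid in rxn.right:
            producers.setdefault(mid, set()).add(rxn.id)
        for mid in rxn.left:
            consumers.setdefault(mid, set()).add(rxn.id)
        if rxn.reversible:
            for mid in rxn.left:
                producers.setdefault(mid, set()).add(rxn.id)
            for mid in rxn.right:
                consumers.setdefault(mid, set()).add(rxn.id)

    def _other(index: dict[str, set[str]], mid: str, rid: str) -> bool:
        return bool(index.get(mid, set()) - {rid})

    flagged: list[str] = []
    for rxn in network.reactions:
        orientations = [(rxn.left, rxn.right)]
        if rxn.reversible:
            orientations.append((rxn.right, rxn.left))
        disconnected = all(
            not any(_other(producers, mid, rxn.id) for mid in inputs)
            and not any(_other(consumers, mid, rxn.id) for mid in outputs)
            for inputs, outputs in orientations
        )
        if disconnected:
            flagged.append(rxn.id)
    return flagged


_SPLIT_SUFFIXES = ["BIS", "TER", "QUATER"]


def split_generic_reaction(
    reaction: Reaction, substitutions: Sequence[tuple[str, str]]
) -> list[Reaction]:
    """Instantiate a reaction over a generic compound into specific copies.

    Each (generic id, specific id) substitution yields one reaction in which
    the generic metabolite is replaced by the specific one on whichever
    side(s) it occurs, all other participants preserved. Ids are suffixed
    deterministically: BIS, TER, QUATER, then numeric.
    """
    out: list[Reaction] = []
    for idx, (generic, specific) in enumerate(substitutions):
        if generic not in reaction.participants:
            raise NetworkValidationError(
                f"reaction {reaction.id}: generic metabolite {generic} not present"
            )
        suffix = _SPLIT_SUFFIXES[idx] if idx < len(_SPLIT_SUFFIXES) else str(idx + 2)
        new = reaction.copy()
        new.id = f"{reaction.id}{suffix}"
        for side in (new.left, new.right):
            if generic in side:
                coeff = side.pop(generic)
                side[specific] = side.get(specific, 0.0) + coeff
        out.append(new)
    return out


def apply_manual_overrides(
    network: MetabolicNetwork,
    removals: Sequence[tuple[str, str | None]],
) -> tuple[MetabolicNetwork, RemovalLog]:
    """Apply curator-specified removals, last in the pass order.

    Each entry is (reaction id, metabolite id) to delete one occurrence, or
    (reaction id, None) to delete the whole reaction. Unknown ids are errors:
    silent no-ops would defeat the audit trail.
    """
    result = network.copy()
    log = RemovalLog()
    touched: set[str] = set()
    for rid, mid in removals:
        try:
            rxn = result.get_reaction(rid)
        except KeyError:
            raise NetworkValidationError(f"manual override names unknown reaction {rid}")
        if mid is None:
            result.reactions.remove(rxn)
            log.add(rid, "reaction", "manual")
            touched |= rxn.participants
        else:
            hit = False
            for side in (rxn.left, rxn.right):
                if mid in side:
                    del side[mid]
                    hit = True
            if not hit:
                raise NetworkValidationError(
                    f"manual override: {mid} does not occur in reaction {rid}"
                )
            touched.add(mid)
            log.add(f"{rid}:{mid}", "metabolite-occurrence", "manual")
    _drop_orphans(result, touched)
    return result, log


def filter_network(
    network: MetabolicNetwork,
    rules: Sequence[SideCompoundRule] | None = None,
    inorganic_ids: Iterable[str] | None = None,
    manual_removals: Sequence[tuple[str, str | None]] = (),
) -> tuple[MetabolicNetwork, RemovalLog]:
    """Run the full fixed-order filtering pipeline.

    Order: side-compound rules -> inorganic removal -> manual overrides ->
    carbonless-reaction drop. The merged log preserves pass order so that
    deviations from the default configuration stay auditable.
    """
    rules = default_rules() if rules is None else rules
    log = RemovalLog()
    net, sub = apply_side_compound_rules(network, rules)
    log.extend(sub)
    net, sub = remove_inorganics(net, inorganic_ids)
    log.extend(sub)
    if manual_removals:
        net, sub = apply_manual_overrides(net, manual_removals)
        log.extend(sub)
    net, sub = drop_carbonless_reactions(net)
    log.extend(sub)
    return net, log
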