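"""Draft network assembly from donor models through an ortholog map.

A donor reaction is carried into the draft when at least one gene in its
GPR maps to a target-organism gene; mapped leaves are replaced by the OR of
their target co-orthologs (isozyme semantics — ortholog groups mix
orthologs and recent paralogs, so one-to-many expansion is disjunctive).
Donor genes with no target ortholog are left behind as namespaced leaves
(``organism::gene``) and resolved afterwards: pruned from rules that retain
a fully mapped alternative branch, or — when every satisfying branch needs
the absent gene, i.e. it is a required complex subunit with no isozyme —
the whole reaction is removed.

Reactions with empty donor GPRs (spontaneous/orphan) are never transferred
automatically; they are logged as candidates for manual opt-in.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .core import (
    GprExpr,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)
from .curation import reaction_signature

__all__ = [
    "OrthologMap",
    "TransferRecord",
    "TransferLog",
    "read_ortholog_map",
    "read_localization",
    "read_relocation_rules",
    "transfer_reactions",
    "resolve_unmapped",
    "candidate_orphans",
    "assign_compartments",
    "UNMAPPED_SEP",
]

#: Separator marking a donor-namespace (unmapped) gene leaf in a draft GPR.
UNMAPPED_SEP = "::"


@dataclass
class OrthologMap:
    """Ortholog groups linking donor genes to target-organism genes."""

    target_organism: str
    groups: Dict[str, Set[Tuple[str, str]]] = field(default_factory=dict)
    _index: Dict[Tuple[str, str], str] = field(default_factory=dict, repr=False)

    def add(self, group_id: str, organism: str, gene_id: str) -> None:
        key = (organism, gene_id)
        existing = self._index.get(key)
        if existing is not None and existing != group_id:
            raise ModelError(
                f"gene {gene_id!r} of {organism!r} is in two groups "
                f"({existing!r}, {group_id!r})"
            )
        self.groups.setdefault(group_id, set()).add(key)
        self._index[key] = group_id

    def lookup(self, organism: str, gene_id: str) -> Set[str]:
        """Target-organism genes sharing a group with (organism, gene)."""
        group_id = self._index.get((organism, gene_id))
        if group_id is None:
            return set()
        return {
            g for (org, g) in self.groups[group_id] if org == self.target_organism
        }

    def organisms(self) -> Set[str]:
        return {org for members in self.groups.values() for org, _ in members}


@dataclass
class TransferRecord:
    donor_model: str
    donor_reaction_id: str
    action: str  # transferred | gpr_pruned | removed_complex | skipped_no_ortholog
    detail: str = ""


@dataclass
class TransferLog:
    records: List[TransferRecord] = field(default_factory=list)

    def add(self, donor: str, rid: str, action: str, detail: str = "") -> None:
        self.records.append(TransferRecord(donor, rid, action, detail))

    def by_action(self, action: str) -> List[TransferRecord]:
        return [r for r in self.records if r.action == action]

    def write_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["donor_model", "donor_reaction_id", "action", "detail"])
            for r in self.records:
                w.writerow([r.donor_model, r.donor_reaction_id, r.action, r.detail])


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------


def read_ortholog_map(path: str, target_organism: str) -> OrthologMap:
    """TSV with columns group_id, organism, gene_id."""
    omap = OrthologMap(target_organism=target_organism)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            omap.add(row["group_id"], row["organism"], row["gene_id"])
    return omap


def read_localization(path: str) -> Dict[str, Set[str]]:
    """TSV with columns gene_id, compartments (comma-separated), signal_peptide."""
    table: Dict[str, Set[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            comps = {c.strip() for c in row["compartments"].split(",") if c.strip()}
            table[row["gene_id"]] = comps
    return table


def read_relocation_rules(path: str) -> List[Tuple[str, str, str]]:
    """TSV with columns selector, from, to (selector = reaction id, subsystem or *)."""
    rules = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rules.append((row["selector"], row["from"], row["to"]))
    return rules


# ---------------------------------------------------------------------------
# Reaction transfer
# ---------------------------------------------------------------------------


def _rewrite_gpr(gpr: GprExpr, organism: str, omap: OrthologMap) -> GprExpr:
    if gpr.op == "leaf":
        targets = sorted(omap.lookup(organism, gpr.gene))
        if targets:
            return GprExpr.any_of([GprExpr.leaf(t) for t in targets])
        return GprExpr.leaf(f"{organism}{UNMAPPED_SEP}{gpr.gene}")
    if gpr.op in ("and", "or"):
        return GprExpr(
            gpr.op, children=tuple(_rewrite_gpr(c, organism, omap) for c in gpr.children)
        )
    return gpr


def transfer_reactions(
    donors: Sequence[MetabolicModel],
    omap: OrthologMap,
    target_id: str = "draft",
    donor_organisms: Optional[Sequence[str]] = None,
) -> Tuple[MetabolicModel, TransferLog]:
    """Assemble a draft model from donor reactions with orthologous genes.

    Donors are processed in the given order; on duplicate reactions (same id
    or same canonical stoichiometry signature) the first donor's metadata
    wins, GPRs are unioned with OR, and the conflict is logged.
    ``donor_organisms`` defaults to each donor model's own id.
    """
    organisms = list(donor_organisms) if donor_organisms is not None else [d.id for d in donors]
    if len(organisms) != len(donors):
        raise ModelError("donor_organisms must match donors in length")
    known = omap.organisms()
    for org in organisms:
        if org not in known:
            raise ModelError(f"donor organism {org!r} absent from the ortholog map")

    draft = MetabolicModel(id=target_id)
    log = TransferLog()
    sig_to_rid: Dict[Tuple, str] = {}

    for donor, organism in zip(donors, organisms):
        for rxn in donor.reactions.values():
            if rxn.is_boundary:
                continue
            genes = rxn.gpr.genes()
            if not genes:
                log.add(donor.id, rxn.id, "skipped_no_ortholog",
                        "empty GPR (candidate orphan; manual opt-in)")
                continue
            if not any(omap.lookup(organism, g) for g in genes):
                log.add(donor.id, rxn.id, "skipped_no_ortholog",
                        "no gene maps to a target ortholog")
                continue
            new_gpr = _rewrite_gpr(rxn.gpr, organism, omap)
            sig = reaction_signature(rxn)
            existing_id = sig_to_rid.get(sig)
            if existing_id is None and rxn.id in draft.reactions:
                existing_id = rxn.id
            if existing_id is not None:
                kept = draft.reactions[existing_id]
                kept.gpr = GprExpr.any_of([kept.gpr, new_gpr]) if not kept.gpr.is_empty else new_gpr
                detail = f"duplicate of {existing_id}; GPR unioned, first-donor metadata kept"
                if (kept.lower_bound, kept.upper_bound) != (rxn.lower_bound, rxn.upper_bound):
                    detail += " (bounds conflict: first donor wins)"
                log.add(donor.id, rxn.id, "transferred", detail)
                continue
            for met_id in rxn.stoichiometry:
                if met_id in draft.metabolites:
                    continue
                met = donor.metabolites[met_id]
                if met.compartment and met.compartment not in draft.compartments:
                    draft.compartments[met.compartment] = donor.compartments.get(
                        met.compartment, met.compartment
                    )
                draft.add_metabolite(met.copy())
            new_rxn = rxn.copy()
            new_rxn.gpr = new_gpr
            draft.add_reaction(new_rxn)
            sig_to_rid[sig] = new_rxn.id
            log.add(donor.id, rxn.id, "transferred",
                    f"from {donor.id}")
    return draft, log


def candidate_orphans(log: TransferLog) -> List[Tuple[str, str]]:
    """(donor, reaction) pairs skipped for having empty GPRs."""
    return [
        (r.donor_model, r.donor_reaction_id)
        for r in log.by_action("skipped_no_ortholog")
        if "empty GPR" in r.detail
    ]


# ---------------------------------------------------------------------------
# Unmapped-gene resolution
# ---------------------------------------------------------------------------


def _is_unmapped(gene: str) -> bool:
    return UNMAPPED_SEP in gene


def resolve_unmapped(
    draft: MetabolicModel, log: Optional[TransferLog] = None
) -> Tuple[MetabolicModel, TransferLog]:
    """Resolve donor-namespace leaves left in draft GPRs.

    Working on the disjunctive normal form of each rule: branches containing
    an unmapped gene are deleted when at least one fully mapped branch
    survives (isozyme pruning); when no branch is fully mapped the reaction
    is removed (missing complex subunit with no isozyme).  Idempotent, and
    the result contains no donor-namespace genes.
    """
    if log is None:
        log = TransferLog()
    model = draft.copy()
    for rid in list(model.reactions):
        rxn = model.reactions[rid]
        genes = rxn.gpr.genes()
        unmapped = {g for g in genes if _is_unmapped(g)}
        if not unmapped:
            continue
        branches = rxn.gpr.to_dnf()
        mapped_branches = [b for b in branches if not any(_is_unmapped(g) for g in b)]
        if mapped_branches:
            rxn.gpr = GprExpr.from_dnf(mapped_branches)
            log.add(model.id, rid, "gpr_pruned",
                    f"dropped branches requiring unmapped genes {sorted(unmapped)}")
        else:
            model.remove_reaction(rid)
            log.add(model.id, rid, "removed_complex",
                    f"all branches require unmapped genes {sorted(unmapped)}")
    model.prune_unused()
    return model, log


# ---------------------------------------------------------------------------
# Compartment assignment
# ---------------------------------------------------------------------------


def _resuffix(met_id: str, compartment: str, to: str) -> str:
    suffix = "_" + compartment
    if met_id.endswith(suffix):
        return met_id[: -len(suffix)] + "_" + to
    return met_id + "_" + to


def _relocate(model: MetabolicModel, rid: str, from_comp: str, to_comp: str) -> None:
    rxn = model.reactions[rid]
    new_stoich: Dict[str, float] = {}
    for met_id, coef in rxn.stoichiometry.items():
        met = model.metabolites[met_id]
        if met.compartment != from_comp:
            new_stoich[met_id] = new_stoich.get(met_id, 0.0) + coef
            continue
        new_id = _resuffix(met_id, from_comp, to_comp)
        if new_id not in model.metabolites:
            moved = met.copy()
            moved.id = new_id
            moved.compartment = to_comp
            model.add_metabolite(moved)
        new_stoich[new_id] = new_stoich.get(new_id, 0.0) + coef
    rxn.stoichiometry = {k: v for k, v in new_stoich.items() if v != 0}


def assign_compartments(
    model: MetabolicModel,
    localization: Optional[Mapping[str, Set[str]]] = None,
    rules: Optional[Sequence[Tuple[str, str, str]]] = None,
    target_compartments: Optional[Iterable[str]] = None,
    log: Optional[TransferLog] = None,
) -> Tuple[MetabolicModel, TransferLog]:
    """Relocate or remove reactions sitting in foreign compartments.

    ``rules`` are ``(selector, from, to)`` rows matched against reaction id,
    subsystem, or ``*``.  Reactions in compartments outside
    ``target_compartments`` with no applicable rule are relocated to a
    compartment their genes localize to (when the localization table offers
    a declared one) and removed otherwise.  Relocation to an undeclared
    compartment is an error.  Relocations that create a duplicate signature
    collapse onto the existing copy.
    """
    if log is None:
        log = TransferLog()
    rules = list(rules or [])
    localization = dict(localization or {})
    out = model.copy()
    declared = set(target_compartments) if target_compartments is not None else set(out.compartments)
    for comp in declared:
        out.compartments.setdefault(comp, comp)
    for _sel, _from, to in rules:
        if to not in declared:
            raise ModelError(f"relocation rule targets undeclared compartment {to!r}")

    sig_index: Dict[Tuple, str] = {
        reaction_signature(r): r.id for r in out.reactions.values()
    }

    for rid in list(out.reactions):
        rxn = out.reactions.get(rid)
        if rxn is None:
            continue
        comps = {out.metabolites[m].compartment for m in rxn.stoichiometry}
        foreign = comps - declared
        moves: List[Tuple[str, str]] = []
        for rule_sel, rule_from, rule_to in rules:
            if rule_sel not in ("*", rid, rxn.subsystem):
                continue
            if rule_from in comps:
                moves.append((rule_from, rule_to))
        ruled_from = {f for f, _ in moves}
        unresolved = foreign - ruled_from
        if unresolved:
            allowed: Optional[Set[str]] = None
            for gene in sorted(rxn.gpr.genes()):
                loc = localization.get(gene)
                if loc is None:
                    continue
                allowed = loc if allowed is None else allowed & loc
            candidates = sorted((allowed or set()) & declared)
            if candidates:
                moves.extend((f, candidates[0]) for f in sorted(unresolved))
            else:
                sig_index.pop(reaction_signature(rxn), None)
                out.remove_reaction(rid)
                log.add(out.id, rid, "removed_complex",
                        f"foreign compartments {sorted(unresolved)} with no relocation rule")
                continue
        if not moves:
            continue
        old_sig = reaction_signature(rxn)
        for from_comp, to_comp in moves:
            if to_comp not in declared:
                raise ModelError(f"relocation of {rid!r} targets undeclared compartment {to_comp!r}")
            _relocate(out, rid, from_comp, to_comp)
        sig_index.pop(old_sig, None)
        new_sig = reaction_signature(rxn)
        existing = sig_index.get(new_sig)
        if existing is not None and existing != rid:
            kept = out.reactions[existing]
            if not rxn.gpr.is_empty:
                kept.gpr = (GprExpr.any_of([kept.gpr, rxn.gpr])
                            if not kept.gpr.is_empty else rxn.gpr)
            out.remove_reaction(rid)
            log.add(out.id, rid, "transferred",
                    f"relocation duplicated {existing}; collapsed")
        else:
            sig_index[new_sig] = rid
            log.add(out.id, rid, "transferred",
                    "relocated " + ", ".join(f"{f}->{t}" for f, t in moves))
    out.prune_unused()
    out.compartments = {
        c: n for c, n in out.compartments.items()
        if c in declared or any(m.compartment == c for m in out.metabolites.values())
    }
    return out, log
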