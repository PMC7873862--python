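"""Mechanical curation audits: duplicates, merges, dead ends.

Duplicate *metabolites* are candidates sharing a ``(formula, charge,
compartment)`` key, a known alias pair, or (for ranking only) a normalized
name token.  Duplicate *reactions* share a canonical stoichiometry
signature: metabolite ids sorted, coefficients rescaled so the
lexicographically smallest participant has coefficient -1 (anchored at +1
for pure-production reactions), which makes the signature invariant both to
insertion order and to writing a reversible reaction in either direction.

Every mutating operation appends to a :class:`ChangeLog` so a curator can
review what was merged or dropped and why.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .core import (
    GprExpr,
    MetabolicModel,
    ModelError,
    Reaction,
    ReactionKind,
    format_formula,
)

__all__ = [
    "ChangeLog",
    "DuplicateCandidate",
    "reaction_signature",
    "metabolite_key",
    "find_duplicate_metabolites",
    "merge_metabolites",
    "find_duplicate_reactions",
    "dedup_reactions",
    "DeadEnd",
    "dead_end_report",
]


@dataclass
class ChangeRecord:
    operation: str
    ids: Tuple[str, ...]
    detail: str = ""


@dataclass
class ChangeLog:
    records: List[ChangeRecord] = field(default_factory=list)

    def add(self, operation: str, ids: Sequence[str], detail: str = "") -> None:
        self.records.append(ChangeRecord(operation, tuple(ids), detail))

    def by_operation(self, operation: str) -> List[ChangeRecord]:
        return [r for r in self.records if r.operation == operation]


# ---------------------------------------------------------------------------
# Keys and signatures
# ---------------------------------------------------------------------------


def metabolite_key(model: MetabolicModel, met_id: str) -> Optional[Tuple[str, Optional[int], str]]:
    """(formula, charge, compartment) key; None when the formula is unknown."""
    met = model.metabolites[met_id]
    if met.formula is None:
        return None
    return (format_formula(met.formula), met.charge, met.compartment)


_NAME_STRIP = re.compile(r"[^a-z0-9]+")


def name_token(name: str) -> str:
    """Lowercased, non-alphanumeric-stripped name token (ranking only)."""
    return _NAME_STRIP.sub("", name.lower())


def reaction_signature(rxn: Reaction, ndigits: int = 9) -> Tuple:
    """Canonical, direction- and scale-normalized stoichiometry signature."""
    items = sorted(rxn.stoichiometry.items())
    if not items:
        return (rxn.kind.value,)
    anchor_coef = items[0][1]
    if all(c > 0 for _, c in items):
        scale = 1.0 / anchor_coef
    else:
        scale = -1.0 / anchor_coef
    body = tuple((met, round(coef * scale, ndigits)) for met, coef in items)
    return (rxn.kind.value,) + body


def _signature_scale(reference: Reaction, other: Reaction) -> Optional[float]:
    """alpha with other = alpha * reference elementwise, or None."""
    if set(other.stoichiometry) != set(reference.stoichiometry):
        return None
    alphas = {
        round(other.stoichiometry[m] / reference.stoichiometry[m], 9)
        for m in reference.stoichiometry
    }
    return alphas.pop() if len(alphas) == 1 else None


# ---------------------------------------------------------------------------
# Duplicate metabolites
# ---------------------------------------------------------------------------


@dataclass
class DuplicateCandidate:
    keep_id: str
    drop_id: str
    reason: str  # exact-key | alias | name-token
    evidence: str = ""


def find_duplicate_metabolites(
    model: MetabolicModel,
    alias_table: Optional[Mapping[str, str]] = None,
) -> List[DuplicateCandidate]:
    """Rank duplicate-metabolite candidates.

    Exact ``(formula, charge, compartment)`` matches come first, then alias
    pairs, then same-compartment name-token matches (suggestions only —
    never auto-merged).  Metabolites without formulas can only be matched
    through the alias table or name tokens.
    """
    out: List[DuplicateCandidate] = []
    seen_pairs: Set[Tuple[str, str]] = set()

    def emit(a: str, b: str, reason: str, evidence: str = "") -> None:
        keep, drop = sorted([a, b])
        if (keep, drop) in seen_pairs or keep == drop:
            return
        seen_pairs.add((keep, drop))
        out.append(DuplicateCandidate(keep, drop, reason, evidence))

    by_key: Dict[Tuple, List[str]] = {}
    for met_id in model.metabolites:
        key = metabolite_key(model, met_id)
        if key is not None:
            by_key.setdefault(key, []).append(met_id)
    for key, ids in sorted(by_key.items()):
        if len(ids) > 1:
            ids = sorted(ids)
            for other in ids[1:]:
                emit(ids[0], other, "exact-key", evidence=str(key))

    if alias_table:
        for a, b in alias_table.items():
            if a in model.metabolites and b in model.metabolites:
                emit(a, b, "alias")

    by_token: Dict[Tuple[str, str], List[str]] = {}
    for met in model.metabolites.values():
        tok = name_token(met.name)
        if tok:
            by_token.setdefault((tok, met.compartment), []).append(met.id)
    for (_tok, _comp), ids in sorted(by_token.items()):
        if len(ids) > 1:
            ids = sorted(ids)
            for other in ids[1:]:
                emit(ids[0], other, "name-token")
    order = {"exact-key": 0, "alias": 1, "name-token": 2}
    out.sort(key=lambda c: (order[c.reason], c.keep_id, c.drop_id))
    return out


def merge_metabolites(
    model: MetabolicModel,
    keep_id: str,
    drop_id: str,
    log: Optional[ChangeLog] = None,
) -> MetabolicModel:
    """Rewrite all references of ``drop_id`` to ``keep_id`` and delete it.

    Coefficients on the two ids within one reaction are summed; entries
    cancelling to zero are removed (a reaction emptied this way is deleted).
    Reactions whose signature now duplicates another are flagged in the log.
    Cross-compartment merges are refused — relocate first.
    """
    for mid in (keep_id, drop_id):
        if mid not in model.metabolites:
            raise ModelError(f"cannot merge: metabolite {mid!r} not in model")
    keep = model.metabolites[keep_id]
    drop = model.metabolites[drop_id]
    if keep.compartment != drop.compartment:
        raise ModelError(
            f"cross-compartment merge {drop_id!r} ({drop.compartment}) -> "
            f"{keep_id!r} ({keep.compartment}); relocate first"
        )
    out = model.copy()
    emptied = []
    for rxn in out.reactions.values():
        if drop_id not in rxn.stoichiometry:
            continue
        coef = rxn.stoichiometry.pop(drop_id)
        merged = rxn.stoichiometry.get(keep_id, 0.0) + coef
        if merged == 0.0:
            rxn.stoichiometry.pop(keep_id, None)
        else:
            rxn.stoichiometry[keep_id] = merged
        if not rxn.stoichiometry and not rxn.is_boundary:
            emptied.append(rxn.id)
    for rid in emptied:
        out.remove_reaction(rid)
        if log is not None:
            log.add("remove_emptied_reaction", [rid], f"emptied by merging {drop_id} into {keep_id}")
    del out.metabolites[drop_id]
    if log is not None:
        log.add("merge_metabolites", [keep_id, drop_id], "drop merged into keep")
        for group in find_duplicate_reactions(out):
            touched = [
                rid for rid in group if keep_id in out.reactions[rid].stoichiometry
            ]
            if touched:
                log.add("duplicate_reaction_flag", group,
                        f"signatures collide after merging {drop_id} into {keep_id}")
    return out


# ---------------------------------------------------------------------------
# Duplicate reactions
# ---------------------------------------------------------------------------


def find_duplicate_reactions(model: MetabolicModel) -> List[List[str]]:
    """Groups of reactions (sorted ids) sharing a canonical signature."""
    by_sig: Dict[Tuple, List[str]] = {}
    for rxn in model.reactions.values():
        by_sig.setdefault(reaction_signature(rxn), []).append(rxn.id)
    groups = [sorted(ids) for ids in by_sig.values() if len(ids) > 1]
    groups.sort()
    return groups


def dedup_reactions(
    model: MetabolicModel,
    log: Optional[ChangeLog] = None,
) -> MetabolicModel:
    """Collapse each duplicate group onto its lexicographically smallest id.

    The kept reaction unions the GPRs with OR and takes the widest bounds,
    with each dropped reaction's bounds mapped through its stoichiometric
    scale factor relative to the kept one (so a reversed copy widens the
    reverse direction).  Idempotent, and flux-cone preserving.
    """
    out = model.copy()
    for group in find_duplicate_reactions(out):
        keep_id = group[0]
        keep = out.reactions[keep_id]
        gprs = [keep.gpr]
        lo, hi = keep.lower_bound, keep.upper_bound
        for drop_id in group[1:]:
            drop = out.reactions[drop_id]
            alpha = _signature_scale(keep, drop)
            if alpha is None or alpha == 0:  # pragma: no cover - signature guarantees
                continue
            mapped = sorted([drop.lower_bound / alpha, drop.upper_bound / alpha])
            lo = min(lo, mapped[0])
            hi = max(hi, mapped[1])
            if not drop.gpr.is_empty:
                gprs.append(drop.gpr)
            out.remove_reaction(drop_id)
            if log is not None:
                log.add("dedup_reaction", [keep_id, drop_id],
                        f"duplicate of {keep_id} (scale {alpha})")
        keep.lower_bound, keep.upper_bound = lo, hi
        non_empty = [g for g in gprs if not g.is_empty]
        keep.gpr = GprExpr.any_of(non_empty) if non_empty else GprExpr.empty()
    out.prune_unused()
    return out


# ---------------------------------------------------------------------------
# Dead ends
# ---------------------------------------------------------------------------


@dataclass
class DeadEnd:
    metabolite_id: str
    role: str  # only-produced | only-consumed | disconnected


def dead_end_report(model: MetabolicModel) -> List[DeadEnd]:
    """Classify dead-end metabolites from the stoichiometric sparsity pattern.

    A metabolite is producible if some flux-capable reaction can create it
    (positive coefficient with a positive upper bound, or negative
    coefficient with a negative lower bound), and symmetrically consumable.
    Boundary reactions count, so a fully exchanged model reports nothing.
    """
    producible: Set[str] = set()
    consumable: Set[str] = set()
    touched: Set[str] = set()
    for rxn in model.reactions.values():
        can_fwd = rxn.upper_bound > 0
        can_rev = rxn.lower_bound < 0
        if not (can_fwd or can_rev):
            continue
        for met, coef in rxn.stoichiometry.items():
            touched.add(met)
            if (coef > 0 and can_fwd) or (coef < 0 and can_rev):
                producible.add(met)
            if (coef < 0 and can_fwd) or (coef > 0 and can_rev):
                consumable.add(met)
    report = []
    for met_id in model.metabolites:
        if met_id not in touched:
            report.append(DeadEnd(met_id, "disconnected"))
        elif met_id in producible and met_id not in consumable:
            report.append(DeadEnd(met_id, "only-produced"))
        elif met_id in consumable and met_id not in producible:
            report.append(DeadEnd(met_id, "only-consumed"))
    return report
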