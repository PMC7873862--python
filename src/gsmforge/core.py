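"""Core domain types for compartmentalized constraint-based metabolic models.

The central object is :class:`MetabolicModel`, a collection of compartments,
metabolites, reactions and genes together with an objective.  Every other
stage of the reconstruction pipeline (draft transfer, curation, biomass
assembly, simulation, validation) consumes and produces this type.

Conventions follow the BiGG dialect: metabolite ids are base id plus an
underscore-separated compartment suffix (``glc__D_c``), gene-protein-reaction
(GPR) rules are infix boolean strings over gene ids with ``and`` binding
tighter than ``or``, and chemical formulas are serialized in Hill order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "FormulaError",
    "GprParseError",
    "ModelError",
    "parse_formula",
    "format_formula",
    "formula_weight",
    "GprExpr",
    "parse_gpr",
    "evaluate_gpr",
    "Metabolite",
    "ReactionKind",
    "Reaction",
    "Gene",
    "MetabolicModel",
    "BalanceReport",
    "check_balance",
    "ATOMIC_WEIGHTS",
]


class FormulaError(ValueError):
    """Raised for a chemical formula that does not match the grammar."""


class GprParseError(ValueError):
    """Raised for a malformed gene-protein-reaction rule string."""


class ModelError(ValueError):
    """Raised for referential-integrity violations in a model."""


# ---------------------------------------------------------------------------
# Chemical formulas
# ---------------------------------------------------------------------------

# Element symbol: one uppercase letter optionally followed by lowercase
# letters.  Pseudo-elements "R" and "X" (lumped acyl chains / unspecified
# groups) are ordinary symbols under this grammar and take part in balance
# arithmetic like any element.
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]*)(\d*)")

#: Standard atomic weights (g/mol) for the elements used by the packaged
#: fixtures and biomass arithmetic.  Pseudo-elements carry weight 0.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Cl": 35.45, "Se": 78.971, "Cu": 63.546,
    "Mn": 54.938, "Mo": 95.95, "Co": 58.933, "R": 0.0, "X": 0.0,
}


def parse_formula(text: str) -> Dict[str, int]:
    """Parse a chemical formula string into an element -> count map.

    Omitted counts are read as 1 (``H2O`` -> ``{"H": 2, "O": 1}``).  Repeated
    element symbols accumulate.  Raises :class:`FormulaError` naming the
    offending token for anything outside the grammar.
    """
    if text is None:
        raise FormulaError("formula is None")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at position {pos} "
                f"({text[pos:pos + 8]!r})"
            )
        element, count_str = m.groups()
        count = int(count_str) if count_str else 1
        if count < 0:  # pragma: no cover - regex forbids signs
            raise FormulaError(f"negative count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return {el: n for el, n in counts.items() if n != 0}


def format_formula(counts: Mapping[str, int]) -> str:
    """Serialize an element map in Hill order.

    Carbon first, then hydrogen, then all other elements alphabetically; when
    no carbon is present all elements sort alphabetically.  Counts of 1 are
    omitted, so ``parse -> format -> parse`` is the identity.
    """
    items = dict(counts)
    ordered: List[str] = []
    if "C" in items:
        ordered.append("C")
        if "H" in items:
            ordered.append("H")
        ordered.extend(sorted(k for k in items if k not in ("C", "H")))
    else:
        ordered.extend(sorted(items))
    parts = []
    for el in ordered:
        n = items[el]
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def formula_weight(counts: Mapping[str, int]) -> float:
    """Molecular weight (g/mol) from an element map; unknown elements error."""
    total = 0.0
    for el, n in counts.items():
        if el not in ATOMIC_WEIGHTS:
            raise FormulaError(f"no atomic weight for element {el!r}")
        total += ATOMIC_WEIGHTS[el] * n
    return total


# ---------------------------------------------------------------------------
# Gene-protein-reaction boolean rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GprExpr:
    """Boolean expression over gene ids.

    ``op`` is one of ``"and"``, ``"or"``, ``"leaf"`` or ``"empty"``.  The
    empty expression denotes "no gene requirement" and always evaluates
    satisfied.  AND/OR nodes are flattened (associative) and carry at least
    two children.
    """

    op: str
    gene: Optional[str] = None
    children: Tuple["GprExpr", ...] = ()

    # -- constructors -------------------------------------------------------
    @staticmethod
    def empty() -> "GprExpr":
        return GprExpr("empty")

    @staticmethod
    def leaf(gene: str) -> "GprExpr":
        return GprExpr("leaf", gene=gene)

    @staticmethod
    def all_of(children: Sequence["GprExpr"]) -> "GprExpr":
        return _combine("and", children)

    @staticmethod
    def any_of(children: Sequence["GprExpr"]) -> "GprExpr":
        return _combine("or", children)

    # -- queries ------------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> Set[str]:
        if self.op == "leaf":
            return {self.gene}
        out: Set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, knocked_out: Iterable[str] = ()) -> bool:
        ko = set(knocked_out)
        if self.op == "empty":
            return True
        if self.op == "leaf":
            return self.gene not in ko
        if self.op == "and":
            return all(c.evaluate(ko) for c in self.children)
        return any(c.evaluate(ko) for c in self.children)

    def to_dnf(self) -> List[FrozenSet[str]]:
        """Disjunctive normal form: a list of conjunctions (gene sets).

        The empty expression yields a single empty conjunction (always
        satisfiable).  Subsumed conjunctions (supersets of another) are
        dropped so each returned set is a minimal satisfying branch.
        """
        if self.op == "empty":
            return [frozenset()]
        if self.op == "leaf":
            return [frozenset([self.gene])]
        if self.op == "or":
            branches: List[FrozenSet[str]] = []
            for child in self.children:
                branches.extend(child.to_dnf())
        else:  # and: cartesian product of children's branches
            branches = [frozenset()]
            for child in self.children:
                branches = [a | b for a in branches for b in child.to_dnf()]
        # drop duplicates and supersets
        unique = sorted(set(branches), key=lambda s: (len(s), sorted(s)))
        minimal: List[FrozenSet[str]] = []
        for b in unique:
            if not any(m <= b for m in minimal):
                minimal.append(b)
        return minimal

    @staticmethod
    def from_dnf(branches: Sequence[Iterable[str]]) -> "GprExpr":
        terms = []
        for branch in branches:
            genes = sorted(set(branch))
            if not genes:
                return GprExpr.empty()
            terms.append(GprExpr.all_of([GprExpr.leaf(g) for g in genes]))
        if not terms:
            raise ValueError("DNF with no branches is unsatisfiable, not empty")
        return GprExpr.any_of(terms)

    # -- serialization ------------------------------------------------------
    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "leaf":
            return self.gene
        if self.op == "or":
            return " or ".join(c.to_string() for c in self.children)
        # and binds tighter than or, so or-children need parentheses
        parts = []
        for c in self.children:
            s = c.to_string()
            parts.append(f"({s})" if c.op == "or" else s)
        return " and ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _combine(op: str, children: Sequence[GprExpr]) -> GprExpr:
    flat: List[GprExpr] = []
    for c in children:
        if c.op == "empty":
            continue
        if c.op == op:
            flat.extend(c.children)
        else:
            flat.append(c)
    # deduplicate identical children, preserving order
    seen = set()
    uniq = []
    for c in flat:
        key = c.to_string()
        if key not in seen:
            seen.add(key)
            uniq.append(c)
    if not uniq:
        return GprExpr.empty()
    if len(uniq) == 1:
        return uniq[0]
    return GprExpr(op, children=tuple(uniq))


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GprExpr:
    """Parse an infix GPR string (``"(g1 and g2) or g3"``).

    ``and``/``or`` are case-insensitive keywords; ``and`` binds tighter than
    ``or``.  Empty or whitespace-only text is the always-satisfied empty
    rule.  Errors report the character position of the offending token.
    """
    if text is None:
        text = ""
    tokens: List[Tuple[str, int]] = [
        (m.group(0), m.start()) for m in _GPR_TOKEN.finditer(text)
    ]
    if not tokens:
        return GprExpr.empty()
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos][0] if pos < len(tokens) else None

    def error(msg: str) -> GprParseError:
        at = tokens[pos][1] if pos < len(tokens) else len(text)
        return GprParseError(f"{msg} at position {at} in {text!r}")

    def parse_or() -> GprExpr:
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        return GprExpr.any_of(terms)

    def parse_and() -> GprExpr:
        nonlocal pos
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            terms.append(parse_atom())
        return GprExpr.all_of(terms)

    def parse_atom() -> GprExpr:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise error("unexpected end of rule")
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise error("unbalanced parentheses: expected ')'")
            pos += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise error(f"unexpected token {tok!r}")
        pos += 1
        return GprExpr.leaf(tok)

    expr = parse_or()
    if pos != len(tokens):
        raise error(f"stray token {tokens[pos][0]!r}")
    return expr


def evaluate_gpr(gpr: GprExpr, knocked_out: Iterable[str] = ()) -> bool:
    """True iff the rule is satisfied with the given genes knocked out."""
    return gpr.evaluate(knocked_out)


# ---------------------------------------------------------------------------
# Model components
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: Optional[Dict[str, int]] = None
    charge: Optional[int] = None
    compartment: str = ""

    def copy(self) -> "Metabolite":
        return replace(self, formula=dict(self.formula) if self.formula is not None else None)


@dataclass
class Gene:
    id: str
    name: str = ""


class ReactionKind(str, Enum):
    METABOLIC = "metabolic"
    EXCHANGE = "exchange"
    TRANSPORT = "transport"
    DEMAND = "demand"
    SINK = "sink"
    BIOMASS = "biomass"


#: Reaction kinds exempt from the mass/charge balance audit: they move mass
#: across the system boundary by design.
BOUNDARY_KINDS = {
    ReactionKind.EXCHANGE,
    ReactionKind.DEMAND,
    ReactionKind.SINK,
    ReactionKind.BIOMASS,
}


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GprExpr = field(default_factory=GprExpr.empty)
    name: str = ""
    subsystem: str = ""
    kind: ReactionKind = ReactionKind.METABOLIC

    def __post_init__(self) -> None:
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if isinstance(self.kind, str):
            self.kind = ReactionKind(self.kind)
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_boundary(self) -> bool:
        return self.kind in BOUNDARY_KINDS

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    """A compartmentalized constraint-based model.

    ``objective`` is a ``(reaction_id, direction)`` pair with direction
    ``"max"`` or ``"min"``.
    """

    id: str = "model"
    compartments: Dict[str, str] = field(default_factory=dict)
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    genes: Dict[str, Gene] = field(default_factory=dict)
    objective: Optional[Tuple[str, str]] = None

    # -- construction -------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        if met.compartment and met.compartment not in self.compartments:
            raise ModelError(
                f"metabolite {met.id!r}: compartment {met.compartment!r} not declared"
            )
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, register_genes: bool = True) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelError(
                f"reaction {rxn.id!r} references undeclared metabolites: {missing}"
            )
        if not rxn.stoichiometry and not rxn.is_boundary:
            raise ModelError(f"reaction {rxn.id!r} has empty stoichiometry")
        self.reactions[rxn.id] = rxn
        if register_genes:
            for g in rxn.gpr.genes():
                self.genes.setdefault(g, Gene(g))

    def remove_reaction(self, rxn_id: str) -> None:
        del self.reactions[rxn_id]

    def prune_unused(self) -> Tuple[Set[str], Set[str]]:
        """Drop metabolites and genes no reaction references; return dropped ids."""
        used_mets: Set[str] = set()
        used_genes: Set[str] = set()
        for rxn in self.reactions.values():
            used_mets |= set(rxn.stoichiometry)
            used_genes |= rxn.gpr.genes()
        drop_m = set(self.metabolites) - used_mets
        drop_g = set(self.genes) - used_genes
        for m in drop_m:
            del self.metabolites[m]
        for g in drop_g:
            del self.genes[g]
        return drop_m, drop_g

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            compartments=dict(self.compartments),
            metabolites={k: v.copy() for k, v in self.metabolites.items()},
            reactions={k: v.copy() for k, v in self.reactions.items()},
            genes={k: replace(v) for k, v in self.genes.items()},
            objective=self.objective,
        )

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Check referential integrity; raises :class:`ModelError`."""
        for met in self.metabolites.values():
            if met.compartment and met.compartment not in self.compartments:
                raise ModelError(
                    f"metabolite {met.id!r}: undeclared compartment {met.compartment!r}"
                )
        for rxn in self.reactions.values():
            for m in rxn.stoichiometry:
                if m not in self.metabolites:
                    raise ModelError(f"reaction {rxn.id!r}: unknown metabolite {m!r}")
            for g in rxn.gpr.genes():
                if g not in self.genes:
                    raise ModelError(f"reaction {rxn.id!r}: unknown gene {g!r}")
        if self.objective is not None and self.objective[0] not in self.reactions:
            raise ModelError(f"objective reaction {self.objective[0]!r} not in model")

    # -- linear algebra -----------------------------------------------------
    def stoichiometric_matrix(self) -> Tuple[np.ndarray, List[str], List[str]]:
        """Dense S with one row per metabolite, one column per reaction.

        Returns ``(S, metabolite_ids, reaction_ids)`` with rows/columns in
        the returned id order.
        """
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for m, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[m], j] = coef
        return S, met_ids, rxn_ids

    def exchanges(self) -> List[str]:
        return [r.id for r in self.reactions.values() if r.kind == ReactionKind.EXCHANGE]

    def boundary_reactions(self) -> List[str]:
        return [r.id for r in self.reactions.values() if r.is_boundary]


# ---------------------------------------------------------------------------
# Mass / charge balance audit
# ---------------------------------------------------------------------------


@dataclass
class ReactionImbalance:
    reaction_id: str
    element_net: Dict[str, float]
    charge_net: Optional[float]
    has_pseudo_elements: bool
    unauditable: bool = False
    missing: Tuple[str, ...] = ()


@dataclass
class BalanceReport:
    """Audit result listing only unbalanced or unauditable reactions."""

    imbalances: List[ReactionImbalance] = field(default_factory=list)

    @property
    def unbalanced_ids(self) -> List[str]:
        return [r.reaction_id for r in self.imbalances if not r.unauditable]

    @property
    def unauditable_ids(self) -> List[str]:
        return [r.reaction_id for r in self.imbalances if r.unauditable]

    @property
    def is_clean(self) -> bool:
        return not self.imbalances


def _reaction_net(
    rxn: Reaction, model: MetabolicModel
) -> Tuple[Dict[str, float], Optional[float], bool, List[str]]:
    element_net: Dict[str, float] = {}
    charge_net: Optional[float] = 0.0
    pseudo = False
    missing: List[str] = []
    for met_id, coef in rxn.stoichiometry.items():
        met = model.metabolites[met_id]
        if met.formula is None:
            missing.append(met_id)
            continue
        for el, n in met.formula.items():
            if el in ("R", "X"):
                pseudo = True
            element_net[el] = element_net.get(el, 0.0) + coef * n
        if met.charge is None:
            missing.append(met_id)
        elif charge_net is not None:
            charge_net += coef * met.charge
    if any(model.metabolites[m].charge is None for m in rxn.stoichiometry):
        charge_net = None
    element_net = {el: v for el, v in element_net.items() if v != 0}
    return element_net, charge_net, pseudo, missing


def check_balance(model: MetabolicModel, tol: float = 1e-6) -> BalanceReport:
    """Audit mass and charge balance of every non-boundary reaction.

    Exchange, demand, sink and biomass reactions are exempt.  A reaction is
    balanced iff every element net and the charge net are zero — exactly for
    integer stoichiometries, within ``tol`` when any coefficient is
    non-integer (biomass-style fractional stoichiometries).  Reactions whose
    metabolites lack formula or charge are reported as unauditable rather
    than silently skipped.
    """
    report = BalanceReport()
    for rxn in model.reactions.values():
        if rxn.is_boundary:
            continue
        element_net, charge_net, pseudo, missing = _reaction_net(rxn, model)
        if missing:
            report.imbalances.append(
                ReactionImbalance(rxn.id, element_net, charge_net, pseudo,
                                  unauditable=True, missing=tuple(sorted(set(missing))))
            )
            continue
        all_integer = all(float(c).is_integer() for c in rxn.stoichiometry.values())
        thresh = 0.0 if all_integer else tol
        bad_elements = {el: v for el, v in element_net.items() if abs(v) > thresh}
        charge_bad = charge_net is not None and abs(charge_net) > thresh
        if bad_elements or charge_bad:
            report.imbalances.append(
                ReactionImbalance(rxn.id, bad_elements, charge_net, pseudo)
            )
    return report
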