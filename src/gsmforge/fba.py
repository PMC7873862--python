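"""Constraint-based simulation: FBA, gene deletions, and cycle audits.

Flux balance analysis solves ``max/min c'v`` subject to steady state
``S v = 0`` and flux bounds, via the HiGHS solvers behind
:func:`scipy.optimize.linprog`.  Shadow prices are the dual values of the
metabolite mass-balance rows, with the sign convention that a positive
shadow price means relaxing that metabolite's balance (allowing net
accumulation) would increase the objective.

Energy-generating cycles (EGCs) — internal loops that produce an energy
currency such as ATP or a trans-mitochondrial proton gradient with every
exchange closed — are detected by maximizing a currency-dissipation flux
and, when positive, localized with a mixed-integer program that finds the
minimum set of active reactions sustaining the dissipation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, linprog, milp
from scipy.optimize import Bounds as OptBounds

from .core import MetabolicModel, ModelError, Reaction, ReactionKind

__all__ = [
    "FluxResult",
    "DeletionResult",
    "CurrencySpec",
    "EgcFinding",
    "apply_medium",
    "fba",
    "diagnose_precursors",
    "delete_genes",
    "single_gene_deletions",
    "flux_variability",
    "default_currency_specs",
    "find_egc",
    "GROWTH_TOL",
    "ESSENTIALITY_THRESHOLD",
]

#: Flux below which a growth value is called "no growth" (mmol·gDW⁻¹·h⁻¹).
GROWTH_TOL = 1e-6
#: A deletion is essential when growth drops below this fraction of reference.
ESSENTIALITY_THRESHOLD = 0.1

MediumValue = Union[float, Tuple[float, float]]


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)
    shadow_prices: Dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class DeletionResult:
    genes: Tuple[str, ...]
    disabled_reactions: Tuple[str, ...]
    growth: float
    growth_ratio: float
    essential: bool


@dataclass
class CurrencySpec:
    """Dissipation stoichiometry for one energy currency.

    e.g. ATP hydrolysis ``{"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1,
    "h_c": 1}`` or the trans-mitochondrial proton gradient ``{"h_c": -1,
    "h_m": 1}``.
    """

    name: str
    stoichiometry: Dict[str, float]


@dataclass
class EgcFinding:
    currency: str
    dissipation_flux: float
    reactions: Tuple[str, ...]
    minimality_proven: bool = True


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------


def apply_medium(model: MetabolicModel, medium: Optional[Mapping[str, MediumValue]]) -> MetabolicModel:
    """Return a copy with exchange bounds set from a medium table.

    Every exchange reaction not named in ``medium`` has its lower bound set
    to 0 (no uptake; secretion stays as declared).  Entries are either a
    lower bound (a negative number allows uptake) or an explicit
    ``(lower, upper)`` pair.
    """
    out = model.copy()
    if medium is None:
        return out
    for rid in out.exchanges():
        out.reactions[rid].lower_bound = max(out.reactions[rid].lower_bound, 0.0)
    for rid, value in medium.items():
        if rid not in out.reactions:
            raise ModelError(f"medium names unknown reaction {rid!r}")
        rxn = out.reactions[rid]
        if isinstance(value, (tuple, list)):
            rxn.lower_bound, rxn.upper_bound = float(value[0]), float(value[1])
        else:
            rxn.lower_bound = float(value)
            if rxn.upper_bound < rxn.lower_bound:
                rxn.upper_bound = rxn.lower_bound
    return out


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(model: MetabolicModel, objective: Tuple[str, str]) -> FluxResult:
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    obj_rid, direction = objective
    if obj_rid not in model.reactions:
        raise ModelError(f"objective reaction {obj_rid!r} not in model")
    c = np.zeros(n)
    sign = -1.0 if direction == "max" else 1.0
    c[rxn_ids.index(obj_rid)] = sign
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    res = linprog(
        c,
        A_eq=sp.csr_matrix(S) if n else None,
        b_eq=np.zeros(len(met_ids)) if n else None,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxResult(status=status, objective_value=None)
    fluxes = dict(zip(rxn_ids, res.x))
    # Duals of the equality rows.  HiGHS reports d(min obj)/d(rhs); for a
    # maximization the true objective is the negation, so the sign flips.
    marginals = np.asarray(res.eqlin.marginals)
    duals = marginals if direction == "min" else -marginals
    shadow = dict(zip(met_ids, duals))
    value = res.fun if direction == "min" else -res.fun
    return FluxResult(status="optimal", objective_value=float(value),
                      fluxes=fluxes, shadow_prices=shadow)


def fba(
    model: MetabolicModel,
    medium: Optional[Mapping[str, MediumValue]] = None,
    objective: Optional[Tuple[str, str]] = None,
) -> FluxResult:
    """Solve an FBA problem; returns status, objective, fluxes, shadow prices."""
    constrained = apply_medium(model, medium)
    obj = objective or constrained.objective
    if obj is None:
        raise ModelError("model has no objective and none was given")
    if isinstance(obj, str):
        obj = (obj, "max")
    return _solve(constrained, obj)


# ---------------------------------------------------------------------------
# Biomass precursor diagnosis
# ---------------------------------------------------------------------------


@dataclass
class PrecursorDiagnosis:
    metabolite: str
    producible: bool
    max_flux: float
    blocking_dead_ends: Tuple[str, ...] = ()


def _upstream_metabolites(model: MetabolicModel, target: str) -> Set[str]:
    """Metabolites reachable backwards from ``target`` through reactions."""
    producers: Dict[str, List[Reaction]] = {}
    for rxn in model.reactions.values():
        for met, coef in rxn.stoichiometry.items():
            if (coef > 0 and rxn.upper_bound > 0) or (coef < 0 and rxn.lower_bound < 0):
                producers.setdefault(met, []).append(rxn)
    seen = {target}
    stack = [target]
    while stack:
        met = stack.pop()
        for rxn in producers.get(met, []):
            for other, coef in rxn.stoichiometry.items():
                consumed_fwd = coef < 0 and rxn.upper_bound > 0
                consumed_rev = coef > 0 and rxn.lower_bound < 0
                if (consumed_fwd or consumed_rev) and other not in seen:
                    seen.add(other)
                    stack.append(other)
    return seen


def diagnose_precursors(
    model: MetabolicModel,
    biomass_id: Optional[str] = None,
    medium: Optional[Mapping[str, MediumValue]] = None,
    tol: float = GROWTH_TOL,
) -> List[PrecursorDiagnosis]:
    """Test producibility of every consumed biomass precursor.

    For each metabolite with a negative biomass coefficient, a temporary
    demand is maximized; the precursor is producible iff its maximum
    synthesis flux exceeds ``tol``.  For blocked precursors the dead-end
    metabolites lying upstream are listed as evidence.
    """
    from .curation import dead_end_report  # local import to avoid a cycle

    if biomass_id is None:
        if model.objective is None:
            raise ModelError("no biomass reaction given and no objective set")
        biomass_id = model.objective[0]
    biomass = model.reactions[biomass_id]
    precursors = [m for m, c in biomass.stoichiometry.items() if c < 0]
    base = apply_medium(model, medium)
    base.reactions[biomass_id].lower_bound = 0.0
    base.reactions[biomass_id].upper_bound = 0.0
    dead_ends = {d.metabolite_id for d in dead_end_report(base)}
    out: List[PrecursorDiagnosis] = []
    for met in precursors:
        probe = base.copy()
        probe.add_reaction(
            Reaction(id="RT_DM__diag", stoichiometry={met: -1.0},
                     lower_bound=0.0, upper_bound=1000.0, kind=ReactionKind.DEMAND)
        )
        res = _solve(probe, ("RT_DM__diag", "max"))
        flux = res.objective_value if res.ok else 0.0
        producible = bool(res.ok and flux > tol)
        evidence: Tuple[str, ...] = ()
        if not producible:
            upstream = _upstream_metabolites(base, met)
            evidence = tuple(sorted(upstream & dead_ends))
        out.append(PrecursorDiagnosis(met, producible, float(flux), evidence))
    return out


# ---------------------------------------------------------------------------
# Gene deletions
# ---------------------------------------------------------------------------


def _disabled_reactions(model: MetabolicModel, knocked_out: Set[str]) -> List[str]:
    disabled = []
    for rxn in model.reactions.values():
        if rxn.gpr.is_empty:
            continue
        if not rxn.gpr.genes() & knocked_out:
            continue
        if not rxn.gpr.evaluate(knocked_out):
            disabled.append(rxn.id)
    return disabled


def delete_genes(
    model: MetabolicModel,
    genes: Union[str, Iterable[str]],
    medium: Optional[Mapping[str, MediumValue]] = None,
    reference_growth: Optional[float] = None,
    essentiality_threshold: float = ESSENTIALITY_THRESHOLD,
) -> DeletionResult:
    """Knock out genes, disable unsatisfied reactions, and re-solve growth."""
    if isinstance(genes, str):
        genes = [genes]
    ko = set(genes)
    unknown = ko - set(model.genes)
    if unknown:
        raise ModelError(f"unknown genes: {sorted(unknown)}")
    constrained = apply_medium(model, medium)
    if reference_growth is None:
        ref = _solve(constrained, constrained.objective)
        if not ref.ok:
            raise ModelError("reference FBA is not feasible on this medium")
        reference_growth = ref.objective_value
    disabled = _disabled_reactions(constrained, ko)
    for rid in disabled:
        constrained.reactions[rid].lower_bound = 0.0
        constrained.reactions[rid].upper_bound = 0.0
    res = _solve(constrained, constrained.objective)
    growth = res.objective_value if res.ok else 0.0
    growth = max(growth, 0.0)
    ratio = growth / reference_growth if reference_growth > GROWTH_TOL else 0.0
    return DeletionResult(
        genes=tuple(sorted(ko)),
        disabled_reactions=tuple(sorted(disabled)),
        growth=float(growth),
        growth_ratio=float(ratio),
        essential=bool(ratio < essentiality_threshold),
    )


def single_gene_deletions(
    model: MetabolicModel,
    medium: Optional[Mapping[str, MediumValue]] = None,
    genes: Optional[Sequence[str]] = None,
    essentiality_threshold: float = ESSENTIALITY_THRESHOLD,
) -> Dict[str, DeletionResult]:
    """Delete each gene singly; genes disabling no reaction reuse the reference."""
    constrained = apply_medium(model, medium)
    ref = _solve(constrained, constrained.objective)
    if not ref.ok:
        raise ModelError("reference FBA is not feasible on this medium")
    ref_growth = ref.objective_value
    targets = list(genes) if genes is not None else list(model.genes)
    out: Dict[str, DeletionResult] = {}
    for gene in targets:
        disabled = _disabled_reactions(constrained, {gene})
        if not disabled:
            out[gene] = DeletionResult((gene,), (), float(ref_growth), 1.0,
                                       essential=1.0 < essentiality_threshold)
            continue
        out[gene] = delete_genes(
            constrained, gene, medium=None, reference_growth=ref_growth,
            essentiality_threshold=essentiality_threshold,
        )
    return out


def flux_variability(
    model: MetabolicModel,
    reactions: Optional[Sequence[str]] = None,
    medium: Optional[Mapping[str, MediumValue]] = None,
    fraction_of_optimum: float = 0.0,
) -> Dict[str, Tuple[float, float]]:
    """Min/max attainable flux per reaction (optionally at a growth fraction)."""
    constrained = apply_medium(model, medium)
    if fraction_of_optimum > 0:
        if constrained.objective is None:
            raise ModelError("fraction_of_optimum requires an objective")
        ref = _solve(constrained, constrained.objective)
        if not ref.ok:
            raise ModelError("reference FBA infeasible")
        obj = constrained.reactions[constrained.objective[0]]
        obj.lower_bound = max(obj.lower_bound, fraction_of_optimum * ref.objective_value)
    targets = list(reactions) if reactions is not None else list(constrained.reactions)
    out: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        lo = _solve(constrained, (rid, "min"))
        hi = _solve(constrained, (rid, "max"))
        out[rid] = (
            lo.objective_value if lo.ok else np.nan,
            hi.objective_value if hi.ok else np.nan,
        )
    return out


# ---------------------------------------------------------------------------
# Energy-generating cycle detection
# ---------------------------------------------------------------------------


def default_currency_specs(model: MetabolicModel) -> List[CurrencySpec]:
    """Dissipation specs for ATP, GTP, NAD(P)H, FADH2 and the mitochondrial
    proton gradient, restricted to species present in the model."""
    candidates = [
        CurrencySpec("ATP", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}),
        CurrencySpec("GTP", {"gtp_c": -1, "h2o_c": -1, "gdp_c": 1, "pi_c": 1, "h_c": 1}),
        CurrencySpec("NADH", {"nadh_c": -1, "nad_c": 1, "h_c": 1}),
        CurrencySpec("NADPH", {"nadph_c": -1, "nadp_c": 1, "h_c": 1}),
        CurrencySpec("FADH2", {"fadh2_c": -1, "fad_c": 1, "h_c": 2}),
        CurrencySpec("proton_gradient_mito", {"h_c": -1, "h_m": 1}),
    ]
    return [
        spec for spec in candidates
        if all(m in model.metabolites for m in spec.stoichiometry)
    ]


_DISS_ID = "RT_EGC_DISSIPATION"


def _closed_model(model: MetabolicModel) -> MetabolicModel:
    closed = model.copy()
    for rid in closed.boundary_reactions():
        closed.reactions[rid].lower_bound = 0.0
        closed.reactions[rid].upper_bound = 0.0
    # forced fluxes (e.g. a maintenance floor) would make the closed system
    # infeasible and mask real cycles; relax them to zero
    for rxn in closed.reactions.values():
        if rxn.lower_bound > 0:
            rxn.lower_bound = 0.0
        if rxn.upper_bound < 0:
            rxn.upper_bound = 0.0
    return closed


def find_egc(
    model: MetabolicModel,
    currencies: Optional[Sequence[CurrencySpec]] = None,
    flux_epsilon: float = 1e-4,
    tol: float = GROWTH_TOL,
    time_limit: float = 60.0,
) -> List[EgcFinding]:
    """Detect energy-generating cycles per currency.

    All exchange/demand/sink/biomass bounds are closed, a dissipation
    reaction is added, and its flux maximized.  If dissipation is possible,
    a MIP minimizes the number of reactions with ``|v| > flux_epsilon``
    subject to dissipation >= 1 (big-M linking with M set from the largest
    bound), returning the minimal active reaction set.
    """
    if currencies is None:
        currencies = default_currency_specs(model)
    findings: List[EgcFinding] = []
    for spec in currencies:
        missing = [m for m in spec.stoichiometry if m not in model.metabolites]
        if missing:
            raise ModelError(f"currency {spec.name!r}: unknown metabolites {missing}")
        closed = _closed_model(model)
        closed.add_reaction(
            Reaction(id=_DISS_ID, stoichiometry=dict(spec.stoichiometry),
                     lower_bound=0.0, upper_bound=1000.0, kind=ReactionKind.DEMAND)
        )
        probe = _solve(closed, (_DISS_ID, "max"))
        if not probe.ok or probe.objective_value <= tol:
            continue
        members, proven = _minimal_active_set(closed, spec, flux_epsilon, time_limit)
        findings.append(
            EgcFinding(currency=spec.name,
                       dissipation_flux=float(probe.objective_value),
                       reactions=tuple(sorted(members)),
                       minimality_proven=proven)
        )
    return findings


def _minimal_active_set(
    closed: MetabolicModel, spec: CurrencySpec, flux_epsilon: float, time_limit: float
) -> Tuple[List[str], bool]:
    S, met_ids, rxn_ids = closed.stoichiometric_matrix()
    n = len(rxn_ids)
    diss_idx = rxn_ids.index(_DISS_ID)
    internal = [j for j, rid in enumerate(rxn_ids)
                if rid != _DISS_ID and not closed.reactions[rid].is_boundary]
    k = len(internal)
    lb = np.array([closed.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([closed.reactions[r].upper_bound for r in rxn_ids])
    big_m = max(1.0, float(np.max(np.abs(np.concatenate([lb, ub])))))

    # variables: v (n continuous), y (k binary)
    nv = n + k
    c = np.zeros(nv)
    c[n:] = 1.0

    rows = []
    # steady state
    A_eq = sp.hstack([sp.csr_matrix(S), sp.csr_matrix((len(met_ids), k))])
    rows.append(LinearConstraint(A_eq, 0.0, 0.0))
    # dissipation >= 1
    a = np.zeros(nv)
    a[diss_idx] = 1.0
    rows.append(LinearConstraint(a, 1.0, np.inf))
    # |v_i| <= M y_i for internal reactions
    data, ri, ci = [], [], []
    for row, j in enumerate(internal):
        data += [1.0, -big_m]
        ri += [row, row]
        ci += [j, n + row]
    A_pos = sp.csr_matrix((data, (ri, ci)), shape=(k, nv))
    rows.append(LinearConstraint(A_pos, -np.inf, 0.0))
    data, ri, ci = [], [], []
    for row, j in enumerate(internal):
        data += [-1.0, -big_m]
        ri += [row, row]
        ci += [j, n + row]
    A_neg = sp.csr_matrix((data, (ri, ci)), shape=(k, nv))
    rows.append(LinearConstraint(A_neg, -np.inf, 0.0))

    var_lb = np.concatenate([lb, np.zeros(k)])
    var_ub = np.concatenate([ub, np.ones(k)])
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    res = milp(
        c=c,
        constraints=rows,
        bounds=OptBounds(var_lb, var_ub),
        integrality=integrality,
        options={"time_limit": time_limit},
    )
    if res.status not in (0,) or res.x is None:
        # fall back: report every active reaction in the LP relaxation
        probe = _solve(closed, (_DISS_ID, "max"))
        members = [rid for rid, v in probe.fluxes.items()
                   if rid != _DISS_ID and abs(v) > flux_epsilon
                   and not closed.reactions[rid].is_boundary]
        return members, False
    v = res.x[:n]
    members = [rxn_ids[j] for row, j in enumerate(internal)
               if res.x[n + row] > 0.5 and abs(v[j]) > flux_epsilon]
    return members, True
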