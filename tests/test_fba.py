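"""LP core, shadow prices, deletions and cycle detection."""

import itertools

import numpy as np
import pytest

from gsmforge.core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionKind,
)
from gsmforge.fba import (
    CurrencySpec,
    delete_genes,
    diagnose_precursors,
    fba,
    find_egc,
    flux_variability,
    single_gene_deletions,
)

from conftest import make_toy_chain


# ---------------------------------------------------------------------------
# FBA basics
# ---------------------------------------------------------------------------


def test_single_bottleneck_chain_hits_uptake_limit(toy_chain):
    res = fba(toy_chain, medium={"EX_A_e": -10.0})
    assert res.ok
    assert res.objective_value == pytest.approx(10.0)


def test_closed_required_uptake_gives_zero_growth(toy_chain):
    res = fba(toy_chain, medium={"EX_A_e": 0.0})
    assert res.ok
    assert res.objective_value == pytest.approx(0.0)


def test_forced_flux_with_closed_medium_is_infeasible(toy_chain):
    toy_chain.reactions["BIOMASS"].lower_bound = 1.0
    res = fba(toy_chain, medium={"EX_A_e": 0.0})
    assert res.status == "infeasible"


def test_steady_state_and_bounds_hold_at_optimum(demo, media):
    res = fba(demo, medium=media["glucose"])
    assert res.ok
    S, mets, rxns = demo.stoichiometric_matrix()
    v = np.array([res.fluxes[r] for r in rxns])
    assert np.abs(S @ v).max() < 1e-6


def test_shadow_price_sensitivity_identity(toy_chain):
    """Duality: d(objective)/d(uptake bound) equals the boundary shadow
    price chain on a non-degenerate toy."""
    base = fba(toy_chain, medium={"EX_A_e": -10.0})
    bumped = fba(toy_chain, medium={"EX_A_e": -10.0 - 1e-3})
    dobj = bumped.objective_value - base.objective_value
    # relaxing A_e's balance by one unit is worth one unit of biomass here
    assert base.shadow_prices["A_e"] == pytest.approx(-dobj / 1e-3, abs=1e-4)


# ---------------------------------------------------------------------------
# Brute-force polytope oracle
# ---------------------------------------------------------------------------


def _enumerate_vertices(S, lb, ub):
    """All vertices of {S v = 0, lb <= v <= ub} by active-set enumeration."""
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    free_count = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), free_count):
        free = [j for j in range(n) if j not in fixed]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(choice) if fixed else np.zeros(S.shape[0])
            A = S[:, free]
            if free and np.linalg.matrix_rank(A) < len(free):
                continue
            sol, residual, *_ = np.linalg.lstsq(A, rhs, rcond=None) if free else (np.array([]), None)
            v = np.zeros(n)
            for j, val in zip(fixed, choice):
                v[j] = val
            for j, val in zip(free, sol):
                v[j] = val
            if np.abs(S @ v).max() > 1e-8:
                continue
            if (v < lb - 1e-8).any() or (v > ub + 1e-8).any():
                continue
            vertices.append(v)
    return vertices


def test_lp_objective_matches_vertex_enumeration_on_random_networks():
    """On 200 random networks (<=6 reactions, finite bounds) the LP optimum
    equals the best vertex of the flux polytope within 1e-6."""
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(200):
        n_rxn = int(rng.integers(2, 7))
        n_met = int(rng.integers(1, 4))
        S = rng.integers(-2, 3, size=(n_met, n_rxn)).astype(float)
        lb = np.where(rng.random(n_rxn) < 0.5, -10.0, 0.0)
        ub = np.full(n_rxn, 10.0)
        model = MetabolicModel(id="rand")
        model.compartments = {"c": ""}
        for i in range(n_met):
            model.add_metabolite(Metabolite(id=f"m{i}_c", compartment="c"))
        for j in range(n_rxn):
            stoich = {f"m{i}_c": S[i, j] for i in range(n_met) if S[i, j] != 0}
            model.add_reaction(Reaction(
                id=f"r{j}", stoichiometry=stoich, lower_bound=lb[j],
                upper_bound=ub[j],
                kind=ReactionKind.EXCHANGE if not stoich else ReactionKind.METABOLIC))
        obj = f"r{int(rng.integers(0, n_rxn))}"
        res = fba(model, objective=(obj, "max"))
        vertices = _enumerate_vertices(S, lb, ub)
        if not vertices:
            assert res.status in ("infeasible", "optimal")
            continue
        j_obj = int(obj[1:])
        best = max(v[j_obj] for v in vertices)
        assert res.ok
        assert res.objective_value == pytest.approx(best, abs=1e-6)
        checked += 1
    assert checked >= 100  # the vast majority of draws exercise the oracle


# ---------------------------------------------------------------------------
# Precursor diagnosis
# ---------------------------------------------------------------------------


def test_constructed_block_is_flagged_non_producible(toy_chain):
    toy_chain.reactions["AB"].upper_bound = 0.0  # sever the only route to B
    diags = {d.metabolite: d for d in diagnose_precursors(
        toy_chain, medium={"EX_A_e": -10.0})}
    assert not diags["B_c"].producible
    assert diags["B_c"].max_flux == pytest.approx(0.0, abs=1e-9)


def test_all_precursors_producible_on_open_toy(toy_chain):
    diags = diagnose_precursors(toy_chain, medium={"EX_A_e": -10.0})
    assert all(d.producible for d in diags)


def test_blocked_precursor_lists_upstream_dead_end(toy_chain):
    toy_chain.reactions["At"].upper_bound = 0.0  # A_c unreachable
    diags = {d.metabolite: d for d in diagnose_precursors(
        toy_chain, medium={"EX_A_e": -10.0})}
    assert not diags["B_c"].producible
    assert "A_c" in diags["B_c"].blocking_dead_ends or "B_c" in diags["B_c"].blocking_dead_ends


# ---------------------------------------------------------------------------
# Gene deletions
# ---------------------------------------------------------------------------


def test_isozyme_deletion_keeps_reaction_open():
    from gsmforge.core import Gene, parse_gpr

    m = make_toy_chain()
    m.reactions["AB"].gpr = parse_gpr("g1 or g")
    m.genes = {g: Gene(g) for g in m.reactions["AB"].gpr.genes()}
    res = delete_genes(m, "g", medium={"EX_A_e": -10.0})
    assert res.growth_ratio == pytest.approx(1.0)
    assert not res.essential


def test_sole_pathway_gene_deletion_kills_growth(toy_chain):
    res = delete_genes(toy_chain, "g1", medium={"EX_A_e": -10.0})
    assert res.growth == pytest.approx(0.0, abs=1e-9)
    assert res.essential
    assert res.disabled_reactions == ("AB",)


def test_unknown_gene_raises(toy_chain):
    with pytest.raises(ModelError):
        delete_genes(toy_chain, "nope", medium={"EX_A_e": -10.0})


def test_deleting_superset_never_increases_growth(demo, media):
    medium = media["D-xylose"]
    singles = {g: delete_genes(demo, g, medium=medium).growth
               for g in ["9990", "9837", "8905"]}
    pair = delete_genes(demo, ["9837", "8905"], medium=medium).growth
    triple = delete_genes(demo, ["9990", "9837", "8905"], medium=medium).growth
    assert pair <= min(singles["9837"], singles["8905"]) + 1e-6
    assert triple <= pair + 1e-6


def test_single_deletions_match_cobra_oracle(demo, media):
    """All single deletions of the pathway genes agree with an independent
    COBRA implementation of GPR-masked FBA on the same model and medium."""
    cobra = pytest.importorskip("cobra")
    from gsmforge.fba import apply_medium

    medium = media["D-xylose"]
    constrained = apply_medium(demo, medium)

    cm = cobra.Model("demo")
    for met in constrained.metabolites.values():
        cmet = cobra.Metabolite(met.id, compartment=met.compartment or "c")
        cm.add_metabolites([cmet])
    for rxn in constrained.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cm.add_reactions([cr])
        cr.add_metabolites({cm.metabolites.get_by_id(m): c
                            for m, c in rxn.stoichiometry.items()})
        cr.bounds = (rxn.lower_bound, rxn.upper_bound)
        cr.gene_reaction_rule = rxn.gpr.to_string()
    cm.objective = "RT_BIOMASS"

    ref = cm.slim_optimize()
    table_genes = [g for g in demo.genes if not g.startswith("200")]
    ours = single_gene_deletions(demo, medium=medium, genes=table_genes)
    for gene in table_genes:
        with cm as scoped:
            scoped.genes.get_by_id(gene).knock_out()
            growth = scoped.slim_optimize()
        growth = 0.0 if growth is None or np.isnan(growth) else max(growth, 0.0)
        assert ours[gene].growth == pytest.approx(growth, abs=1e-5), gene


# ---------------------------------------------------------------------------
# Energy-generating cycles
# ---------------------------------------------------------------------------


def _loop_instance():
    """A tiny closed network with a 3-reaction proton pump/leak loop plus
    decoys — small enough for exhaustive subset search."""
    m = MetabolicModel(id="egc_toy")
    m.compartments = {"c": "", "m": ""}
    for mid, comp in [("h_c", "c"), ("h_m", "m"), ("a_c", "c"), ("b_c", "c"),
                      ("c_c", "c"), ("d_c", "c")]:
        m.add_metabolite(Metabolite(id=mid, compartment=comp,
                                    formula={"H": 1}, charge=0))
    m.add_reaction(Reaction(id="PUMP", stoichiometry={
        "a_c": -1, "h_m": -1, "b_c": 1, "h_c": 1}, lower_bound=0, upper_bound=100))
    m.add_reaction(Reaction(id="ISOM", stoichiometry={"b_c": -1, "c_c": 1},
                            lower_bound=0, upper_bound=100))
    m.add_reaction(Reaction(id="RESET", stoichiometry={"c_c": -1, "a_c": 1},
                            lower_bound=0, upper_bound=100))
    # decoys that cannot sustain the loop
    m.add_reaction(Reaction(id="DECOY1", stoichiometry={"c_c": -1, "d_c": 1},
                            lower_bound=0, upper_bound=100))
    m.add_reaction(Reaction(id="DECOY2", stoichiometry={"d_c": -1, "b_c": 1},
                            lower_bound=0, upper_bound=100))
    return m


def _exhaustive_minimal_sets(model, spec):
    """Oracle: smallest reaction subsets sustaining dissipation >= 1 with
    everything else closed."""
    from gsmforge.fba import _DISS_ID, _closed_model, _solve

    closed = _closed_model(model)
    closed.add_reaction(Reaction(id=_DISS_ID, stoichiometry=dict(spec.stoichiometry),
                                 lower_bound=0, upper_bound=1000,
                                 kind=ReactionKind.DEMAND))
    internal = [r for r in closed.reactions if r != _DISS_ID]
    best = []
    for size in range(1, len(internal) + 1):
        for subset in itertools.combinations(internal, size):
            probe = closed.copy()
            for rid in internal:
                if rid not in subset:
                    probe.reactions[rid].lower_bound = 0.0
                    probe.reactions[rid].upper_bound = 0.0
            res = _solve(probe, (_DISS_ID, "max"))
            if res.ok and res.objective_value >= 1.0 - 1e-9:
                best.append(frozenset(subset))
        if best:
            return best
    return best


def test_proton_loop_minimal_set_matches_exhaustive_search():
    model = _loop_instance()
    spec = CurrencySpec("proton_gradient_mito", {"h_c": -1, "h_m": 1})
    findings = find_egc(model, currencies=[spec])
    assert len(findings) == 1
    found = frozenset(findings[0].reactions)
    oracle_sets = _exhaustive_minimal_sets(model, spec)
    assert found in oracle_sets
    assert len(found) == min(len(s) for s in oracle_sets) == 3


def test_removing_a_loop_member_clears_the_finding():
    model = _loop_instance()
    spec = CurrencySpec("proton_gradient_mito", {"h_c": -1, "h_m": 1})
    member = find_egc(model, currencies=[spec])[0].reactions[0]
    model.reactions[member].upper_bound = 0.0
    assert find_egc(model, currencies=[spec]) == []


def test_loop_free_model_reports_nothing(toy_chain):
    spec = CurrencySpec("bogus", {"A_c": -1, "B_c": 1})
    assert find_egc(toy_chain, currencies=[spec]) == []


def test_reported_cycle_replays_with_only_its_members_open():
    """EGC soundness: the loop sustains dissipation >= 1 when only its
    members (and the dissipation probe) are open."""
    from gsmforge.fba import _DISS_ID, _closed_model, _solve

    model = _loop_instance()
    spec = CurrencySpec("proton_gradient_mito", {"h_c": -1, "h_m": 1})
    members = set(find_egc(model, currencies=[spec])[0].reactions)
    closed = _closed_model(model)
    for rid in list(closed.reactions):
        if rid not in members:
            closed.reactions[rid].lower_bound = 0.0
            closed.reactions[rid].upper_bound = 0.0
    closed.add_reaction(Reaction(id=_DISS_ID, stoichiometry=dict(spec.stoichiometry),
                                 lower_bound=0, upper_bound=1000,
                                 kind=ReactionKind.DEMAND))
    res = _solve(closed, (_DISS_ID, "max"))
    assert res.ok and res.objective_value >= 1.0


# ---------------------------------------------------------------------------
# FVA sanity
# ---------------------------------------------------------------------------


def test_flux_variability_bounds_contain_fba_solution(toy_chain):
    res = fba(toy_chain, medium={"EX_A_e": -10.0})
    fva = flux_variability(toy_chain, medium={"EX_A_e": -10.0})
    for rid, (lo, hi) in fva.items():
        assert lo - 1e-9 <= res.fluxes[rid] <= hi + 1e-9
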