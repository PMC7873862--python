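"""Duplicate detection/merging, dead ends, and signature invariances."""

import numpy as np
import pytest

from gsmforge.core import (
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionKind,
    parse_formula,
)
from gsmforge.curation import (
    ChangeLog,
    dead_end_report,
    dedup_reactions,
    find_duplicate_metabolites,
    find_duplicate_reactions,
    merge_metabolites,
    reaction_signature,
)
from gsmforge.fba import flux_variability


def _model(mets, rxns):
    m = MetabolicModel(id="t")
    m.compartments = {"c": "", "m": "", "e": ""}
    for mid, formula, charge in mets:
        comp = mid.rsplit("_", 1)[1]
        m.add_metabolite(Metabolite(
            id=mid, name=mid, compartment=comp,
            formula=parse_formula(formula) if formula else None, charge=charge))
    for spec in rxns:
        m.add_reaction(Reaction(**spec))
    return m


# ---------------------------------------------------------------------------
# Duplicate metabolites
# ---------------------------------------------------------------------------


def test_identical_key_pair_reported():
    m = _model([("a_c", "C6H12O6", 0), ("b_c", "C6H12O6", 0), ("x_c", "C2", -1)], [])
    pairs = [(c.keep_id, c.drop_id) for c in find_duplicate_metabolites(m)]
    assert pairs == [("a_c", "b_c")]


def test_cytochrome_alias_pair_reported_via_alias_table():
    """ficytc/ficytC: the duplicated cytochrome identifiers are matched by
    the alias table even without formulas."""
    m = _model([("ficytc_m", None, None), ("ficytC_m", None, None)], [])
    pairs = find_duplicate_metabolites(m, alias_table={"ficytc_m": "ficytC_m"})
    assert [(p.keep_id, p.drop_id, p.reason) for p in pairs] == [
        ("ficytC_m", "ficytc_m", "alias")]


def test_all_distinct_keys_yield_empty_list():
    m = _model([("a_c", "C6H12O6", 0), ("b_c", "C5H10O5", 0), ("c_c", "C6H12O6", -1)], [])
    assert find_duplicate_metabolites(m) == []


def test_metabolites_without_formulas_only_match_by_alias():
    m = _model([("u_c", None, None), ("v_c", None, None)], [])
    assert find_duplicate_metabolites(m) == []


# ---------------------------------------------------------------------------
# Metabolite merging
# ---------------------------------------------------------------------------


def _merge_model():
    return _model(
        [("a_c", "C2", 0), ("adup_c", "C2", 0), ("b_c", "C2", 0), ("z_m", "C2", 0)],
        [
            dict(id="iso", stoichiometry={"a_c": -1.0, "adup_c": 1.0}),
            dict(id="use", stoichiometry={"adup_c": -1.0, "b_c": 1.0}),
            dict(id="use2", stoichiometry={"a_c": -1.0, "b_c": 1.0}),
        ])


def test_merge_cancels_and_flags_new_duplicates():
    log = ChangeLog()
    merged = merge_metabolites(_merge_model(), "a_c", "adup_c", log=log)
    assert "adup_c" not in merged.metabolites
    # the isomerase a -> adup collapses to nothing and is removed
    assert "iso" not in merged.reactions
    # 'use' now duplicates 'use2' and is flagged
    flags = log.by_operation("duplicate_reaction_flag")
    assert flags and sorted(flags[0].ids) == ["use", "use2"]


def test_cross_compartment_merge_refused():
    with pytest.raises(ModelError):
        merge_metabolites(_merge_model(), "a_c", "z_m")


def test_merge_of_missing_id_errors():
    with pytest.raises(ModelError):
        merge_metabolites(_merge_model(), "a_c", "ghost_c")


def test_merge_preserves_balance_of_untouched_reactions():
    from gsmforge.core import check_balance

    m = _merge_model()
    before = check_balance(m).unbalanced_ids
    merged = merge_metabolites(m, "a_c", "adup_c")
    after = check_balance(merged).unbalanced_ids
    assert [r for r in after if r in m.reactions] == [r for r in before if r in merged.reactions]


# ---------------------------------------------------------------------------
# Duplicate reactions
# ---------------------------------------------------------------------------


def test_reversed_copy_shares_signature_and_groups():
    m = _model(
        [("a_c", "C2", 0), ("b_c", "C2", 0)],
        [
            dict(id="fwd", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                 lower_bound=-1000, upper_bound=1000),
            dict(id="rev", stoichiometry={"a_c": 1.0, "b_c": -1.0},
                 lower_bound=-1000, upper_bound=1000),
        ])
    assert find_duplicate_reactions(m) == [["fwd", "rev"]]


def test_dedup_unions_gprs_with_or_and_widens_bounds():
    m = _model(
        [("a_c", "C2", 0), ("b_c", "C2", 0)],
        [
            dict(id="r1", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                 lower_bound=0, upper_bound=500, gpr="g1"),
            dict(id="r2", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                 lower_bound=-100, upper_bound=200, gpr="g2"),
        ])
    out = dedup_reactions(m)
    assert set(out.reactions) == {"r1"}
    kept = out.reactions["r1"]
    assert kept.gpr.to_string() in ("g1 or g2", "g2 or g1")
    assert (kept.lower_bound, kept.upper_bound) == (-100, 500)


def test_dedup_is_idempotent_and_preserves_flux_cone():
    m = _model(
        [("a_c", "C2", 0), ("a_e", "C2", 0), ("b_c", "C2", 0)],
        [
            dict(id="EX_a", stoichiometry={"a_e": -1.0}, lower_bound=-10,
                 upper_bound=1000, kind=ReactionKind.EXCHANGE),
            dict(id="At", stoichiometry={"a_e": -1.0, "a_c": 1.0},
                 lower_bound=0, upper_bound=1000, kind=ReactionKind.TRANSPORT),
            dict(id="r1", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                 lower_bound=0, upper_bound=1000),
            dict(id="r1copy", stoichiometry={"a_c": -2.0, "b_c": 2.0},
                 lower_bound=0, upper_bound=1000),  # scaled duplicate
            dict(id="DM_b", stoichiometry={"b_c": -1.0}, lower_bound=0,
                 upper_bound=1000, kind=ReactionKind.DEMAND),
        ])
    fva_before = flux_variability(m, reactions=["DM_b", "EX_a"])
    out = dedup_reactions(m)
    again = dedup_reactions(out)
    assert set(out.reactions) == set(again.reactions)
    assert "r1copy" not in out.reactions
    # uptake-limited capacity is unchanged by collapsing the duplicate
    fva_merged = flux_variability(out, reactions=["DM_b", "EX_a"])
    assert fva_merged == pytest.approx(fva_before)


def test_random_model_with_injected_duplicates_finds_exactly_those_groups():
    from gsmforge.synth import UniverseSpec, make_universe

    uni = make_universe(UniverseSpec(seed=7, n_reactions=50, n_target_genes=90,
                                     n_duplicate_reactions=5))
    groups = find_duplicate_reactions(uni.truth)
    assert sorted(groups) == sorted(uni.ledger.duplicate_reaction_groups)
    assert len(groups) == 5


def test_signature_invariant_to_insertion_order():
    rxn_a = Reaction(id="x", stoichiometry={"a_c": -1.0, "b_c": 2.0, "c_c": 1.0})
    rxn_b = Reaction(id="y", stoichiometry={"c_c": 1.0, "a_c": -1.0, "b_c": 2.0})
    assert reaction_signature(rxn_a)[1:] == reaction_signature(rxn_b)[1:]


# ---------------------------------------------------------------------------
# Dead ends
# ---------------------------------------------------------------------------


def test_chain_terminus_is_only_produced():
    m = _model(
        [("a_c", "C2", 0), ("b_c", "C2", 0)],
        [dict(id="ab", stoichiometry={"a_c": -1.0, "b_c": 1.0},
              lower_bound=0, upper_bound=10),
         dict(id="EX_a", stoichiometry={"a_c": -1.0}, lower_bound=-10,
              upper_bound=10, kind=ReactionKind.EXCHANGE)])
    report = {d.metabolite_id: d.role for d in dead_end_report(m)}
    assert report == {"b_c": "only-produced"}


def test_fully_exchanged_model_has_empty_report(toy_chain):
    assert dead_end_report(toy_chain) == []


def test_disconnected_metabolite_reported():
    m = _model([("a_c", "C2", 0), ("lonely_c", "C2", 0)],
               [dict(id="EX_a", stoichiometry={"a_c": -1.0}, lower_bound=-1,
                     upper_bound=1, kind=ReactionKind.EXCHANGE)])
    report = {d.metabolite_id: d.role for d in dead_end_report(m)}
    assert report == {"lonely_c": "disconnected"}


def test_dead_end_report_matches_bipartite_graph_oracle(demo):
    """Classification agrees with a networkx-based traversal of the
    metabolite/reaction bipartite graph (reversibility honored)."""
    import networkx as nx

    G = nx.DiGraph()
    for rxn in demo.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met, coef in rxn.stoichiometry.items():
            produced = (coef > 0 and fwd) or (coef < 0 and rev)
            consumed = (coef < 0 and fwd) or (coef > 0 and rev)
            if produced:
                G.add_edge(rxn.id, met)
            if consumed:
                G.add_edge(met, rxn.id)
    oracle = {}
    for met in demo.metabolites:
        has_producer = met in G and G.in_degree(met) > 0
        has_consumer = met in G and G.out_degree(met) > 0
        if not has_producer and not has_consumer:
            oracle[met] = "disconnected"
        elif has_producer and not has_consumer:
            oracle[met] = "only-produced"
        elif has_consumer and not has_producer:
            oracle[met] = "only-consumed"
    ours = {d.metabolite_id: d.role for d in dead_end_report(demo)}
    assert ours == oracle
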