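"""Formula arithmetic, GPR logic, matrix assembly and balance audits."""

import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmforge.core import (
    FormulaError,
    GprExpr,
    GprParseError,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
    ReactionKind,
    check_balance,
    evaluate_gpr,
    format_formula,
    parse_formula,
    parse_gpr,
)


# ---------------------------------------------------------------------------
# Chemical formulas
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("text,expected", [
    ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
    ("H2O", {"H": 2, "O": 1}),
    ("HO4P", {"H": 1, "O": 4, "P": 1}),
    ("C10H12N5O13P3", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}),
    ("R", {"R": 1}),           # pseudo-element: lumped acyl chain
    ("C2RX3", {"C": 2, "R": 1, "X": 3}),
    ("NaCl", {"Na": 1, "Cl": 1}),
])
def test_parse_formula_examples(text, expected):
    assert parse_formula(text) == expected


def test_coenzyme_a_formula_roundtrip_against_character_scan():
    """The CoA backbone parses to 7 elements and round-trips exactly."""
    text = "C21H36N7O16P3S"
    parsed = parse_formula(text)
    # independent oracle: scan characters and accumulate counts by hand
    oracle = {}
    i = 0
    while i < len(text):
        sym = text[i]
        i += 1
        digits = ""
        while i < len(text) and text[i].isdigit():
            digits += text[i]
            i += 1
        oracle[sym] = oracle.get(sym, 0) + (int(digits) if digits else 1)
    assert parsed == oracle
    assert len(parsed) == 6  # C, H, N, O, P, S
    assert format_formula(parsed) == text


@pytest.mark.parametrize("bad", ["C6H12O6!", "c6", "1H2", "C-3", "Xx$"])
def test_malformed_formulas_raise(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


@given(st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "P", "S", "Fe", "Na", "R", "X"]),
    st.integers(min_value=1, max_value=99), min_size=1, max_size=6))
@settings(max_examples=200, deadline=None)
def test_formula_roundtrip_property(counts):
    """parse(format(m)) == m for any element map (Hill-order serialization)."""
    assert parse_formula(format_formula(counts)) == counts


def test_hill_order_carbon_first_then_alphabetical():
    assert format_formula({"O": 6, "C": 6, "H": 12}) == "C6H12O6"
    assert format_formula({"P": 1, "O": 4, "H": 1}) == "HO4P"  # no carbon: alphabetical


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("rule,ko,expected", [
    ("(g1 and g2) or g3", {"g1"}, True),     # g3 branch survives
    ("g1 and g2", {"g2"}, False),
    ("", set(), True),                        # empty rule: no gene requirement
    ("g1 or g2", {"g1", "g2"}, False),
    ("g1 AND g2", set(), True),               # keywords case-insensitive
])
def test_gpr_evaluation_examples(rule, ko, expected):
    assert evaluate_gpr(parse_gpr(rule), ko) is expected


def test_gpr_precedence_and_binds_tighter_than_or():
    expr = parse_gpr("a and b or c")
    # (a and b) or c: knocking out a alone leaves c
    assert expr.evaluate({"a"})
    assert not expr.evaluate({"a", "c"})


@pytest.mark.parametrize("bad", ["(g1 and g2", "g1 and", "and g1", "g1 ) g2", "g1 g2 or"])
def test_gpr_parse_errors_report_position(bad):
    with pytest.raises(GprParseError) as err:
        parse_gpr(bad)
    assert "position" in str(err.value)


_RULES_4 = [
    "a", "a or b", "a and b", "(a and b) or c", "(a or b) and (c or d)",
    "a and (b or (c and d))", "((a and b) or (c and d))",
    "a or (b and c) or d", "a and b and c and d",
]


@pytest.mark.parametrize("rule", _RULES_4)
def test_gpr_matches_truth_table_enumeration(rule):
    """Evaluation equals brute-force truth tables over all knockout subsets."""
    expr = parse_gpr(rule)
    genes = sorted(expr.genes())

    def brute(text, alive):
        # oracle: substitute and eval with Python's own boolean operators
        py = re.sub(r"\b(?!and\b|or\b)(\w+)\b",
                    lambda m: str(m.group(1) in alive), text)
        return eval(py)

    for r in range(len(genes) + 1):
        for ko in itertools.combinations(genes, r):
            alive = set(genes) - set(ko)
            assert expr.evaluate(set(ko)) == brute(rule, alive), (rule, ko)


def test_gpr_serialization_roundtrip():
    for rule in _RULES_4:
        expr = parse_gpr(rule)
        again = parse_gpr(expr.to_string())
        genes = sorted(expr.genes())
        for r in range(len(genes) + 1):
            for ko in itertools.combinations(genes, r):
                assert expr.evaluate(set(ko)) == again.evaluate(set(ko))


def test_gpr_dnf_branches_are_minimal_satisfying_sets():
    expr = parse_gpr("(a and b) or a")
    assert expr.to_dnf() == [frozenset({"a"})]
    expr = parse_gpr("(a or b) and c")
    assert sorted(expr.to_dnf(), key=sorted) == [frozenset({"a", "c"}), frozenset({"b", "c"})]


# ---------------------------------------------------------------------------
# Model assembly and stoichiometric matrix
# ---------------------------------------------------------------------------


def _two_met_model():
    m = MetabolicModel(id="t")
    m.compartments = {"c": "cytosol"}
    m.add_metabolite(Metabolite(id="a_c", formula={"C": 1}, charge=0, compartment="c"))
    m.add_metabolite(Metabolite(id="b_c", formula={"C": 1}, charge=0, compartment="c"))
    return m


def test_matrix_shape_and_exchange_column():
    m = _two_met_model()
    m.add_reaction(Reaction(id="EX_a", stoichiometry={"a_c": -1.0},
                            kind=ReactionKind.EXCHANGE))
    m.add_reaction(Reaction(id="ab", stoichiometry={"a_c": -1.0, "b_c": 1.0}))
    S, mets, rxns = m.stoichiometric_matrix()
    assert S.shape == (2, 2)
    ex_col = S[:, rxns.index("EX_a")]
    assert np.count_nonzero(ex_col) == 1


def test_undeclared_metabolite_and_duplicate_ids_rejected():
    m = _two_met_model()
    with pytest.raises(ModelError):
        m.add_reaction(Reaction(id="bad", stoichiometry={"zzz_c": -1.0}))
    with pytest.raises(ModelError):
        m.add_metabolite(Metabolite(id="a_c", compartment="c"))


def test_reaction_with_inverted_bounds_rejected():
    with pytest.raises(ModelError):
        Reaction(id="r", stoichiometry={"a_c": -1.0}, lower_bound=5, upper_bound=1)


# ---------------------------------------------------------------------------
# Balance audit
# ---------------------------------------------------------------------------


def _hexokinase_model(omit_water_in=None):
    m = MetabolicModel(id="bal")
    m.compartments = {"c": "cytosol"}
    species = {
        "glc__D_c": ("C6H12O6", 0), "atp_c": ("C10H12N5O13P3", -4),
        "g6p_c": ("C6H11O9P", -2), "adp_c": ("C10H12N5O10P2", -3),
        "h_c": ("H", 1), "h2o_c": ("H2O", 0), "pi_c": ("HO4P", -2),
    }
    for mid, (formula, charge) in species.items():
        m.add_metabolite(Metabolite(id=mid, formula=parse_formula(formula),
                                    charge=charge, compartment="c"))
    m.add_reaction(Reaction(id="HEX", stoichiometry={
        "glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1}))
    hydrolysis = {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}
    if omit_water_in:
        del hydrolysis["h2o_c"]
    m.add_reaction(Reaction(id="ATPH", stoichiometry=hydrolysis))
    return m


def test_correct_phosphorylation_and_hydrolysis_are_balanced():
    """Hand-summed elements/charges agree: glucose + ATP -> G6P + ADP + H."""
    report = check_balance(_hexokinase_model())
    assert report.is_clean


def test_omitted_water_reports_H2_O1_deficit():
    """A condensation written without its water product nets {H:-2, O:-1};
    the hydrolysis direction missing its water reactant nets the mirror."""
    m = _hexokinase_model()
    m.add_reaction(Reaction(id="ATPSYN_NOWATER", stoichiometry={
        "adp_c": -1, "pi_c": -1, "h_c": -1, "atp_c": 1}))
    report = check_balance(m)
    assert report.unbalanced_ids == ["ATPSYN_NOWATER"]
    assert report.imbalances[0].element_net == {"H": -2.0, "O": -1.0}

    report2 = check_balance(_hexokinase_model(omit_water_in="ATPH"))
    assert report2.unbalanced_ids == ["ATPH"]
    assert report2.imbalances[0].element_net == {"H": 2.0, "O": 1.0}


def test_empty_model_yields_empty_report():
    assert check_balance(MetabolicModel()).is_clean


def test_missing_formula_reported_unauditable_not_skipped():
    m = _two_met_model()
    m.metabolites["a_c"].formula = None
    m.add_reaction(Reaction(id="ab", stoichiometry={"a_c": -1.0, "b_c": 1.0}))
    report = check_balance(m)
    assert report.unauditable_ids == ["ab"]
    assert "a_c" in report.imbalances[0].missing


def test_boundary_kinds_exempt_from_audit():
    m = _two_met_model()
    for rid, kind in [("EX_a", ReactionKind.EXCHANGE), ("DM_a", ReactionKind.DEMAND),
                      ("SK_a", ReactionKind.SINK)]:
        m.add_reaction(Reaction(id=rid, stoichiometry={"a_c": -1.0}, kind=kind))
    assert check_balance(m).is_clean


def test_balance_audit_is_local_to_each_reaction():
    """Adding a balanced reaction never changes other reactions' verdicts."""
    m = _hexokinase_model(omit_water_in="ATPH")
    before = {r.reaction_id: r.element_net for r in check_balance(m).imbalances}
    # glucose-6-phosphatase: balanced (G6P + H2O -> glucose + Pi)
    m.add_reaction(Reaction(id="G6PASE", stoichiometry={
        "g6p_c": -1, "h2o_c": -1, "glc__D_c": 1, "pi_c": 1}))
    after = {r.reaction_id: r.element_net for r in check_balance(m).imbalances}
    assert before == after


def test_fractional_coefficients_use_tolerance():
    m = _two_met_model()
    m.metabolites["a_c"].formula = parse_formula("C2")
    m.metabolites["b_c"].formula = parse_formula("C1")
    m.add_reaction(Reaction(id="half", stoichiometry={"a_c": -0.5, "b_c": 1.0 + 1e-9}))
    assert check_balance(m).is_clean
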