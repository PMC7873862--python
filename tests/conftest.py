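import pytest

from gsmforge.core import (
    GprExpr,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
    parse_formula,
)
from gsmforge.fixture import demo_media, demo_model


@pytest.fixture(scope="session")
def demo():
    """The packaged demo network (session-scoped: building it is cheap but
    the audits that use it are not)."""
    return demo_model()


@pytest.fixture(scope="session")
def media():
    return demo_media()


def make_toy_chain(with_exchanges: bool = True) -> MetabolicModel:
    """EX_A -> A -> B -> biomass, single bottleneck at 10."""
    m = MetabolicModel(id="toy_chain")
    m.compartments = {"c": "cytosol", "e": "extracellular"}
    for mid, comp in [("A_e", "e"), ("A_c", "c"), ("B_c", "c")]:
        m.add_metabolite(Metabolite(id=mid, name=mid, formula=parse_formula("C2H4O2"),
                                    charge=0, compartment=comp))
    if with_exchanges:
        m.add_reaction(Reaction(id="EX_A_e", stoichiometry={"A_e": -1.0},
                                lower_bound=-10.0, upper_bound=1000.0,
                                kind=ReactionKind.EXCHANGE))
    m.add_reaction(Reaction(id="At", stoichiometry={"A_e": -1.0, "A_c": 1.0},
                            lower_bound=0.0, upper_bound=1000.0,
                            kind=ReactionKind.TRANSPORT))
    m.add_reaction(Reaction(id="AB", stoichiometry={"A_c": -1.0, "B_c": 1.0},
                            lower_bound=0.0, upper_bound=1000.0, gpr="g1 and g2"))
    m.add_reaction(Reaction(id="BIOMASS", stoichiometry={"B_c": -1.0},
                            lower_bound=0.0, upper_bound=1000.0,
                            kind=ReactionKind.BIOMASS))
    m.objective = ("BIOMASS", "max")
    return m


@pytest.fixture
def toy_chain():
    return make_toy_chain()
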