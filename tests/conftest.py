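import warnings

import pytest

from ebpr_gem.constraint_core import MetabolicModel, Metabolite, Reaction
from ebpr_gem.ebpr_cycle import CycleConfig
from ebpr_gem.synthetic_data import make_pao_model

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def pao_model():
    """The complete synthetic PAO network (no knockouts)."""
    return make_pao_model()


@pytest.fixture(scope="session")
def cycle_config():
    """Default cycle at the reference anaerobic acetate-uptake rate."""
    return CycleConfig(uptake_rate=3.0)


def build_chain_model(uptake=10.0, ngam_lb=0.0, atp_blocked=False):
    """Minimal hand-solvable model: A_ext -(uptake<=10)-> A -> biomass, with
    an ATP side branch (A -> ATP) feeding an optional maintenance demand.

    FBA optimum at biomass equals the uptake bound (1:1 stoichiometry), which
    is the hand-derived LP solution used as a frozen expected value. With
    ``atp_blocked`` and a positive maintenance bound the model is infeasible
    (no route can supply the demanded ATP).
    """
    mets = [
        Metabolite("A_e", "A", "extracellular", carbon_atoms=1, role="carbon_substrate"),
        Metabolite("A_c", "A", "cytosol", carbon_atoms=1),
        Metabolite("atp_c", "ATP", "cytosol"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1}, -uptake, 1000.0, frozenset({"exchange"})),
        Reaction("T_A", {"A_e": -1, "A_c": 1}, 0.0, 1000.0, frozenset({"transport"})),
        Reaction(
            "ATPGEN", {"A_c": -1, "atp_c": 1}, 0.0, 0.0 if atp_blocked else 1000.0, frozenset({"internal"})
        ),
        Reaction("ATPM", {"atp_c": -1}, ngam_lb, 1000.0, frozenset({"maintenance"})),
        Reaction("BIOMASS", {"A_c": -1}, 0.0, 1000.0, frozenset({"biomass"})),
    ]
    model = MetabolicModel(
        id="chain",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction="BIOMASS",
        maintenance_reaction="ATPM",
        o2_exchange=None,
        carbon_exchanges={"EX_A"},
    )
    model.validate()
    return model
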