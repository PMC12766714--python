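"""Unit and property tests for the stoichiometric core: FBA/pFBA/min-flux
solves, phase constraints, SBML round-trips, and LP-level invariants checked
against independent oracles (hand-derived solutions, exhaustive vertex
enumeration, and cobrapy's own optimizer)."""

import itertools
import math

import numpy as np
import pytest

from ebpr_gem.constraint_core import (
    DEFAULT_NGAM,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    apply_aerobic,
    apply_anaerobic,
    read_sbml,
    set_maintenance,
    solve_fba,
    solve_min_total_flux,
    solve_pfba,
    write_sbml,
)
from ebpr_gem.synthetic_data import make_pao_model

from conftest import build_chain_model


def min_total_flux_by_vertex_enumeration(model, fixed_bounds=None):
    """Independent oracle: minimize sum|v| over the flux polytope by
    enumerating its vertices (every vertex has >= n - rank(S) variables at a
    bound); valid for the small fixture models used here."""
    S = model.stoichiometric_matrix()
    bounds = model.bounds()
    if fixed_bounds:
        bounds = list(bounds)
        for rid, (lo, hi) in fixed_bounds.items():
            bounds[model.reaction_ids.index(rid)] = (lo, hi)
    n = len(bounds)
    r = np.linalg.matrix_rank(S)
    best = math.inf
    for free_idx in itertools.combinations(range(n), r):
        fixed_idx = [i for i in range(n) if i not in free_idx]
        A = S[:, list(free_idx)]
        for choice in itertools.product(*[(bounds[i][0], bounds[i][1]) for i in fixed_idx]):
            b = -S[:, fixed_idx] @ np.array(choice)
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ sol - b)) > 1e-7:
                continue
            v = np.zeros(n)
            v[list(free_idx)] = sol
            v[fixed_idx] = choice
            if all(bounds[i][0] - 1e-9 <= v[i] <= bounds[i][1] + 1e-9 for i in range(n)):
                best = min(best, float(np.abs(v).sum()))
    return best


# ---------------------------------------------------------------------------
# model construction / validation
# ---------------------------------------------------------------------------

class TestModelInvariants:
    def test_bounds_must_be_ordered(self):
        with pytest.raises(ModelValidationError):
            Reaction("r", {"x": 1.0}, lower_bound=5.0, upper_bound=1.0)

    def test_storage_role_requires_pool_compartment(self):
        with pytest.raises(ModelValidationError):
            Metabolite("phb", "PHA", "cytosol", carbon_atoms=4, role="storage_PHA")

    def test_ion_cannot_carry_carbon(self):
        with pytest.raises(ModelValidationError):
            Metabolite("nh4", "ammonium", "cytosol", carbon_atoms=1, role="ion")

    def test_exchange_must_touch_one_extracellular_metabolite(self):
        m = build_chain_model()
        bad = m.copy()
        bad.reactions[0] = Reaction("EX_A", {"A_c": -1}, -10, 1000, frozenset({"exchange"}))
        with pytest.raises(ModelValidationError):
            MetabolicModel(
                id="bad",
                metabolites=bad.metabolites,
                reactions=bad.reactions,
                biomass_reaction="BIOMASS",
                maintenance_reaction="ATPM",
            ).validate()

    def test_unknown_objective_raises(self):
        with pytest.raises(KeyError):
            solve_fba(build_chain_model(), objective="NOPE")


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

class TestFBA:
    def test_linear_chain_optimum_equals_uptake_bound(self):
        # hand LP: 1:1 stoichiometry, uptake capped at 10 -> optimum 10
        sol = solve_fba(build_chain_model(uptake=10.0))
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)
        assert sol.growth_rate == pytest.approx(10.0, abs=1e-8)

    def test_biomass_forced_to_zero(self):
        m = build_chain_model()
        m.set_bounds("BIOMASS", 0.0, 0.0)
        sol = solve_fba(m)
        assert sol.growth_rate == pytest.approx(0.0, abs=1e-9)

    def test_unsatisfiable_maintenance_is_infeasible(self):
        m = build_chain_model(ngam_lb=1.0, atp_blocked=True)
        assert solve_fba(m).status == "infeasible"

    def test_steady_state_holds_for_every_balanced_metabolite(self, pao_model):
        sol = solve_fba(pao_model)
        S = pao_model.stoichiometric_matrix()
        v = np.array([sol.fluxes[r.id] for r in pao_model.reactions])
        assert np.max(np.abs(S @ v)) < 1e-6

    def test_row_scaling_leaves_optimum_unchanged(self, pao_model):
        base = solve_fba(pao_model).growth_rate
        scaled = pao_model.copy()
        for r in scaled.reactions:
            if "accoa_c" in r.stoichiometry:
                r.stoichiometry["accoa_c"] *= 3.0
        assert solve_fba(scaled).growth_rate == pytest.approx(base, rel=1e-7)

    def test_tightening_any_uptake_never_increases_optimum(self, pao_model):
        base = solve_fba(pao_model).growth_rate
        for r in pao_model.reactions:
            if "exchange" in r.tags and r.lower_bound < 0:
                tightened = pao_model.copy()
                tightened.reaction(r.id).lower_bound = 0.0
                mu = solve_fba(tightened).growth_rate
                assert mu <= base + 1e-7, r.id

    def test_matches_cobrapy_optimum(self, pao_model, tmp_path):
        # independent oracle: the same model solved by cobrapy's optimizer
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "pao.xml"
        write_sbml(pao_model, str(path))
        cm = cobra.io.read_sbml_model(str(path))
        mine = solve_fba(pao_model).growth_rate
        theirs = cm.optimize().objective_value
        assert mine == pytest.approx(theirs, rel=1e-6)


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

def build_parallel_pathway_model():
    """Two routes from A to biomass: a direct one and a 2-step detour.
    pFBA must route everything through the shorter path (enumerable: the
    only two flux-distribution vertices at optimum have |v| sums 30 and 40)."""
    mets = [
        Metabolite("A_e", "A", "extracellular", role="carbon_substrate"),
        Metabolite("A_c", "A", "cytosol"),
        Metabolite("B_c", "B", "cytosol"),
        Metabolite("P_c", "P", "cytosol"),
        Metabolite("atp_c", "ATP", "cytosol"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1}, -10, 1000, frozenset({"exchange"})),
        Reaction("T_A", {"A_e": -1, "A_c": 1}, 0, 1000, frozenset({"transport"})),
        Reaction("DIRECT", {"A_c": -1, "P_c": 1}, 0, 1000, frozenset({"internal"})),
        Reaction("DETOUR1", {"A_c": -1, "B_c": 1}, 0, 1000, frozenset({"internal"})),
        Reaction("DETOUR2", {"B_c": -1, "P_c": 1}, 0, 1000, frozenset({"internal"})),
        Reaction("ATPM", {"atp_c": -1}, 0, 1000, frozenset({"maintenance"})),
        Reaction("BIOMASS", {"P_c": -1}, 0, 1000, frozenset({"biomass"})),
    ]
    m = MetabolicModel(
        id="parallel",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction="BIOMASS",
        maintenance_reaction="ATPM",
        carbon_exchanges={"EX_A"},
    )
    m.validate()
    return m


class TestPFBA:
    def test_routes_through_shorter_pathway(self):
        sol = solve_pfba(build_parallel_pathway_model())
        assert sol.growth_rate == pytest.approx(10.0, rel=1e-6)
        assert sol.fluxes["DIRECT"] == pytest.approx(10.0, rel=1e-5)
        assert abs(sol.fluxes["DETOUR1"]) < 1e-6
        # vertex enumeration: direct route 3 interior steps -> |v| = 40;
        # detour adds one more -> 50; the pFBA optimum must be the smaller
        assert sol.total_absolute_flux() == pytest.approx(40.0, rel=1e-4)

    def test_total_flux_not_above_plain_fba(self, pao_model):
        fba = solve_fba(pao_model)
        pfba = solve_pfba(pao_model)
        assert pfba.growth_rate == pytest.approx(fba.growth_rate, rel=1e-5)
        assert pfba.total_absolute_flux() <= fba.total_absolute_flux() + 1e-6

    def test_single_pathway_fluxes_match_fba(self):
        m = build_chain_model()
        fba, pfba = solve_fba(m), solve_pfba(m)
        for rid in m.reaction_ids:
            # equal up to the pFBA biomass slack (1e-6 relative)
            assert pfba.fluxes[rid] == pytest.approx(fba.fluxes[rid], rel=1e-5, abs=1e-5)

    def test_infeasible_base_problem_propagates(self):
        m = build_chain_model(ngam_lb=1.0, atp_blocked=True)
        assert solve_pfba(m).status == "infeasible"


# ---------------------------------------------------------------------------
# min total flux (anaerobic objective)
# ---------------------------------------------------------------------------

class TestMinTotalFlux:
    def test_zero_uptake_zero_ngam_gives_zero_flux(self):
        m = build_chain_model(uptake=10.0, ngam_lb=0.0)
        m.set_bounds("BIOMASS", 0.0, 0.0)
        sol = solve_min_total_flux(m, "EX_A", 0.0)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_anaerobic_pao_stores_pha_and_hydrolyzes_polyp(self, pao_model):
        ana = apply_anaerobic(set_maintenance(pao_model, DEFAULT_NGAM))
        ana.set_bounds(ana.biomass_reaction, 0.0, 0.0)
        for rid in ana.amino_acid_exchanges.values():
            ana.reaction(rid).lower_bound = 0.0
        for rid in ana.carbon_exchanges - {"EX_ac"}:
            ana.reaction(rid).lower_bound = 0.0
        sol = solve_min_total_flux(ana, "EX_ac", 3.0)
        assert sol.status == "optimal"
        assert sol.fluxes["SINK_PHA"] > 0.1          # PHA accumulates
        assert sol.fluxes["SINK_PP"] < -0.1          # poly-P is consumed
        assert sol.fluxes["EX_pi"] > 0.1             # phosphate released

    def test_matches_vertex_enumeration_oracle(self):
        m = build_chain_model(uptake=5.0, ngam_lb=0.5)
        m.set_bounds("BIOMASS", 0.0, 0.0)
        sol = solve_min_total_flux(m, "EX_A", 2.0)
        oracle = min_total_flux_by_vertex_enumeration(m, fixed_bounds={"EX_A": (-2.0, -2.0)})
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_infeasible_returns_status_not_exception(self):
        m = build_chain_model(ngam_lb=1.0, atp_blocked=True)
        assert solve_min_total_flux(m, "EX_A", 1.0).status == "infeasible"

    def test_non_carbon_exchange_rejected(self, pao_model):
        with pytest.raises(ValueError):
            solve_min_total_flux(pao_model, "EX_o2", 1.0)


# ---------------------------------------------------------------------------
# phase constraints
# ---------------------------------------------------------------------------

class TestPhaseConstraints:
    def test_anaerobic_zeroes_etc_and_o2_uptake(self, pao_model):
        ana = apply_anaerobic(pao_model)
        assert ana.reaction("EX_o2").lower_bound == 0.0
        for r in ana.reactions:
            if "ETC" in r.tags:
                assert (r.lower_bound, r.upper_bound) == (0.0, 0.0)
        # original untouched
        assert pao_model.reaction("EX_o2").lower_bound < 0

    def test_anaerobic_idempotent(self, pao_model):
        once = apply_anaerobic(pao_model)
        twice = apply_anaerobic(once)
        assert [r.lower_bound for r in once.reactions] == [r.lower_bound for r in twice.reactions]
        assert [r.upper_bound for r in once.reactions] == [r.upper_bound for r in twice.reactions]

    def test_aerobic_blocks_carbon_not_amino_acids(self, pao_model):
        aer = apply_aerobic(pao_model)
        for rid in pao_model.carbon_exchanges:
            assert aer.reaction(rid).lower_bound == 0.0
        for rid in pao_model.amino_acid_exchanges.values():
            assert aer.reaction(rid).lower_bound < 0  # uptake still allowed
        assert aer.reaction("EX_o2").lower_bound == -pao_model.o2_uptake_limit

    def test_aerobic_idempotent(self, pao_model):
        once = apply_aerobic(pao_model)
        twice = apply_aerobic(once)
        assert [r.lower_bound for r in once.reactions] == [r.lower_bound for r in twice.reactions]

    def test_anaerobic_without_storage_cannot_grow(self):
        bare = make_pao_model(include_storage=False)
        assert solve_fba(bare).growth_rate > 0.01     # aerobically fine
        ana = apply_anaerobic(set_maintenance(bare, DEFAULT_NGAM))
        assert solve_fba(ana).status == "infeasible"  # no ATP route for NGAM

    def test_set_maintenance_reads_back(self, pao_model):
        m = set_maintenance(pao_model, 0.398)
        assert m.reaction(m.maintenance_reaction).lower_bound == pytest.approx(0.398)

    def test_negative_ngam_rejected(self, pao_model):
        with pytest.raises(ValueError):
            set_maintenance(pao_model, -0.1)

    def test_excessive_ngam_makes_solves_infeasible(self):
        m = set_maintenance(build_chain_model(uptake=1.0), ngam=5000.0)
        assert solve_fba(m).status == "infeasible"


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

class TestSBMLRoundTrip:
    def test_structural_round_trip(self, pao_model, tmp_path):
        path = tmp_path / "m.xml"
        write_sbml(pao_model, str(path))
        back = read_sbml(str(path))
        assert {r.id for r in back.reactions} == {r.id for r in pao_model.reactions}
        for r in pao_model.reactions:
            r2 = back.reaction(r.id)
            assert r2.stoichiometry == r.stoichiometry
            assert r2.tags == r.tags
            assert r2.lower_bound == pytest.approx(r.lower_bound)
            assert r2.upper_bound == pytest.approx(r.upper_bound)
        for m in pao_model.metabolites:
            m2 = back.metabolite(m.id)
            assert (m2.compartment, m2.role, m2.carbon_atoms, m2.phosphorus_atoms) == (
                m.compartment, m.role, m.carbon_atoms, m.phosphorus_atoms,
            )
        assert back.biomass_reaction == pao_model.biomass_reaction
        assert back.carbon_exchanges == pao_model.carbon_exchanges
        assert back.amino_acid_exchanges == pao_model.amino_acid_exchanges

    def test_round_trip_preserves_solutions(self, pao_model, tmp_path):
        path = tmp_path / "m.xml"
        write_sbml(pao_model, str(path))
        back = read_sbml(str(path))
        assert solve_fba(back).growth_rate == pytest.approx(solve_fba(pao_model).growth_rate, rel=1e-7)

    def test_malformed_file_raises_parse_error(self, tmp_path):
        from ebpr_gem.constraint_core import SBMLParseError

        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml>this is not valid</sbml>")
        with pytest.raises(SBMLParseError):
            read_sbml(str(bad))
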