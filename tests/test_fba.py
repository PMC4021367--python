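"""FBA/FVA correctness against closed forms, enumeration, and cobra."""

import numpy as np
import pytest

from conftest import linear_chain_model
from helpers import enumerate_vertices_optimum
from thermoflux.core import (MetabolicModel, Metabolite, Reaction,
                             check_steady_state)
from thermoflux.fba import (FbaProblem, FvaError, MediumError, MediumSpec,
                            apply_medium, run_fva, solve_fba)
from thermoflux.synth import (FIXTURE_NGAM, build_thermophile_fixture,
                              generate_planted_network, random_planted_spec)


def test_single_path_yield(chain_model):
    sol = solve_fba(chain_model)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(10.0, abs=1e-9)


def test_two_chain_min_ratio():
    """u=(10,6), y=(1/2,1), a=(1,2) -> mu* = min(5, 3) = 3."""
    from fractions import Fraction
    from thermoflux.synth import SyntheticNetworkSpec
    spec = SyntheticNetworkSpec(
        n_chains=2, chain_lengths=(1, 1),
        yields_=(Fraction(1, 2), Fraction(1)),
        uptakes=(Fraction(10), Fraction(6)),
        biomass_coeffs=(Fraction(1), Fraction(2)))
    model, mu_star = generate_planted_network(spec)
    assert mu_star == 3
    sol = solve_fba(model)
    assert sol.objective_value == pytest.approx(3.0, abs=1e-9)


@pytest.mark.parametrize("seed", range(12))
def test_optimum_matches_vertex_enumeration(seed):
    """LP optimum equals brute-force vertex enumeration (<=6 free fluxes)."""
    model, mu_star = generate_planted_network(random_planted_spec(seed))
    brute = enumerate_vertices_optimum(model)
    sol = solve_fba(model)
    assert sol.objective_value == pytest.approx(brute, abs=1e-8)
    assert sol.objective_value == pytest.approx(float(mu_star), abs=1e-8)


def test_exchange_scaling_homogeneity():
    """Scaling every exchange bound by k scales Z by k (zero-RHS LP)."""
    model, _ = generate_planted_network(random_planted_spec(7))
    base = solve_fba(model).objective_value
    scaled = model.copy()
    for rxn in scaled.exchanges():
        rxn.lower_bound *= 2.5
        rxn.upper_bound *= 2.5
    assert solve_fba(scaled).objective_value == pytest.approx(2.5 * base,
                                                              rel=1e-9)


def test_solution_satisfies_steady_state_and_bounds(fixture, fixture_growth):
    for constrained, sol in fixture_growth.values():
        assert check_steady_state(constrained, sol) <= 1e-6
        for rid, v in sol.fluxes.items():
            rxn = constrained.reactions[rid]
            assert rxn.lower_bound - 1e-6 <= v <= rxn.upper_bound + 1e-6


class TestApplyMedium:
    def test_listed_unconstrained_and_closed(self, fixture):
        constrained = apply_medium(fixture.model, fixture.dmm,
                                   ngam=FIXTURE_NGAM)
        assert constrained.reactions["EX_GLC"].lower_bound == -2.0
        assert constrained.reactions["EX_NH4"].lower_bound == -1000.0
        # leucine exchange closed to uptake, secretion still possible
        assert constrained.reactions["EX_L_LEU"].lower_bound == 0.0
        assert constrained.reactions["EX_L_LEU"].upper_bound == 1000.0
        assert constrained.reactions["ATPM"].lower_bound == FIXTURE_NGAM

    def test_oxygen_uptake_capped(self, fixture_growth):
        for constrained, sol in fixture_growth.values():
            assert sol.fluxes["EX_O2"] >= -10.0 - 1e-9

    def test_non_exchange_id_rejected(self, fixture):
        bad = MediumSpec("bad", bounds={"GLYC": (-5, 5)})
        with pytest.raises(MediumError, match="GLYC"):
            apply_medium(fixture.model, bad)

    def test_closed_medium_no_growth(self, fixture):
        closed = MediumSpec("closed")
        sol = solve_fba(FbaProblem(fixture.model, closed, ngam=0.0))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_closed_medium_with_ngam_infeasible_scores_zero(self, fixture):
        closed = MediumSpec("closed")
        sol = solve_fba(FbaProblem(fixture.model, closed,
                                   ngam=FIXTURE_NGAM))
        assert sol.status == "infeasible"
        assert sol.objective_value == 0.0


def test_unbounded_objective_flagged():
    """A reversible free exchange pair lets biomass run away."""
    m = MetabolicModel("runaway")
    m.add_metabolite(Metabolite("A[c]"))
    m.add_reaction(Reaction("SRC", {"A[c]": 1.0}, lower_bound=-1000,
                            upper_bound=float("inf")))
    m.add_reaction(Reaction("BIOMASS", {"A[c]": -1.0},
                            upper_bound=float("inf"), subsystem="biomass"))
    m.set_objective("BIOMASS")
    assert solve_fba(m).status == "unbounded"


class TestFva:
    def test_unique_optimum_collapses_ranges(self, chain_model):
        result = run_fva(chain_model)
        sol = solve_fba(chain_model)
        for rid in chain_model.reactions:
            lo, hi = result.range(rid)
            assert lo == pytest.approx(hi, abs=1e-7)
            assert lo == pytest.approx(sol.fluxes[rid], abs=1e-7)

    def test_parallel_paths_span_zero_to_total(self):
        """Two identical irreversible routes jointly carrying T range [0,T]."""
        m = MetabolicModel("parallel")
        for mid in ("A[e]", "A[c]", "B[c]"):
            m.add_metabolite(Metabolite(mid))
        m.add_reaction(Reaction("EX_A", {"A[e]": -1.0}, lower_bound=-8,
                                subsystem="exchange"))
        m.add_reaction(Reaction("T", {"A[e]": -1.0, "A[c]": 1.0},
                                subsystem="transport"))
        m.add_reaction(Reaction("P1", {"A[c]": -1.0, "B[c]": 1.0}))
        m.add_reaction(Reaction("P2", {"A[c]": -1.0, "B[c]": 1.0}))
        m.add_reaction(Reaction("BIOMASS", {"B[c]": -1.0},
                                subsystem="biomass"))
        m.set_objective("BIOMASS")
        result = run_fva(m, reactions=["P1", "P2"])
        for rid in ("P1", "P2"):
            lo, hi = result.range(rid)
            assert lo == pytest.approx(0.0, abs=1e-7)
            assert hi == pytest.approx(8.0, abs=1e-7)

    def test_sandwich_property_on_fixture(self, fixture, fixture_growth):
        for constrained, sol in fixture_growth.values():
            result = run_fva(constrained, z_obj=sol.objective_value)
            for rid in constrained.reactions:
                lo, hi = result.range(rid)
                assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6
                rxn = constrained.reactions[rid]
                assert lo >= rxn.lower_bound - 1e-6
                assert hi <= rxn.upper_bound + 1e-6

    def test_unattainable_z_obj_raises(self, chain_model):
        with pytest.raises(FvaError):
            run_fva(chain_model, z_obj=99.0)


def test_agrees_with_cobra_on_fixture(fixture):
    """Independent solver stack (cobrapy/GLPK) reproduces both growth rates."""
    cobra = pytest.importorskip("cobra")
    for medium in (fixture.dmm, fixture.tm):
        constrained = apply_medium(fixture.model, medium, FIXTURE_NGAM)
        cm = cobra.Model("check")
        mets = {mid: cobra.Metabolite(mid.replace("[", "_").rstrip("]"),
                                      compartment=mid[-2])
                for mid in constrained.metabolites}
        reactions = []
        for rid, rxn in constrained.reactions.items():
            cr = cobra.Reaction(rid)
            cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
            reactions.append(cr)
        cm.add_reactions(reactions)
        for rid, rxn in constrained.reactions.items():
            cm.reactions.get_by_id(rid).add_metabolites(
                {mets[mid]: coeff for mid, coeff in rxn.stoichiometry.items()})
        cm.objective = "BIOMASS"
        reference = cm.optimize()
        ours = solve_fba(constrained)
        assert reference.status == "optimal"
        assert ours.objective_value == pytest.approx(
            reference.objective_value, abs=1e-6)
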