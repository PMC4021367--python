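"""Flux comparison tables and amino-acid supply/demand accounting."""

import numpy as np
import pytest

from thermoflux.compare import (AccountingError, amino_acid_balance,
                                biosynthetic_demand, close_balance_row,
                                compare_conditions, guess_amino_acid_ids)
from thermoflux.datasets import reported_amino_acid_fluxes
from thermoflux.fba import FbaProblem, apply_medium, run_fva, solve_fba
from thermoflux.synth import FIXTURE_BIOMASS_COEFFS, FIXTURE_NGAM


class TestDemand:
    def test_zero_growth_zero_demand(self):
        demand = biosynthetic_demand({"leucine": 0.35}, 0.0)
        assert demand["leucine"] == 0.0

    def test_linear_in_growth_rate(self):
        coeffs = {"leucine": 0.35, "valine": 0.3}
        d1 = biosynthetic_demand(coeffs, 0.33)
        d2 = biosynthetic_demand(coeffs, 0.66)
        for k in coeffs:
            assert d2[k] == pytest.approx(2 * d1[k])

    def test_methionine_style_backsolve(self):
        """A coefficient back-solved from printed demand/mu forward-checks."""
        mu = 0.66
        coefficient = 0.015 / mu          # mmol/gDCW implied by the report
        demand = biosynthetic_demand({"methionine": coefficient}, mu)
        assert demand["methionine"] == pytest.approx(0.015, abs=1e-12)

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError):
            biosynthetic_demand({}, -0.1)


class TestRowClosure:
    def test_demand_from_supply_and_conversion(self):
        """Published glycine row: demand implied by supply + from_others."""
        table = reported_amino_acid_fluxes()
        row = table.loc["glycine"]
        implied = close_balance_row(supply=row["supply"], demand=None,
                                    to_others=row["to_others"],
                                    from_others=row["from_others"])
        assert implied == pytest.approx(row["demand"], abs=5e-4)

    def test_to_others_from_supply_minus_demand(self):
        """Published leucine row: conversion flux implied by the closure."""
        table = reported_amino_acid_fluxes()
        row = table.loc["leucine"]
        implied = row["supply"] - row["demand"]  # from_others is 0
        assert implied == pytest.approx(row["to_others"], abs=5e-4)

    def test_balanced_consumers_have_no_side_terms(self):
        """Methionine-style rows: supply equals demand, nothing else."""
        table = reported_amino_acid_fluxes()
        for aa in ("methionine", "phenylalanine", "cysteine"):
            row = table.loc[aa]
            assert row["supply"] == pytest.approx(row["demand"], abs=5e-4)
            assert row[["to_others", "from_others"]].abs().max() < 1e-9

    def test_every_reported_row_closes(self):
        table = reported_amino_acid_fluxes()
        residual = (table["supply"] + table["from_others"]
                    - table["demand"] - table["to_others"])
        assert residual.abs().max() < 1e-3

    def test_exactly_one_unknown_required(self):
        with pytest.raises(ValueError):
            close_balance_row(supply=1.0, demand=1.0)


class TestFixtureBalance:
    def test_rows_close_on_every_optimal_solution(self, fixture,
                                                  fixture_growth):
        for constrained, sol in fixture_growth.values():
            ids = guess_amino_acid_ids(constrained)
            balance = amino_acid_balance(sol, constrained, ids)
            residual = (balance.table["supply"]
                        + balance.table["from_others"]
                        - balance.table["demand"]
                        - balance.table["to_others"])
            assert residual.abs().max() <= 1e-3

    def test_balance_equals_direct_flux_summation(self, fixture_growth):
        """Independent oracle: per-metabolite signed flux sums."""
        constrained, sol = fixture_growth["TM_like"]
        ids = guess_amino_acid_ids(constrained)
        balance = amino_acid_balance(sol, constrained, ids)
        for name, mid in ids.items():
            transport = internal = 0.0
            for rid, rxn in constrained.reactions.items():
                if rid == "BIOMASS" or rxn.is_exchange:
                    continue
                rate = rxn.stoichiometry.get(mid, 0.0) * sol.fluxes[rid]
                if rxn.subsystem == "transport":
                    transport += rate
                else:
                    internal += rate
            row = balance.row(name)
            assert row["supply"] == pytest.approx(transport, abs=1e-9)
            assert row["from_others"] - row["to_others"] == pytest.approx(
                internal, abs=1e-9)

    def test_demand_uses_biomass_coefficients(self, fixture_growth):
        constrained, sol = fixture_growth["DMM_like"]
        ids = guess_amino_acid_ids(constrained)
        balance = amino_acid_balance(sol, constrained, ids)
        mu = sol.objective_value
        assert balance.row("leucine")["demand"] == pytest.approx(
            mu * FIXTURE_BIOMASS_COEFFS["L_LEU[c]"], rel=1e-9)

    def test_non_optimal_solution_rejected(self, fixture_growth):
        constrained, sol = fixture_growth["DMM_like"]
        from thermoflux.core import FluxSolution
        bad = FluxSolution("infeasible", 0.0, sol.fluxes)
        with pytest.raises(AccountingError):
            amino_acid_balance(bad, constrained,
                               guess_amino_acid_ids(constrained))


@pytest.fixture(scope="module")
def two_conditions(fixture):
    out = []
    for medium in (fixture.dmm, fixture.tm):
        prob = FbaProblem(fixture.model, medium, FIXTURE_NGAM)
        sol = solve_fba(prob)
        fva = run_fva(prob, z_obj=sol.objective_value)
        out.append((sol, fva))
    return out


class TestConditionComparison:
    def test_identical_conditions_zero_deltas(self, two_conditions):
        cmp_result = compare_conditions(two_conditions[0],
                                        two_conditions[0])
        assert cmp_result.table["delta"].abs().max() == 0
        assert not cmp_result.table["sign_flip"].any()

    def test_leucine_transaminase_flips_direction(self, two_conditions):
        """Synthesis on minimal medium, degradation when leucine is fed."""
        cmp_result = compare_conditions(two_conditions[0],
                                        two_conditions[1],
                                        reactions=["LEUTA"])
        row = cmp_result.table.loc["LEUTA"]
        assert row["flux_a"] > 0 > row["flux_b"]
        assert bool(row["sign_flip"])

    def test_deltas_equal_elementwise_subtraction(self, two_conditions):
        cmp_result = compare_conditions(two_conditions[0],
                                        two_conditions[1])
        sol_a, sol_b = two_conditions[0][0], two_conditions[1][0]
        for rid, row in cmp_result.table.iterrows():
            assert row["delta"] == pytest.approx(
                sol_a.fluxes[rid] - sol_b.fluxes[rid], abs=1e-12)

    def test_missing_reaction_rejected(self, two_conditions):
        with pytest.raises(KeyError):
            compare_conditions(two_conditions[0], two_conditions[1],
                               reactions=["NOPE"])
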