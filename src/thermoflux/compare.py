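"""Condition comparison reports: flux/FVA side-by-sides and the
amino-acid supply-versus-demand accounting.

The accounting views each cytosolic amino acid at steady state:

    supply (net import) + production from others
        = biosynthetic demand (mu x biomass coefficient)
          + conversion to others

Signs follow the reporting convention of nutrient-consumption tables:
positive supply means consumption from the medium, negative supply net
secretion.  Row closure is a theorem of steady state, so it is asserted
(to 1e-3) rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import FluxSolution, MetabolicModel
from .fba import FVAResult

CLOSURE_TOLERANCE = 1e-3

_THREE_LETTER = {
    "ALA": "alanine", "ARG": "arginine", "ASN": "asparagine",
    "ASP": "aspartate", "CYS": "cysteine", "GLU": "glutamate",
    "GLN": "glutamine", "GLY": "glycine", "HIS": "histidine",
    "ILE": "isoleucine", "LEU": "leucine", "LYS": "lysine",
    "MET": "methionine", "PHE": "phenylalanine", "PRO": "proline",
    "SER": "serine", "THR": "threonine", "TRP": "tryptophan",
    "TYR": "tyrosine", "VAL": "valine",
}


class AccountingError(ValueError):
    pass


def guess_amino_acid_ids(model: MetabolicModel) -> Dict[str, str]:
    """Map amino-acid names to cytosolic ids by the ``L_XXX[c]`` pattern."""
    out: Dict[str, str] = {}
    for mid in model.metabolites:
        if mid.startswith("L_") and mid.endswith("[c]"):
            code = mid[2:-3]
            if code in _THREE_LETTER:
                out[_THREE_LETTER[code]] = mid
    return out


def biosynthetic_demand(biomass_coefficients: Mapping[str, float],
                        growth_rate: float) -> Dict[str, float]:
    """demand_i = mu * biomass coefficient of i, mmol gDCW^-1 h^-1."""
    if growth_rate < 0:
        raise ValueError(f"growth rate must be >= 0, got {growth_rate}")
    return {k: growth_rate * c for k, c in biomass_coefficients.items()}


@dataclass
class AminoAcidBalance:
    """Per-amino-acid flux bookkeeping in one optimal solution.

    Columns: supply (positive = consumed from medium), demand
    (mu x biomass coefficient), to_others / from_others (one-sided net
    internal conversion), residual (closure check), remark.
    """

    table: pd.DataFrame
    growth_rate: float

    def row(self, amino_acid: str) -> pd.Series:
        return self.table.loc[amino_acid]


def amino_acid_balance(solution: FluxSolution,
                       model: MetabolicModel,
                       amino_acid_ids: Mapping[str, str],
                       biomass_id: Optional[str] = None,
                       tolerance: float = CLOSURE_TOLERANCE
                       ) -> AminoAcidBalance:
    """Build the supply/demand/conversion table from an optimal solution.

    ``amino_acid_ids`` maps display names to cytosolic metabolite ids
    (e.g. ``{"leucine": "L_LEU[c]"}``).  Supply is the net rate at which
    transport reactions deliver the amino acid into the cytosol
    (positive = consumption); from_others/to_others split the net
    production by all other internal reactions into its positive and
    negative parts, matching one-sided report columns.
    """
    if solution.status != "optimal":
        raise AccountingError(
            f"need an optimal solution, got status {solution.status}")
    if biomass_id is None:
        biomass_id = model.objective_reaction_id()
    mu = solution.objective_value

    rows = []
    for name, mid in amino_acid_ids.items():
        if mid not in model.metabolites:
            raise AccountingError(f"unknown metabolite {mid!r} for {name!r}")
        demand = -model.reactions[biomass_id].stoichiometry.get(mid, 0.0) * mu
        supply = 0.0
        net_internal = 0.0
        for rid, rxn in model.reactions.items():
            if rid == biomass_id or rxn.is_exchange:
                continue
            coeff = rxn.stoichiometry.get(mid, 0.0)
            if coeff == 0.0:
                continue
            rate = coeff * solution.fluxes.get(rid, 0.0)
            if rxn.subsystem == "transport":
                supply += rate
            else:
                net_internal += rate
        from_others = max(net_internal, 0.0)
        to_others = max(-net_internal, 0.0)
        residual = supply + from_others - demand - to_others
        if abs(residual) > tolerance:
            raise AccountingError(
                f"balance row for {name} ({mid}) does not close: "
                f"supply {supply:.4f} + from_others {from_others:.4f} "
                f"- demand {demand:.4f} - to_others {to_others:.4f} "
                f"= {residual:.2e}")
        rows.append({"amino_acid": name, "supply": supply, "demand": demand,
                     "to_others": to_others, "from_others": from_others,
                     "residual": residual})
    table = pd.DataFrame(rows).set_index("amino_acid")
    return AminoAcidBalance(table=table, growth_rate=mu)


def close_balance_row(supply: Optional[float] = None,
                      demand: Optional[float] = None,
                      to_others: float = 0.0,
                      from_others: float = 0.0) -> float:
    """Solve the row identity supply + from_others = demand + to_others
    for whichever of supply/demand is left as None.

    Useful for auditing published supply/demand tables where one column
    is implied by the others.
    """
    if (supply is None) == (demand is None):
        raise ValueError("exactly one of supply/demand must be None")
    if demand is None:
        return supply + from_others - to_others
    return demand + to_others - from_others


@dataclass
class ConditionComparison:
    """Per-reaction fluxes and FVA ranges in two conditions."""

    table: pd.DataFrame  # flux_a, lo_a, hi_a, flux_b, lo_b, hi_b, delta, sign_flip
    name_a: str
    name_b: str


def compare_conditions(result_a: Tuple[FluxSolution, FVAResult],
                       result_b: Tuple[FluxSolution, FVAResult],
                       reactions: Optional[Sequence[str]] = None,
                       name_a: str = "A", name_b: str = "B",
                       flip_epsilon: float = 1e-6) -> ConditionComparison:
    """Tabulate flux + range per condition and flag direction changes.

    A sign flip marks reactions carrying materially opposite flux in the
    two conditions — e.g. a transaminase running toward synthesis on
    minimal medium but toward degradation when the product is fed.
    """
    sol_a, fva_a = result_a
    sol_b, fva_b = result_b
    if reactions is None:
        reactions = list(fva_a.ranges.index)
    rows = []
    for rid in reactions:
        if rid not in sol_a.fluxes or rid not in sol_b.fluxes:
            raise KeyError(f"reaction {rid!r} missing from a solution")
        fa, fb = sol_a.fluxes[rid], sol_b.fluxes[rid]
        lo_a, hi_a = fva_a.range(rid)
        lo_b, hi_b = fva_b.range(rid)
        rows.append({
            "reaction_id": rid,
            "flux_a": fa, "lo_a": lo_a, "hi_a": hi_a,
            "flux_b": fb, "lo_b": lo_b, "hi_b": hi_b,
            "delta": fa - fb,
            "sign_flip": (fa > flip_epsilon and fb < -flip_epsilon)
                         or (fa < -flip_epsilon and fb > flip_epsilon),
        })
    return ConditionComparison(pd.DataFrame(rows).set_index("reaction_id"),
                               name_a, name_b)
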