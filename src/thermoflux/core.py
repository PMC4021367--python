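"""In-memory representation of a constraint-based metabolic model.

Conventions (shared by every downstream stage):

* metabolite ids carry a bracketed compartment suffix, ``"L_LEU[c]"`` for
  cytosol and ``"GLC[e]"`` for extracellular;
* flux units are mmol gDCW^-1 h^-1, except the biomass pseudo-reaction
  whose flux is the specific growth rate mu in h^-1;
* uptake through an exchange reaction is a negative flux, secretion
  positive; reversible reactions get default bounds (-1000, 1000) and
  irreversible ones (0, 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .gpr import GprExpression, parse_gpr

#: absolute numerical tolerance for steady-state and balance checks
TOLERANCE = 1e-6
#: "effectively unbounded" flux sentinel, mmol gDCW^-1 h^-1
DEFAULT_BOUND = 1000.0
#: OD600 -> dry cell weight conversion, g L^-1 per OD unit
OD_TO_DCW_FACTOR = 0.34

SUBSYSTEMS = (
    "carbohydrates",
    "amino acid",
    "energy and cofactors",
    "lipids",
    "nucleotides",
    "carotenoids",
    "transport",
    "exchange",
    "biomass",
)


class ModelIntegrityError(ValueError):
    """A structural invariant of the model is violated."""


def parse_compartment(met_id: str) -> str:
    """Extract the compartment letter from a bracketed id suffix."""
    if not met_id.endswith("]") or "[" not in met_id:
        raise ModelIntegrityError(
            f"metabolite id {met_id!r} lacks a [compartment] suffix")
    comp = met_id[met_id.rindex("[") + 1:-1]
    if comp not in ("c", "e"):
        raise ModelIntegrityError(
            f"metabolite id {met_id!r}: unknown compartment {comp!r}")
    return comp


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` maps element symbol to a non-negative integer count and
    may be None (unknown composition; balance checks then skip the
    reactions it participates in).
    """

    id: str
    name: str = ""
    formula: Optional[Dict[str, int]] = None

    def __post_init__(self):
        self.compartment = parse_compartment(self.id)
        if self.formula is not None:
            for elem, n in self.formula.items():
                if not (isinstance(n, int) and n >= 0):
                    raise ModelIntegrityError(
                        f"{self.id}: formula count {elem}={n!r} must be a "
                        "non-negative integer")

    def copy(self) -> "Metabolite":
        return Metabolite(self.id, self.name,
                          dict(self.formula) if self.formula else None)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR rule.

    Negative stoichiometric coefficients mark substrates, positive ones
    products.  Exchange pseudo-reactions are single-metabolite sinks
    ``met[e] <=> (environment)``.
    """

    id: str
    stoichiometry: Dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = "carbohydrates"
    gpr: GprExpression = field(default_factory=GprExpression.empty)

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"{self.id}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}")
        if self.subsystem not in SUBSYSTEMS:
            raise ModelIntegrityError(
                f"{self.id}: unknown subsystem {self.subsystem!r}")
        if not self.stoichiometry:
            raise ModelIntegrityError(f"{self.id}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Exchange sinks: ``EX_`` prefix or one-sided single metabolite.

        Biomass drains are never exchanges even when single-sided.
        """
        if self.subsystem == "biomass":
            return False
        if self.id.startswith("EX_"):
            return True
        return len(self.stoichiometry) == 1

    def genes(self) -> set:
        return self.gpr.genes()

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.name,
                        self.lower_bound, self.upper_bound, self.subsystem,
                        self.gpr)


class MetabolicModel:
    """A genome-scale (or toy) metabolic network.

    Holds metabolites, an ordered collection of reactions, and the linear
    objective c_j (normally 1 on the biomass reaction, 0 elsewhere) that
    defines Z for flux balance analysis.
    """

    def __init__(self, model_id: str = "model"):
        self.id = model_id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}  # insertion-ordered
        self.objective: Dict[str, float] = {}

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction,
                     objective_coefficient: float = 0.0) -> None:
        if rxn.id in self.reactions:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ModelIntegrityError(
                    f"reaction {rxn.id!r} references unknown metabolite "
                    f"{mid!r}")
        self.reactions[rxn.id] = rxn
        if objective_coefficient:
            self.objective[rxn.id] = float(objective_coefficient)

    def set_objective(self, reaction_id: str, coefficient: float = 1.0) -> None:
        if reaction_id not in self.reactions:
            raise ModelIntegrityError(
                f"objective reaction {reaction_id!r} not in model")
        self.objective = {reaction_id: float(coefficient)}

    # -- views --------------------------------------------------------
    @property
    def genes(self) -> set:
        out = set()
        for rxn in self.reactions.values():
            out |= rxn.genes()
        return out

    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> List[str]:
        return list(self.metabolites)

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def objective_reaction_id(self) -> str:
        nz = [rid for rid, c in self.objective.items() if c]
        if len(nz) != 1:
            raise ModelIntegrityError(
                f"expected exactly one objective reaction, found {nz}")
        return nz[0]

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(self.id)
        for met in self.metabolites.values():
            m.add_metabolite(met.copy())
        for rxn in self.reactions.values():
            m.add_reaction(rxn.copy())
        m.objective = dict(self.objective)
        return m

    def __repr__(self) -> str:
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} "
                f"metabolites, {len(self.reactions)} reactions, "
                f"{len(self.genes)} genes>")


@dataclass
class FluxSolution:
    """Result of one FBA solve.

    ``objective_value`` is Z in the objective's units (h^-1 for biomass);
    on non-optimal status it is reported as 0.0 so that downstream
    knockout growth ratios remain well defined.
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float]

    def to_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name="flux")


# ---------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------

def build_stoichiometric_matrix(model: MetabolicModel) -> pd.DataFrame:
    """S matrix as a metabolites x reactions DataFrame.

    S[i, j] is the signed coefficient of metabolite i in reaction j
    (0 where absent); column order follows reaction insertion order.
    """
    met_ids = model.metabolite_ids
    rxn_ids = model.reaction_ids
    S = np.zeros((len(met_ids), len(rxn_ids)))
    met_index = {m: i for i, m in enumerate(met_ids)}
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            if mid not in met_index:
                raise ModelIntegrityError(
                    f"reaction {rid!r} references unresolved metabolite "
                    f"{mid!r}")
            S[met_index[mid], j] = coeff
    return pd.DataFrame(S, index=met_ids, columns=rxn_ids)


def evaluate_gpr(gpr: GprExpression, deleted: Iterable[str]) -> bool:
    """True iff the reaction remains catalyzable after the deletions."""
    return gpr.evaluate(deleted)


@dataclass
class MassBalanceReport:
    """Outcome of an elemental balance audit.

    ``imbalanced`` maps reaction id to {element: net surplus}; reactions
    with any formula-less participant are listed ``unchecked`` rather
    than flagged.  Exchange and biomass reactions are exempt.
    """

    balanced: List[str]
    imbalanced: Dict[str, Dict[str, float]]
    unchecked: List[str]
    exempt: List[str]


def validate_mass_balance(model: MetabolicModel,
                          tolerance: float = TOLERANCE) -> MassBalanceReport:
    """Flag internal reactions whose summed elemental content is nonzero."""
    balanced: List[str] = []
    imbalanced: Dict[str, Dict[str, float]] = {}
    unchecked: List[str] = []
    exempt: List[str] = []
    for rid, rxn in model.reactions.items():
        if rxn.is_exchange or rxn.subsystem == "biomass":
            exempt.append(rid)
            continue
        formulas = [model.metabolites[mid].formula for mid in rxn.stoichiometry]
        if any(f is None for f in formulas):
            unchecked.append(rid)
            continue
        net: Dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            for elem, count in model.metabolites[mid].formula.items():
                net[elem] = net.get(elem, 0.0) + coeff * count
        bad = {e: v for e, v in net.items() if abs(v) > tolerance}
        if bad:
            imbalanced[rid] = bad
        else:
            balanced.append(rid)
    return MassBalanceReport(balanced, imbalanced, unchecked, exempt)


def od_to_dcw(od600: float) -> float:
    """Convert optical density at 600 nm to dry cell weight, g L^-1."""
    if od600 < 0:
        raise ValueError(f"OD600 must be non-negative, got {od600}")
    return od600 * OD_TO_DCW_FACTOR


def check_steady_state(model: MetabolicModel, solution: FluxSolution,
                       tolerance: float = TOLERANCE) -> float:
    """Max absolute metabolite imbalance |S v| of an optimal solution."""
    S = build_stoichiometric_matrix(model)
    v = np.array([solution.fluxes[rid] for rid in S.columns])
    return float(np.max(np.abs(S.to_numpy() @ v))) if len(v) else 0.0
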