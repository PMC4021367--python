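"""Flux balance analysis and flux variability analysis.

FBA solves the linear program

    max Z = sum_j c_j v_j
    s.t.  sum_j S_ij v_j = 0   for every metabolite i
          v_j^min <= v_j <= v_j^max

FVA then fixes the objective at its optimum Z_obj and, reaction by
reaction, maximizes and minimizes v_j under the same constraints,
exposing alternate-optima flexibility.

Both run on scipy's HiGHS solver with default (deterministic)
configuration, so repeated solves return identical vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core import (TOLERANCE, DEFAULT_BOUND, FluxSolution, MetabolicModel,
                   build_stoichiometric_matrix)
from .io import MediumSpec

#: conventional id of the non-growth-associated ATP maintenance reaction
NGAM_REACTION_ID = "ATPM"


class MediumError(ValueError):
    pass


class FvaError(RuntimeError):
    pass


def apply_medium(model: MetabolicModel, medium: MediumSpec,
                 ngam: float = 0.0,
                 ngam_reaction: str = NGAM_REACTION_ID) -> MetabolicModel:
    """Return a copy of the model constrained to one environment.

    Exchanges listed in ``medium.bounds`` get those bounds; ids in
    ``medium.unconstrained`` open to (-1000, 1000); every other exchange
    is closed to uptake (lower bound 0, secretion still allowed).  When
    ``ngam`` > 0 the maintenance reaction's lower bound is raised to it,
    forcing the constant ATP drain.
    """
    constrained = model.copy()
    exchange_ids = {r.id for r in constrained.exchanges()}
    for rid in list(medium.bounds) + list(medium.unconstrained):
        if rid not in constrained.reactions:
            raise MediumError(f"medium {medium.name!r}: unknown reaction "
                              f"{rid!r}")
        if rid not in exchange_ids:
            raise MediumError(f"medium {medium.name!r}: {rid!r} is not an "
                              "exchange reaction")
    for rid in exchange_ids:
        rxn = constrained.reactions[rid]
        if rid in medium.bounds:
            lb, ub = medium.bounds[rid]
            rxn.lower_bound, rxn.upper_bound = float(lb), float(ub)
        elif rid in medium.unconstrained:
            rxn.lower_bound, rxn.upper_bound = -DEFAULT_BOUND, DEFAULT_BOUND
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    if ngam > 0:
        if ngam_reaction not in constrained.reactions:
            raise MediumError(
                f"NGAM requested but reaction {ngam_reaction!r} is absent")
        constrained.reactions[ngam_reaction].lower_bound = float(ngam)
    return constrained


@dataclass
class FbaProblem:
    """One FBA instance: a model, an optional medium, and maintenance.

    ``ngam`` is the lower bound (mmol gDCW^-1 h^-1) imposed on the ATP
    maintenance reaction; the objective sense is always maximization.
    """

    model: MetabolicModel
    medium: Optional[MediumSpec] = None
    ngam: float = 0.0
    ngam_reaction: str = NGAM_REACTION_ID

    def constrained_model(self) -> MetabolicModel:
        if self.medium is None:
            if self.ngam > 0:
                m = self.model.copy()
                if self.ngam_reaction not in m.reactions:
                    raise MediumError(
                        f"NGAM requested but reaction "
                        f"{self.ngam_reaction!r} is absent")
                m.reactions[self.ngam_reaction].lower_bound = float(self.ngam)
                return m
            return self.model
        return apply_medium(self.model, self.medium, self.ngam,
                            self.ngam_reaction)


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible",
           3: "unbounded", 4: "numerical"}


def _solve_lp(S: np.ndarray, c: np.ndarray, bounds: Sequence,
              A_ub: Optional[np.ndarray] = None,
              b_ub: Optional[np.ndarray] = None):
    """Maximize c.v subject to S v = 0, bounds, optional A_ub v <= b_ub."""
    res = linprog(-c, A_ub=A_ub, b_ub=b_ub,
                  A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=bounds, method="highs")
    return res


def solve_fba(problem: FbaProblem | MetabolicModel) -> FluxSolution:
    """Maximize the model objective; returns one optimal vertex.

    Infeasible problems (e.g. the NGAM floor cannot be met on a closed
    medium) report status "infeasible" with objective 0.0 so knockout
    growth ratios stay defined; an unbounded objective is flagged
    explicitly, signalling a missing exchange closure.
    """
    if isinstance(problem, MetabolicModel):
        problem = FbaProblem(problem)
    model = problem.constrained_model()
    if not any(model.objective.values()):
        raise ValueError("model has no objective reaction")
    S_df = build_stoichiometric_matrix(model)
    rxn_ids = list(S_df.columns)
    c = np.array([model.objective.get(rid, 0.0) for rid in rxn_ids])
    bounds = [(model.reactions[rid].lower_bound,
               model.reactions[rid].upper_bound) for rid in rxn_ids]
    res = _solve_lp(S_df.to_numpy(), c, bounds)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=0.0,
                            fluxes={rid: 0.0 for rid in rxn_ids})
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxSolution(status="optimal",
                        objective_value=float(c @ res.x), fluxes=fluxes)


@dataclass
class FVAResult:
    """Per-reaction [min, max] flux ranges at a fixed objective value."""

    z_obj: float
    ranges: pd.DataFrame  # index reaction id, columns minimum/maximum
    fraction_of_optimum: float = 1.0

    def range(self, reaction_id: str) -> tuple:
        row = self.ranges.loc[reaction_id]
        return float(row["minimum"]), float(row["maximum"])


def run_fva(problem: FbaProblem | MetabolicModel,
            z_obj: Optional[float] = None,
            reactions: Optional[Iterable[str]] = None,
            fraction_of_optimum: float = 1.0) -> FVAResult:
    """Flux ranges with the objective held at (a fraction of) Z_obj.

    The objective constraint is c.v >= fraction * Z_obj, guarded by a
    1e-9 relative slack; at the default fraction 1.0 this pins the
    optimum (the maximization direction bounds c.v from above already).
    ``z_obj`` defaults to a fresh FBA solve.
    """
    if isinstance(problem, FbaProblem):
        model = problem.constrained_model()
    else:
        model = problem
        problem = FbaProblem(model)
    if z_obj is None:
        base = solve_fba(problem)
        if base.status != "optimal":
            raise FvaError(f"base FBA not optimal (status {base.status}); "
                           "cannot fix Z_obj")
        z_obj = base.objective_value

    S_df = build_stoichiometric_matrix(model)
    rxn_ids = list(S_df.columns)
    S = S_df.to_numpy()
    c = np.array([model.objective.get(rid, 0.0) for rid in rxn_ids])
    bounds = [(model.reactions[rid].lower_bound,
               model.reactions[rid].upper_bound) for rid in rxn_ids]
    target = fraction_of_optimum * z_obj
    slack = 1e-9 * max(1.0, abs(z_obj))
    A_ub = -c.reshape(1, -1)          # c.v >= target - slack
    b_ub = np.array([-(target - slack)])

    subset = list(reactions) if reactions is not None else rxn_ids
    for rid in subset:
        if rid not in S_df.columns:
            raise KeyError(f"unknown reaction {rid!r} in FVA subset")
    index = {rid: j for j, rid in enumerate(rxn_ids)}
    rows = []
    for rid in subset:
        e = np.zeros(len(rxn_ids))
        e[index[rid]] = 1.0
        lo = _solve_lp(S, -e, bounds, A_ub, b_ub)
        hi = _solve_lp(S, e, bounds, A_ub, b_ub)
        if lo.status != 0 or hi.status != 0:
            raise FvaError(
                f"FVA subproblem for {rid!r} not optimal (statuses "
                f"{lo.status}/{hi.status}); consider a fraction_of_optimum "
                "slightly below 1 to relax the objective constraint")
        rows.append({"reaction_id": rid, "minimum": float(lo.x[index[rid]]),
                     "maximum": float(hi.x[index[rid]])})
    df = pd.DataFrame(rows).set_index("reaction_id")
    # clamp the tiny solver noise that can put min a hair above max
    noisy = df["minimum"] > df["maximum"]
    df.loc[noisy, ["minimum", "maximum"]] = df.loc[
        noisy, ["maximum", "minimum"]].to_numpy()
    return FVAResult(z_obj=float(z_obj), ranges=df,
                     fraction_of_optimum=fraction_of_optimum)
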