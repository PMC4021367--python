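"""Independent oracles used by the tests.

These deliberately avoid the library's own solution paths: FBA optima
are re-derived by exhaustive vertex enumeration of the flux polytope,
dead ends by a naive per-metabolite reachability search, and knockout
models by rebuilding from scratch.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Tuple

import numpy as np

from thermoflux.core import MetabolicModel, build_stoichiometric_matrix


def enumerate_vertices_optimum(model: MetabolicModel,
                               tol: float = 1e-9) -> float:
    """Max of the objective over all vertices of {v : S v = 0, bounds}.

    Brute force: every vertex of the polytope pins at least
    n - rank(S) fluxes at a bound; enumerate all such pinnings, solve
    the remaining square-ish system by least squares, and keep feasible
    points.  Only viable for a handful of degrees of freedom.
    """
    S_df = build_stoichiometric_matrix(model)
    S = S_df.to_numpy()
    rxn_ids = list(S_df.columns)
    n = len(rxn_ids)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    c = np.array([model.objective.get(r, 0.0) for r in rxn_ids])
    rank = np.linalg.matrix_rank(S)
    dof = n - rank
    if dof > 6:
        raise ValueError(f"too many free fluxes ({dof}) for enumeration")
    best = None
    for pinned in itertools.combinations(range(n), dof):
        free = [j for j in range(n) if j not in pinned]
        for values in itertools.product(*[(lb[j], ub[j]) for j in pinned]):
            rhs = -S[:, list(pinned)] @ np.array(values)
            sol, residual, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            v = np.empty(n)
            v[list(pinned)] = values
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            obj = float(c @ v)
            if best is None or obj > best:
                best = obj
    if best is None:
        raise ValueError("no feasible vertex found")
    return best


def brute_force_dead_ends(model: MetabolicModel
                          ) -> Tuple[List[str], List[str]]:
    """Root dead ends recomputed from the stoichiometric matrix.

    Works on sign patterns of S rows against the bound-implied
    direction capabilities, metabolite by metabolite — structurally
    unlike the library's scan over reaction direction lists.
    """
    mets = model.metabolite_ids
    rxn_ids = model.reaction_ids
    S = stoichiometric_matrix_rowwise(model)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    internal = np.array([not model.reactions[r].is_exchange
                         for r in rxn_ids])
    boundary = set()
    for rxn in model.exchanges():
        boundary |= set(rxn.stoichiometry)

    no_prod, no_cons = [], []
    for i, mid in enumerate(mets):
        if mid in boundary:
            continue
        row = S[i]
        made = ((row > 0) & (ub > 0) | (row < 0) & (lb < 0)) & internal
        used = ((row < 0) & (ub > 0) | (row > 0) & (lb < 0)) & internal
        if not made.any():
            no_prod.append(mid)
        if not used.any():
            no_cons.append(mid)
    return no_prod, no_cons


def stoichiometric_matrix_rowwise(model: MetabolicModel) -> np.ndarray:
    """S rebuilt metabolite-by-metabolite (independent of the column scan)."""
    rxn_ids = model.reaction_ids
    rows = []
    for mid in model.metabolite_ids:
        rows.append([model.reactions[rid].stoichiometry.get(mid, 0.0)
                     for rid in rxn_ids])
    return np.array(rows)
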