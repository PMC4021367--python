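"""Network curation checks: dead-end metabolites, blocked reactions,
and carbon-source usability.

Dead-end detection is a solver-free connectivity scan for root gaps:
metabolites no allowed reaction direction can ever form (or ever use).
Blocked-reaction detection is the complementary flux-level question —
which reactions can carry no steady-state flux even with every exchange
open — answered per reaction by linear programming.  Together they
reproduce the detection side of gap-finding workflows without the MILP
machinery; gap *filling* stays out of scope (curated repairs are merely
re-verified here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .core import MetabolicModel
from .fba import FbaProblem, MediumSpec, NGAM_REACTION_ID, apply_medium, \
    solve_fba

GROWTH_EPSILON = 1e-6


def _directions(model: MetabolicModel):
    """Expand reactions into allowed one-way (substrates, products) pairs."""
    for rxn in model.reactions.values():
        if rxn.is_exchange:
            continue
        subs = [m for m, c in rxn.stoichiometry.items() if c < 0]
        prods = [m for m, c in rxn.stoichiometry.items() if c > 0]
        if rxn.upper_bound > 0:
            yield rxn.id, subs, prods
        if rxn.lower_bound < 0:
            yield rxn.id, prods, subs


def _boundary_metabolites(model: MetabolicModel) -> Set[str]:
    """Metabolites touching an exchange reaction (environment access).

    Detection is structural: curation asks what the network *could* do,
    so exchanges count regardless of the bounds a medium happens to set.
    """
    out: Set[str] = set()
    for rxn in model.exchanges():
        out |= set(rxn.stoichiometry)
    return out


def find_dead_end_metabolites(model: MetabolicModel
                              ) -> Tuple[List[str], List[str]]:
    """Root dead ends: (no_production, no_consumption) id lists.

    A metabolite is a no_production dead end when no allowed reaction
    direction ever forms it (and it has no exchange), no_consumption
    when no direction ever uses it.  This is the root-gap notion of
    gap-finding tools: branches that are merely downstream of a root
    gap are caught by `find_blocked_reactions`, which asks the
    steady-state (flux) question the connectivity scan cannot answer
    for conserved cofactor pools.
    """
    boundary = _boundary_metabolites(model)
    producible: Set[str] = set(boundary)
    consumable: Set[str] = set(boundary)
    for _rid, subs, prods in _directions(model):
        producible.update(prods)
        consumable.update(subs)
    all_mets = model.metabolite_ids
    return ([m for m in all_mets if m not in producible],
            [m for m in all_mets if m not in consumable])


def open_all_exchanges(model: MetabolicModel) -> MetabolicModel:
    """Rich-medium copy: every exchange opened to (-1000, 1000)."""
    rich = model.copy()
    for rxn in rich.exchanges():
        rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
    return rich


def find_blocked_reactions(model: MetabolicModel,
                           rich_medium: Optional[MediumSpec] = None,
                           tolerance: float = 1e-7) -> List[str]:
    """Reactions whose flux range is {0} even on a rich medium.

    Runs FVA with the objective constraint dropped (every exchange open,
    no growth requirement); a reaction is blocked when both extrema
    vanish.
    """
    if rich_medium is not None:
        probe = apply_medium(model, rich_medium)
    else:
        probe = open_all_exchanges(model)
    # neutral objective: fix Z at 0 over an all-zero c, i.e. unconstrained
    probe.objective = {}
    from .core import build_stoichiometric_matrix
    import numpy as np
    from .fba import _solve_lp

    S_df = build_stoichiometric_matrix(probe)
    S = S_df.to_numpy()
    rxn_ids = list(S_df.columns)
    bounds = [(probe.reactions[rid].lower_bound,
               probe.reactions[rid].upper_bound) for rid in rxn_ids]
    blocked = []
    for j, rid in enumerate(rxn_ids):
        e = np.zeros(len(rxn_ids))
        e[j] = 1.0
        hi = _solve_lp(S, e, bounds)
        if hi.status == 0 and abs(hi.x[j]) > tolerance:
            continue
        lo = _solve_lp(S, -e, bounds)
        if lo.status == 0 and abs(lo.x[j]) > tolerance:
            continue
        blocked.append(rid)
    return blocked


@dataclass
class CarbonSourceResult:
    source: str            # exchange reaction id of the carbon source
    usable: bool
    growth: float
    reason: str = ""


def check_carbon_sources(model: MetabolicModel,
                         sources: Sequence[str],
                         base_medium: MediumSpec,
                         uptake: float = 10.0,
                         ngam: float = 0.0,
                         ngam_reaction: str = NGAM_REACTION_ID
                         ) -> List[CarbonSourceResult]:
    """Growth test with each source as the sole carbon supply.

    ``base_medium`` carries the non-carbon essentials (O2, minerals);
    each candidate exchange is opened to ``uptake`` on top of it.  A
    source is unusable when FBA growth stays below 1e-6 — the signature
    of an assimilation gap.
    """
    results = []
    for source in sources:
        if source not in model.reactions:
            results.append(CarbonSourceResult(source, False, 0.0,
                                              "no exchange reaction"))
            continue
        medium = MediumSpec(
            name=f"{base_medium.name}+{source}",
            bounds={**base_medium.bounds, source: (-abs(uptake), 1000.0)},
            unconstrained=list(base_medium.unconstrained))
        sol = solve_fba(FbaProblem(model, medium, ngam, ngam_reaction))
        mu = sol.objective_value if sol.status == "optimal" else 0.0
        results.append(CarbonSourceResult(
            source, mu > GROWTH_EPSILON, mu,
            "" if mu > GROWTH_EPSILON else "no growth as sole carbon source"))
    return results


@dataclass
class GapReport:
    """Full curation-support report for one model."""

    no_production: List[str]
    no_consumption: List[str]
    blocked_reactions: List[str]
    unusable_sources: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "no_production": self.no_production,
            "no_consumption": self.no_consumption,
            "blocked_reactions": self.blocked_reactions,
            "unusable_sources": self.unusable_sources,
        }


def gap_report(model: MetabolicModel,
               sources: Sequence[str] = (),
               base_medium: Optional[MediumSpec] = None,
               ngam: float = 0.0) -> GapReport:
    no_prod, no_cons = find_dead_end_metabolites(model)
    blocked = find_blocked_reactions(model)
    unusable: List[str] = []
    if sources:
        if base_medium is None:
            raise ValueError("carbon-source checks need a base medium")
        unusable = [r.source for r in
                    check_carbon_sources(model, sources, base_medium,
                                         ngam=ngam) if not r.usable]
    return GapReport(no_prod, no_cons, blocked, unusable)
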