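"""Single-gene deletion screening and essentiality classification.

Deleting a gene disables every reaction whose GPR rule evaluates false
without it (isozymes survive an OR, complexes die with any AND subunit).
Growth ratios mu_KO / mu_WT are computed per medium; a gene is essential
in a medium when the ratio is <= the threshold (default 5%), completely
essential when essential in every medium, conditionally essential when
essential in at least one but not all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .core import MetabolicModel, evaluate_gpr
from .fba import FbaProblem, MediumSpec, NGAM_REACTION_ID, apply_medium, \
    solve_fba

ESSENTIALITY_THRESHOLD = 0.05

COMPLETELY_ESSENTIAL = "completely_essential"
CONDITIONALLY_ESSENTIAL = "conditionally_essential"
NON_ESSENTIAL = "non_essential"


def disabled_reactions(model: MetabolicModel, gene: str) -> List[str]:
    """Reactions knocked out by deleting one gene via the GPR rules."""
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model")
    return [rid for rid, rxn in model.reactions.items()
            if not evaluate_gpr(rxn.gpr, {gene})]


def delete_gene(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Copy of the model with the gene's dependent reactions closed."""
    knocked = model.copy()
    for rid in disabled_reactions(model, gene):
        rxn = knocked.reactions[rid]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return knocked


@dataclass
class DeletionReport:
    """Outcome of a single-deletion scan across media.

    ``growth_wt`` maps medium name to wild-type mu; ``ratios`` is a
    genes x media DataFrame of mu_KO / mu_WT (infeasible knockouts
    score 0); ``disabled`` lists each gene's dependent reactions.
    """

    growth_wt: Dict[str, float]
    ratios: pd.DataFrame
    disabled: Dict[str, List[str]]

    @property
    def media(self) -> List[str]:
        return list(self.ratios.columns)

    @property
    def genes(self) -> List[str]:
        return list(self.ratios.index)


def scan_single_deletions(model: MetabolicModel,
                          media: Sequence[MediumSpec],
                          ngam: float = 0.0,
                          genes: Optional[Iterable[str]] = None,
                          ngam_reaction: str = NGAM_REACTION_ID
                          ) -> DeletionReport:
    """FBA after deleting every gene one at a time, in each medium.

    Wild-type growth is recomputed per medium; a knockout that renders
    the problem infeasible (e.g. the NGAM floor becomes unreachable)
    scores ratio 0.  A non-growing wild type is a configuration error.
    """
    gene_list = sorted(genes) if genes is not None else sorted(model.genes)
    growth_wt: Dict[str, float] = {}
    columns: Dict[str, List[float]] = {}
    disabled = {g: disabled_reactions(model, g) for g in gene_list}
    for medium in media:
        constrained = apply_medium(model, medium, ngam, ngam_reaction)
        wt = solve_fba(constrained)
        if wt.status != "optimal" or wt.objective_value <= 0:
            raise ValueError(
                f"wild type does not grow in medium {medium.name!r} "
                f"(status {wt.status}, mu {wt.objective_value:.3g})")
        growth_wt[medium.name] = wt.objective_value
        ratios: List[float] = []
        for gene in gene_list:
            if not disabled[gene]:
                ratios.append(1.0)
                continue
            knocked = constrained.copy()
            for rid in disabled[gene]:
                knocked.reactions[rid].lower_bound = 0.0
                knocked.reactions[rid].upper_bound = 0.0
            sol = solve_fba(knocked)
            mu = sol.objective_value if sol.status == "optimal" else 0.0
            ratios.append(max(mu, 0.0) / wt.objective_value)
        columns[medium.name] = ratios
    frame = pd.DataFrame(columns, index=gene_list)
    return DeletionReport(growth_wt=growth_wt, ratios=frame,
                          disabled=disabled)


@dataclass
class EssentialityClassification:
    """Per-gene class plus the per-subsystem tally of essential genes."""

    classes: pd.Series                  # gene -> class label
    essential_in: Dict[str, List[str]]  # gene -> media where essential
    subsystem_tally: pd.DataFrame       # subsystem x class counts
    threshold: float

    def count(self, label: str) -> int:
        return int((self.classes == label).sum())


def classify_essentiality(report: DeletionReport,
                          model: Optional[MetabolicModel] = None,
                          threshold: float = ESSENTIALITY_THRESHOLD
                          ) -> EssentialityClassification:
    """Apply the <=threshold rule per medium and tally by subsystem.

    A ratio exactly at the threshold counts as essential (the rule is
    "less than or equal").  The subsystem tally attributes each gene to
    the subsystems of the reactions it participates in.
    """
    essential = report.ratios.le(threshold + 1e-9)
    classes: Dict[str, str] = {}
    essential_in: Dict[str, List[str]] = {}
    for gene in report.genes:
        media_hit = [m for m in report.media if essential.loc[gene, m]]
        essential_in[gene] = media_hit
        if len(media_hit) == len(report.media) and media_hit:
            classes[gene] = COMPLETELY_ESSENTIAL
        elif media_hit:
            classes[gene] = CONDITIONALLY_ESSENTIAL
        else:
            classes[gene] = NON_ESSENTIAL
    series = pd.Series(classes, name="class")

    tally = pd.DataFrame()
    if model is not None:
        gene_subsystems: Dict[str, set] = {g: set() for g in report.genes}
        for rxn in model.reactions.values():
            for g in rxn.genes():
                if g in gene_subsystems:
                    gene_subsystems[g].add(rxn.subsystem)
        rows = []
        for gene in report.genes:
            for subsystem in sorted(gene_subsystems[gene]) or ["(none)"]:
                rows.append({"subsystem": subsystem, "class": classes[gene]})
        if rows:
            tally = (pd.DataFrame(rows)
                     .value_counts(["subsystem", "class"])
                     .unstack(fill_value=0))
    return EssentialityClassification(classes=series,
                                      essential_in=essential_in,
                                      subsystem_tally=tally,
                                      threshold=threshold)
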