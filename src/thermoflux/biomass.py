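"""Biomass equation assembly from compositional measurements.

A biomass pseudo-reaction drains precursors in their measured
proportions, expressed as mmol per gram dry cell weight, plus a
growth-associated maintenance (GAM) ATP hydrolysis.  Coefficients follow
the standard residue-weight scheme: monomer molecular weight minus the
water released on polymerization, so that

    coeff_a = mass_fraction * 1000 * molfrac_a
              / sum_b(molfrac_b * (MW_b - MW_water))

which guarantees that the coefficients of a macromolecule class
reconstruct exactly its gram-per-gDCW mass fraction.

Nucleotide mole fractions derive from genomic GC content: for DNA,
dG = dC = gc/2 and dA = dT = (1-gc)/2; RNA uses the same split with U
in place of T unless a measured table is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

from .core import Reaction
from .gpr import GprExpression

MW_WATER = 18.02

#: average molecular weights of the 20 free amino acids, g mol^-1
AMINO_ACID_MW: Dict[str, float] = {
    "alanine": 89.09, "arginine": 174.20, "asparagine": 132.12,
    "aspartate": 133.10, "cysteine": 121.16, "glutamate": 147.13,
    "glutamine": 146.15, "glycine": 75.07, "histidine": 155.15,
    "isoleucine": 131.17, "leucine": 131.17, "lysine": 146.19,
    "methionine": 149.21, "phenylalanine": 165.19, "proline": 115.13,
    "serine": 105.09, "threonine": 119.12, "tryptophan": 204.23,
    "tyrosine": 181.19, "valine": 117.15,
}

#: deoxyribonucleoside monophosphates, g mol^-1
DNA_NUCLEOTIDE_MW = {"dAMP": 331.22, "dCMP": 307.20,
                     "dGMP": 347.22, "dTMP": 322.21}
#: ribonucleoside monophosphates, g mol^-1
RNA_NUCLEOTIDE_MW = {"AMP": 347.22, "CMP": 323.20,
                     "GMP": 363.22, "UMP": 324.18}

#: free fatty acid species seen in thermophile membranes, g mol^-1
FATTY_ACID_MW = {
    "iso-C15:0": 242.40, "anteiso-C15:0": 242.40,
    "iso-C16:0": 256.42, "n-C16:0": 256.42,
    "iso-C17:0": 270.45, "anteiso-C17:0": 270.45,
}

#: default metabolite ids for biomass precursors (L_XXX[c]-style tokens)
DEFAULT_PRECURSOR_IDS: Dict[str, str] = {
    **{aa: f"L_{aa[:3].upper()}[c]" for aa in AMINO_ACID_MW},
    "glycine": "L_GLY[c]", "glutamine": "L_GLN[c]", "glutamate": "L_GLU[c]",
    "asparagine": "L_ASN[c]", "aspartate": "L_ASP[c]",
    "isoleucine": "L_ILE[c]", "tryptophan": "L_TRP[c]",
    "threonine": "L_THR[c]",
    "dAMP": "DATP[c]", "dCMP": "DCTP[c]", "dGMP": "DGTP[c]",
    "dTMP": "DTTP[c]",
    "AMP": "ATP[c]", "CMP": "CTP[c]", "GMP": "GTP[c]", "UMP": "UTP[c]",
    "iso-C15:0": "FA_ISO15[c]", "anteiso-C15:0": "FA_AISO15[c]",
    "iso-C16:0": "FA_ISO16[c]", "n-C16:0": "FA_N16[c]",
    "iso-C17:0": "FA_ISO17[c]", "anteiso-C17:0": "FA_AISO17[c]",
}


class CompositionError(ValueError):
    pass


@dataclass
class CompositionTable:
    """Measured cell composition feeding the biomass equation.

    mol% blocks each sum to 100 (+-0.1); macromolecule mass fractions
    (g gDCW^-1) sum to 1 (+-1e-3); ``gam_atp`` is the growth-associated
    ATP cost in mmol gDCW^-1.
    """

    amino_acid_molpct: Dict[str, float]
    fatty_acid_molpct: Dict[str, float]
    macromolecule_mass_fractions: Dict[str, float]
    gc_content: float
    gam_atp: float = 0.0

    def __post_init__(self):
        self._check_molpct(self.amino_acid_molpct, AMINO_ACID_MW,
                           "amino acid")
        self._check_molpct(self.fatty_acid_molpct, FATTY_ACID_MW,
                           "fatty acid")
        total = sum(self.macromolecule_mass_fractions.values())
        if abs(total - 1.0) > 1e-3:
            raise CompositionError(
                f"macromolecule mass fractions sum to {total:.4f}, not 1")
        if not (0.0 < self.gc_content < 1.0):
            raise CompositionError(
                f"GC content {self.gc_content} outside (0, 1)")

    @staticmethod
    def _check_molpct(block: Mapping[str, float], known: Mapping[str, float],
                      label: str) -> None:
        if not block:  # class not measured / not present
            return
        for key in block:
            if key not in known:
                raise CompositionError(f"unknown {label} key {key!r}")
        total = sum(block.values())
        if abs(total - 100.0) > 0.1:
            raise CompositionError(
                f"{label} mol% sums to {total:.3f}, not 100")

    def mass_fraction(self, key: str) -> float:
        return self.macromolecule_mass_fractions.get(key, 0.0)


def _residue_coefficients(molpct: Mapping[str, float],
                          mw: Mapping[str, float],
                          mass_fraction: float,
                          water_per_bond: float = MW_WATER
                          ) -> Dict[str, float]:
    """Shared mmol gDCW^-1 conversion for any polymer class."""
    if mass_fraction < 0:
        raise CompositionError(f"negative mass fraction {mass_fraction}")
    for key in molpct:
        if key not in mw:
            raise CompositionError(f"no molecular weight for {key!r}")
    total = sum(molpct.values())
    molfrac = {k: v / total for k, v in molpct.items()}
    mean_residue_mw = sum(molfrac[k] * (mw[k] - water_per_bond)
                          for k in molfrac)
    return {k: mass_fraction * 1000.0 * molfrac[k] / mean_residue_mw
            for k in molfrac}


def amino_acid_coefficients(molpct: Mapping[str, float],
                            protein_mass_fraction: float
                            ) -> Dict[str, float]:
    """Per-amino-acid biomass coefficients, mmol gDCW^-1.

    Residue weights (free amino acid minus peptide-bond water) are used,
    so total protein mass is reconstructed exactly.
    """
    return _residue_coefficients(molpct, AMINO_ACID_MW,
                                 protein_mass_fraction)


def nucleotide_mole_fractions(gc_content: float,
                              rna: bool = False) -> Dict[str, float]:
    """GC-content-implied base split: G = C = gc/2, A = T/U = (1-gc)/2."""
    if not (0.0 < gc_content < 1.0):
        raise CompositionError(f"GC content {gc_content} outside (0, 1)")
    gc, at = gc_content / 2.0, (1.0 - gc_content) / 2.0
    if rna:
        return {"AMP": at, "CMP": gc, "GMP": gc, "UMP": at}
    return {"dAMP": at, "dCMP": gc, "dGMP": gc, "dTMP": at}


def nucleotide_coefficients(gc_content: float, dna_mass_fraction: float,
                            rna_mass_fraction: float,
                            rna_molpct: Optional[Mapping[str, float]] = None
                            ) -> Dict[str, float]:
    """dNMP/NMP biomass coefficients, mmol gDCW^-1.

    DNA mole fractions always follow the GC rule; RNA follows it too
    unless a measured ``rna_molpct`` table is supplied.
    """
    dna_frac = nucleotide_mole_fractions(gc_content, rna=False)
    out = _residue_coefficients({k: v * 100 for k, v in dna_frac.items()},
                                DNA_NUCLEOTIDE_MW, dna_mass_fraction)
    if rna_molpct is None:
        rna_frac = nucleotide_mole_fractions(gc_content, rna=True)
        rna_molpct = {k: v * 100 for k, v in rna_frac.items()}
    out.update(_residue_coefficients(rna_molpct, RNA_NUCLEOTIDE_MW,
                                     rna_mass_fraction))
    return out


def fatty_acid_coefficients(molpct: Mapping[str, float],
                            lipid_mass_fraction: float,
                            water_per_ester_bond: float = MW_WATER
                            ) -> Dict[str, float]:
    """Per-fatty-acid biomass coefficients, mmol gDCW^-1.

    One water per ester bond is subtracted (acyl residue weight), the
    direct analogue of the peptide-bond correction for protein.
    """
    return _residue_coefficients(molpct, FATTY_ACID_MW, lipid_mass_fraction,
                                 water_per_ester_bond)


@dataclass
class BiomassEquation:
    """mmol gDCW^-1 precursor demands plus the GAM ATP term.

    ``precursors`` maps composition keys (amino acid names, nucleotide
    and fatty-acid species) to coefficients; ``residue_mw`` records the
    residue weight used for each so the dry mass can be audited.
    """

    precursors: Dict[str, float]
    residue_mw: Dict[str, float]
    gam_atp: float = 0.0

    def reconstructed_mass(self) -> float:
        """Dry mass implied by the coefficients, g gDCW^-1."""
        return sum(c * self.residue_mw[k] for k, c in self.precursors.items()
                   ) / 1000.0

    def coefficient(self, key: str) -> float:
        return self.precursors.get(key, 0.0)

    def to_reaction(self,
                    precursor_ids: Optional[Mapping[str, str]] = None,
                    reaction_id: str = "BIOMASS") -> Reaction:
        """Render as a biomass Reaction (flux unit h^-1, objective 1).

        GAM appears as ATP + H2O -> ADP + Pi + H folded into the same
        reaction.  ``precursor_ids`` maps composition keys to model
        metabolite ids (defaults to the L_XXX[c]-style tokens).
        """
        ids = dict(DEFAULT_PRECURSOR_IDS)
        if precursor_ids:
            ids.update(precursor_ids)
        stoich: Dict[str, float] = {}
        for key, coeff in self.precursors.items():
            if key not in ids:
                raise CompositionError(
                    f"no metabolite id mapping for precursor {key!r}")
            stoich[ids[key]] = stoich.get(ids[key], 0.0) - coeff
        if self.gam_atp:
            stoich["ATP[c]"] = stoich.get("ATP[c]", 0.0) - self.gam_atp
            stoich["H2O[c]"] = stoich.get("H2O[c]", 0.0) - self.gam_atp
            stoich["ADP[c]"] = stoich.get("ADP[c]", 0.0) + self.gam_atp
            stoich["PI[c]"] = stoich.get("PI[c]", 0.0) + self.gam_atp
        return Reaction(id=reaction_id, stoichiometry=stoich,
                        name="biomass equation", lower_bound=0.0,
                        subsystem="biomass")


def assemble_biomass(table: CompositionTable,
                     mass_closure_tolerance: float = 0.01
                     ) -> BiomassEquation:
    """Merge all precursor blocks of a composition table.

    Raises when the reconstructed dry mass deviates from the covered
    macromolecule fractions by more than ``mass_closure_tolerance``
    (relative).  Classes without composition data (cell wall, soluble
    pool) are not represented and are excluded from the closure target.
    """
    precursors: Dict[str, float] = {}
    residue_mw: Dict[str, float] = {}
    covered_mass = 0.0

    protein = table.mass_fraction("protein")
    if protein and table.amino_acid_molpct:
        precursors.update(amino_acid_coefficients(table.amino_acid_molpct,
                                                  protein))
        residue_mw.update({k: AMINO_ACID_MW[k] - MW_WATER
                           for k in table.amino_acid_molpct})
        covered_mass += protein

    dna, rna = table.mass_fraction("DNA"), table.mass_fraction("RNA")
    if dna or rna:
        precursors.update(nucleotide_coefficients(table.gc_content, dna, rna))
        residue_mw.update({k: v - MW_WATER for k, v in
                           {**DNA_NUCLEOTIDE_MW, **RNA_NUCLEOTIDE_MW}.items()})
        covered_mass += dna + rna

    lipid = table.mass_fraction("lipid")
    if lipid and table.fatty_acid_molpct:
        precursors.update(fatty_acid_coefficients(table.fatty_acid_molpct,
                                                  lipid))
        residue_mw.update({k: FATTY_ACID_MW[k] - MW_WATER
                           for k in table.fatty_acid_molpct})
        covered_mass += lipid

    eq = BiomassEquation(precursors, residue_mw, gam_atp=table.gam_atp)
    if covered_mass > 0:
        gap = abs(eq.reconstructed_mass() - covered_mass) / covered_mass
        if gap > mass_closure_tolerance:
            raise CompositionError(
                f"biomass mass closure violated: reconstructed "
                f"{eq.reconstructed_mass():.4f} g vs covered fractions "
                f"{covered_mass:.4f} g (relative gap {gap:.2%})")
    return eq


@dataclass
class CompositionDelta:
    """Per-component differences between two composition tables."""

    amino_acid_molpct: Dict[str, float]
    fatty_acid_molpct: Dict[str, float]
    macromolecule_mass_fractions: Dict[str, float]
    gc_content: float


def compare_compositions(table_a: CompositionTable,
                         table_b: CompositionTable) -> CompositionDelta:
    """Signed deltas (a minus b); key sets must match per block."""
    def diff(a: Mapping[str, float], b: Mapping[str, float],
             label: str) -> Dict[str, float]:
        if set(a) != set(b):
            raise CompositionError(
                f"{label} key mismatch: {sorted(set(a) ^ set(b))}")
        return {k: a[k] - b[k] for k in a}

    return CompositionDelta(
        diff(table_a.amino_acid_molpct, table_b.amino_acid_molpct,
             "amino acid"),
        diff(table_a.fatty_acid_molpct, table_b.fatty_acid_molpct,
             "fatty acid"),
        diff(table_a.macromolecule_mass_fractions,
             table_b.macromolecule_mass_fractions, "macromolecule"),
        table_a.gc_content - table_b.gc_content,
    )
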