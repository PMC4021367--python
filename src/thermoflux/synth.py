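"""Deterministic synthetic models for quantitative testing.

Two generators:

* planted-optimum toy networks — parallel substrate->precursor chains
  whose FBA optimum has the closed form mu* = min_k(u_k * y_k / a_k)
  (uptake bound times pathway yield over biomass coefficient), computed
  here in exact rational arithmetic so the LP answer can be checked to
  solver precision;

* a ~45-reaction thermophile-style fixture with the hallmarks of a
  Thermus-like network: ATP-coupled ABC sugar import (no PTS),
  a glycolysis/TCA/oxidative-phosphorylation skeleton, an ATP
  maintenance reaction, branched-chain amino-acid uptake and
  transamination feeding branched-chain fatty-acid synthesis, and a
  linear carotenoid chain of single-gene essential steps ending in a
  zeaxanthin glucoside ester.  It grows on a defined glucose minimal
  medium (DMM-like) and faster on an amino-acid-supplemented complex
  medium (TM-like).

Everything is seed-deterministic and regenerated in memory; nothing is
downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .biomass import CompositionTable
from .core import MetabolicModel, Metabolite, Reaction
from .io import MediumSpec

#: maintenance ATP floor used with the thermophile fixture, mmol gDCW^-1 h^-1
FIXTURE_NGAM = 14.0


# ---------------------------------------------------------------------
# planted-optimum networks
# ---------------------------------------------------------------------

@dataclass
class SyntheticNetworkSpec:
    """Blueprint of a planted-optimum network.

    Chain k imports substrate k at up to ``uptakes[k]``, converts it
    through ``chain_lengths[k]`` steps with overall molar yield
    ``yields_[k]`` into precursor k, which biomass consumes at
    ``biomass_coeffs[k]``.  ``redundancy`` optionally gives the final
    step of a chain an isozyme pair ("or") or a two-subunit complex
    ("and"); ``defects`` removes numbered steps to plant gaps.
    """

    seed: int = 0
    n_chains: int = 2
    chain_lengths: Sequence[int] = (1, 1)
    yields_: Sequence[Fraction] = (Fraction(1), Fraction(1))
    uptakes: Sequence[Fraction] = (Fraction(10), Fraction(10))
    biomass_coeffs: Sequence[Fraction] = (Fraction(1), Fraction(1))
    redundancy: Dict[int, str] = field(default_factory=dict)
    defects: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        n = self.n_chains
        for name in ("chain_lengths", "yields_", "uptakes",
                     "biomass_coeffs"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length n_chains={n}")
        if any(l < 1 for l in self.chain_lengths):
            raise ValueError("chain lengths must be >= 1")
        if any(Fraction(y) <= 0 for y in self.yields_):
            raise ValueError("yields must be positive")
        if any(Fraction(a) <= 0 for a in self.biomass_coeffs):
            raise ValueError("biomass coefficients must be positive")
        if any(Fraction(u) < 0 for u in self.uptakes):
            raise ValueError("uptake bounds must be non-negative")
        for k, kind in self.redundancy.items():
            if kind not in ("or", "and"):
                raise ValueError(f"redundancy kind {kind!r} for chain {k}")

    def analytic_optimum(self) -> Fraction:
        """mu* = min_k(u_k * y_k / a_k); 0 if any chain is defective."""
        if self.defects:
            return Fraction(0)
        return min(Fraction(u) * Fraction(y) / Fraction(a)
                   for u, y, a in zip(self.uptakes, self.yields_,
                                      self.biomass_coeffs))


def generate_planted_network(spec: SyntheticNetworkSpec
                             ) -> Tuple[MetabolicModel, Fraction]:
    """Materialize the blueprint; returns (model, analytic mu*)."""
    model = MetabolicModel(f"planted_seed{spec.seed}")
    defect_set = set(spec.defects)
    for k in range(spec.n_chains):
        ext = f"S{k}[e]"
        model.add_metabolite(Metabolite(ext, f"substrate {k}"))
        intermediates = [f"X{k}_{i}[c]" for i in range(spec.chain_lengths[k])]
        for mid in intermediates:
            model.add_metabolite(Metabolite(mid))
        precursor = f"P{k}[c]"
        model.add_metabolite(Metabolite(precursor, f"precursor {k}"))

        model.add_reaction(Reaction(
            id=f"EX_S{k}", stoichiometry={ext: -1.0},
            name=f"substrate {k} exchange",
            lower_bound=-float(Fraction(spec.uptakes[k])),
            upper_bound=1000.0, subsystem="exchange"))
        model.add_reaction(Reaction(
            id=f"T{k}", stoichiometry={ext: -1.0, intermediates[0]: 1.0},
            name=f"substrate {k} transport", subsystem="transport",
            gpr=f"G{k}T"))
        chain = intermediates + [precursor]
        for i in range(len(chain) - 1):
            if (k, i) in defect_set:
                continue
            last = i == len(chain) - 2
            product_coeff = float(Fraction(spec.yields_[k])) if last else 1.0
            if last and spec.redundancy.get(k) == "or":
                gpr = f"G{k}F_A or G{k}F_B"
            elif last and spec.redundancy.get(k) == "and":
                gpr = f"G{k}F_A and G{k}F_B"
            else:
                gpr = f"G{k}C{i}"
            model.add_reaction(Reaction(
                id=f"C{k}_{i}",
                stoichiometry={chain[i]: -1.0, chain[i + 1]: product_coeff},
                name=f"chain {k} step {i}", subsystem="carbohydrates",
                gpr=gpr))
    biomass_stoich = {f"P{k}[c]": -float(Fraction(spec.biomass_coeffs[k]))
                      for k in range(spec.n_chains)}
    model.add_reaction(Reaction(
        id="BIOMASS", stoichiometry=biomass_stoich, name="biomass drain",
        subsystem="biomass"))
    model.set_objective("BIOMASS")
    return model, spec.analytic_optimum()


_YIELD_CHOICES = [Fraction(1), Fraction(2), Fraction(1, 2), Fraction(3),
                  Fraction(1, 3), Fraction(3, 2), Fraction(2, 3)]


def random_planted_spec(seed: int) -> SyntheticNetworkSpec:
    """A seeded random blueprint (no defects) for property sweeps."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 5))
    lengths = [int(rng.integers(1, 4)) for _ in range(n)]
    yields_ = [_YIELD_CHOICES[int(rng.integers(len(_YIELD_CHOICES)))]
               for _ in range(n)]
    uptakes = [Fraction(int(rng.integers(1, 21))) for _ in range(n)]
    coeffs = [Fraction(int(rng.integers(1, 6))) for _ in range(n)]
    redundancy = {}
    for k in range(n):
        r = rng.random()
        if r < 0.3:
            redundancy[k] = "or"
        elif r < 0.5:
            redundancy[k] = "and"
    return SyntheticNetworkSpec(seed=seed, n_chains=n, chain_lengths=lengths,
                                yields_=yields_, uptakes=uptakes,
                                biomass_coeffs=coeffs, redundancy=redundancy)


# ---------------------------------------------------------------------
# thermophile-style fixture
# ---------------------------------------------------------------------

#: simplified carbon skeleton counts for the fixture metabolites
_FIXTURE_CARBONS = {
    "GLC": 6, "O2": 0, "NH4": 0, "PI": 0, "H2O": 0, "CO2": 1, "AC": 2,
    "L_LEU": 6, "L_VAL": 5, "L_ILE": 6, "L_GLU": 5, "L_ALA": 3,
    "PYR": 3, "ACCOA": 2, "OAA": 4, "AKG": 5,
    "ATP": 0, "ADP": 0, "NAD": 0, "NADH": 0, "NADP": 0, "NADPH": 0,
    "FAD": 0, "FADH2": 0,
    "KIV": 5, "KIC": 6, "KMV": 6,
    "FA_ISO15": 15, "FA_AISO15": 15,
    "PHYT": 40, "LYCO": 40, "ZEAX": 40, "TZEA": 61, "ZEAX_GLC": 46,
}

#: biomass demand coefficients of the fixture, mmol gDCW^-1
FIXTURE_BIOMASS_COEFFS = {
    "L_ALA[c]": 0.5, "L_GLU[c]": 0.5, "L_LEU[c]": 0.35, "L_VAL[c]": 0.3,
    "L_ILE[c]": 0.2, "FA_ISO15[c]": 0.15, "FA_AISO15[c]": 0.05,
    "TZEA[c]": 0.01,
}
#: growth-associated maintenance of the fixture biomass, mmol gDCW^-1
FIXTURE_GAM = 40.0
#: net phosphate incorporated per gDCW (nucleic-acid phosphorus), mmol
FIXTURE_PHOSPHATE = 0.5

#: the four-step linear carotenoid chain: every gene completely essential
CAROTENOID_CHAIN_GENES = ("STH0101", "STH0102", "STH0103", "STH0104")
#: branched-chain amino-acid biosynthesis genes: essential on minimal only
BCAA_PATHWAY_GENES = ("STH0032", "STH0033", "STH0034", "STH0035")


@dataclass
class ThermophileFixture:
    model: MetabolicModel
    dmm: MediumSpec
    tm: MediumSpec
    composition: CompositionTable

    def __iter__(self):
        return iter((self.model, self.dmm, self.tm, self.composition))


def thermophile_composition() -> CompositionTable:
    """Synthetic-but-realistic thermophile composition (70 C style).

    The amino-acid and fatty-acid mol% profiles are plausible inventions
    shaped like thermophile measurements (branched-chain-rich membrane,
    elevated Val/Ile), not any organism's published numbers; GC content
    0.694 and the GAM of 58.34 mmol gDCW^-1 follow common practice for
    thermophile models.
    """
    return CompositionTable(
        amino_acid_molpct={
            "alanine": 10.5, "arginine": 5.5, "asparagine": 3.5,
            "aspartate": 5.5, "cysteine": 0.9, "glutamate": 8.0,
            "glutamine": 3.8, "glycine": 8.8, "histidine": 1.8,
            "isoleucine": 5.9, "leucine": 9.8, "lysine": 4.2,
            "methionine": 2.0, "phenylalanine": 3.7, "proline": 4.6,
            "serine": 4.2, "threonine": 5.2, "tryptophan": 1.1,
            "tyrosine": 2.9, "valine": 8.1,
        },
        fatty_acid_molpct={
            "iso-C15:0": 32.0, "iso-C17:0": 42.0, "anteiso-C15:0": 12.0,
            "anteiso-C17:0": 8.0, "iso-C16:0": 6.0,
        },
        macromolecule_mass_fractions={
            "protein": 0.55, "RNA": 0.16, "DNA": 0.03, "lipid": 0.09,
            "cell_wall": 0.10, "other": 0.07,
        },
        gc_content=0.694,
        gam_atp=58.34,
    )


def build_thermophile_fixture() -> ThermophileFixture:
    """The version-pinned thermophile-like test network.

    Deterministic (no randomness); metabolite formulas carry simplified
    carbon-skeleton counts so every internal reaction is carbon-balanced
    by construction.  The zeaxanthin monoglucoside side product has no
    consumer — a deliberate planted gap for the dead-end/blocked-
    reaction checks.
    """
    m = MetabolicModel("thermophile_fixture")
    for base, carbons in _FIXTURE_CARBONS.items():
        for comp in ("c", "e"):
            mid = f"{base}[{comp}]"
            if comp == "e" and base not in (
                    "GLC", "O2", "NH4", "PI", "H2O", "CO2", "AC",
                    "L_LEU", "L_VAL", "L_ILE", "L_GLU"):
                continue
            m.add_metabolite(Metabolite(mid, base, {"C": carbons}))

    def rxn(rid, stoich, name, subsystem, gpr="", lb=0.0, ub=1000.0):
        m.add_reaction(Reaction(id=rid, stoichiometry=stoich, name=name,
                                lower_bound=lb, upper_bound=ub,
                                subsystem=subsystem, gpr=gpr))

    # exchanges (uptake-negative; media set the actual bounds)
    for base in ("GLC", "O2", "NH4", "PI", "H2O", "CO2", "AC",
                 "L_LEU", "L_VAL", "L_ILE", "L_GLU"):
        rxn(f"EX_{base}", {f"{base}[e]": -1.0}, f"{base} exchange",
            "exchange", lb=0.0)

    # ATP-coupled ABC import (no PTS) and passive diffusion
    rxn("ABC_GLC", {"GLC[e]": -1, "ATP[c]": -1, "H2O[c]": -1,
                    "GLC[c]": 1, "ADP[c]": 1, "PI[c]": 1},
        "glucose ABC transporter", "transport", "STH0010 and STH0011")
    for aa in ("L_LEU", "L_VAL", "L_ILE"):
        rxn(f"ABC_{aa}", {f"{aa}[e]": -1, "ATP[c]": -1, "H2O[c]": -1,
                          f"{aa}[c]": 1, "ADP[c]": 1, "PI[c]": 1},
            f"{aa} ABC transporter", "transport", "STH0012 and STH0011")
    rxn("ABC_L_GLU", {"L_GLU[e]": -1, "ATP[c]": -1, "H2O[c]": -1,
                      "L_GLU[c]": 1, "ADP[c]": 1, "PI[c]": 1},
        "glutamate ABC transporter", "transport", "STH0013 and STH0011")
    for base in ("O2", "NH4", "PI", "H2O", "CO2", "AC"):
        rxn(f"{base}t", {f"{base}[e]": -1, f"{base}[c]": 1},
            f"{base} diffusion", "transport", lb=-1000.0)

    # central carbon core (lumped)
    rxn("GLYC", {"GLC[c]": -1, "ADP[c]": -2, "PI[c]": -2, "NAD[c]": -2,
                 "PYR[c]": 2, "ATP[c]": 2, "NADH[c]": 2, "H2O[c]": 2},
        "glycolysis (lumped)", "carbohydrates", "STH0020")
    rxn("PDH", {"PYR[c]": -1, "NAD[c]": -1,
                "ACCOA[c]": 1, "CO2[c]": 1, "NADH[c]": 1},
        "pyruvate dehydrogenase", "carbohydrates", "STH0021 and STH0022")
    rxn("TCA", {"ACCOA[c]": -1, "NAD[c]": -3, "FAD[c]": -1, "ADP[c]": -1,
                "PI[c]": -1, "H2O[c]": -2,
                "CO2[c]": 2, "NADH[c]": 3, "FADH2[c]": 1, "ATP[c]": 1},
        "TCA cycle (lumped)", "energy and cofactors", "STH0023")
    rxn("OXPHOS_NADH", {"NADH[c]": -1, "O2[c]": -0.5, "ADP[c]": -2,
                        "PI[c]": -2, "NAD[c]": 1, "ATP[c]": 2, "H2O[c]": 3},
        "NADH oxidative phosphorylation", "energy and cofactors", "STH0024")
    rxn("OXPHOS_FADH", {"FADH2[c]": -1, "O2[c]": -0.5, "ADP[c]": -1,
                        "PI[c]": -1, "FAD[c]": 1, "ATP[c]": 1, "H2O[c]": 2},
        "FADH2 oxidative phosphorylation", "energy and cofactors", "STH0025")
    rxn("ATPM", {"ATP[c]": -1, "H2O[c]": -1, "ADP[c]": 1, "PI[c]": 1},
        "ATP maintenance", "energy and cofactors")
    rxn("ACK", {"ACCOA[c]": -1, "ADP[c]": -1, "PI[c]": -1,
                "AC[c]": 1, "ATP[c]": 1},
        "acetate overflow (lumped kinase)", "carbohydrates", "STH0026")
    rxn("PYC", {"PYR[c]": -1, "CO2[c]": -1, "ATP[c]": -1, "H2O[c]": -1,
                "OAA[c]": 1, "ADP[c]": 1, "PI[c]": 1},
        "pyruvate carboxylase", "carbohydrates", "STH0027")
    rxn("CS_AKG", {"OAA[c]": -1, "ACCOA[c]": -1, "NAD[c]": -1, "H2O[c]": -1,
                   "AKG[c]": 1, "CO2[c]": 1, "NADH[c]": 1},
        "oxoglutarate synthesis (lumped)", "carbohydrates", "STH0028")
    rxn("THD", {"NADH[c]": -1, "NADP[c]": -1, "NAD[c]": 1, "NADPH[c]": 1},
        "transhydrogenase", "energy and cofactors", "STH0029")
    rxn("AKGDH", {"AKG[c]": -1, "NAD[c]": -4, "ADP[c]": -1, "PI[c]": -1,
                  "H2O[c]": -3, "CO2[c]": 5, "NADH[c]": 4, "ATP[c]": 1},
        "oxoglutarate oxidation (lumped)", "energy and cofactors", "STH0036")

    # amino-acid metabolism
    rxn("GDH", {"AKG[c]": -1, "NH4[c]": -1, "NADPH[c]": -1,
                "L_GLU[c]": 1, "NADP[c]": 1, "H2O[c]": 1},
        "glutamate dehydrogenase", "amino acid", "STH0030", lb=-1000.0)
    rxn("ALADH", {"PYR[c]": -1, "NH4[c]": -1, "NADH[c]": -1,
                  "L_ALA[c]": 1, "NAD[c]": 1, "H2O[c]": 1},
        "alanine dehydrogenase", "amino acid", "STH0031", lb=-1000.0)
    rxn("KIVS", {"PYR[c]": -2, "NADPH[c]": -1,
                 "KIV[c]": 1, "CO2[c]": 1, "NADP[c]": 1, "H2O[c]": 1},
        "ketoisovalerate synthesis (lumped)", "amino acid", "STH0032")
    rxn("VALTA", {"KIV[c]": -1, "L_GLU[c]": -1,
                  "L_VAL[c]": 1, "AKG[c]": 1},
        "valine transaminase", "amino acid", "STH0033", lb=-1000.0)
    rxn("KICS", {"KIV[c]": -1, "ACCOA[c]": -1, "NAD[c]": -1, "H2O[c]": -1,
                 "KIC[c]": 1, "CO2[c]": 1, "NADH[c]": 1},
        "ketoisocaproate synthesis (lumped)", "amino acid", "STH0034")
    rxn("LEUTA", {"KIC[c]": -1, "L_GLU[c]": -1,
                  "L_LEU[c]": 1, "AKG[c]": 1},
        "leucine transaminase", "amino acid", "STH0033", lb=-1000.0)
    rxn("KMVS", {"OAA[c]": -1, "PYR[c]": -1, "NADPH[c]": -1,
                 "KMV[c]": 1, "CO2[c]": 1, "NADP[c]": 1, "H2O[c]": 1},
        "ketomethylvalerate synthesis (lumped)", "amino acid", "STH0035")
    rxn("ILETA", {"KMV[c]": -1, "L_GLU[c]": -1,
                  "L_ILE[c]": 1, "AKG[c]": 1},
        "isoleucine transaminase", "amino acid", "STH0033", lb=-1000.0)

    # branched-chain fatty acids from BCAA-derived primers
    for rid, primer, product in (("FAS_ISO15", "KIC[c]", "FA_ISO15[c]"),
                                 ("FAS_AISO15", "KMV[c]", "FA_AISO15[c]")):
        rxn(rid, {primer: -1, "ACCOA[c]": -5, "ATP[c]": -5, "NADPH[c]": -10,
                  "H2O[c]": -5, product: 1, "CO2[c]": 1, "NADP[c]": 10,
                  "ADP[c]": 5, "PI[c]": 5},
            f"branched-chain fatty-acid synthase ({product[:-3]})",
            "lipids", "STH0049 or STH0045")

    # linear carotenoid chain ending in the glucoside ester
    rxn("CRT1", {"ACCOA[c]": -20, "ATP[c]": -16, "NADPH[c]": -16,
                 "H2O[c]": -16, "PHYT[c]": 1, "ADP[c]": 16, "PI[c]": 16,
                 "NADP[c]": 16},
        "phytoene synthesis (lumped)", "carotenoids", "STH0101")
    rxn("CRT2", {"PHYT[c]": -1, "NAD[c]": -2, "LYCO[c]": 1, "NADH[c]": 2},
        "phytoene desaturase", "carotenoids", "STH0102")
    rxn("CRT3", {"LYCO[c]": -1, "O2[c]": -1, "NADPH[c]": -1,
                 "ZEAX[c]": 1, "NADP[c]": 1, "H2O[c]": 1},
        "lycopene cyclase/hydroxylase (lumped)", "carotenoids", "STH0103")
    rxn("CRT4", {"ZEAX[c]": -1, "GLC[c]": -1, "FA_ISO15[c]": -1,
                 "TZEA[c]": 1, "H2O[c]": 2},
        "zeaxanthin glucosyl/acyl transfer", "carotenoids", "STH0104")
    rxn("CRT5", {"ZEAX[c]": -1, "GLC[c]": -1, "ZEAX_GLC[c]": 1,
                 "H2O[c]": 1},
        "zeaxanthin monoglucoside side branch", "carotenoids", "STH0105")

    # biomass: hard AND over precursors, GAM folded in
    biomass_stoich = {mid: -coeff
                      for mid, coeff in FIXTURE_BIOMASS_COEFFS.items()}
    biomass_stoich.update({"ATP[c]": -FIXTURE_GAM, "H2O[c]": -FIXTURE_GAM,
                           "ADP[c]": FIXTURE_GAM,
                           "PI[c]": FIXTURE_GAM - FIXTURE_PHOSPHATE})
    m.add_reaction(Reaction(id="BIOMASS", stoichiometry=biomass_stoich,
                            name="thermophile biomass equation",
                            subsystem="biomass"))
    m.set_objective("BIOMASS")

    dmm = MediumSpec(
        name="DMM_like",
        bounds={"EX_GLC": (-2.0, 1000.0), "EX_O2": (-10.0, 1000.0)},
        unconstrained=["EX_NH4", "EX_PI", "EX_H2O", "EX_CO2"])
    tm = MediumSpec(
        name="TM_like",
        bounds={"EX_GLC": (-2.0, 1000.0), "EX_O2": (-10.0, 1000.0),
                "EX_L_LEU": (-1.4, 1000.0), "EX_L_VAL": (-0.25, 1000.0),
                "EX_L_ILE": (-0.5, 1000.0), "EX_L_GLU": (-1.5, 1000.0)},
        unconstrained=["EX_NH4", "EX_PI", "EX_H2O", "EX_CO2"])
    return ThermophileFixture(m, dmm, tm, thermophile_composition())


def generate_media_pair(seed: int) -> Tuple[MediumSpec, MediumSpec]:
    """A seeded random (minimal-like, complex-like) medium pair.

    The minimal medium has glucose as sole carbon source; the complex
    one adds branched-chain amino acids and glutamate.  Ranges are
    chosen so the fixture wild type stays feasible at the standard
    maintenance floor.
    """
    rng = np.random.default_rng(seed)
    glc = -round(float(rng.uniform(1.5, 5.0)), 3)
    o2 = -round(float(rng.uniform(6.0, 15.0)), 3)
    minimal = MediumSpec(
        name=f"minimal_seed{seed}",
        bounds={"EX_GLC": (glc, 1000.0), "EX_O2": (o2, 1000.0)},
        unconstrained=["EX_NH4", "EX_PI", "EX_H2O", "EX_CO2"])
    complex_bounds = dict(minimal.bounds)
    complex_bounds.update({
        "EX_L_LEU": (-round(float(rng.uniform(0.5, 2.0)), 3), 1000.0),
        "EX_L_VAL": (-round(float(rng.uniform(0.1, 0.6)), 3), 1000.0),
        "EX_L_ILE": (-round(float(rng.uniform(0.2, 1.0)), 3), 1000.0),
        "EX_L_GLU": (-round(float(rng.uniform(0.5, 2.5)), 3), 1000.0),
    })
    rich = MediumSpec(name=f"complex_seed{seed}", bounds=complex_bounds,
                      unconstrained=list(minimal.unconstrained))
    return minimal, rich
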