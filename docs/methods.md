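# Methods

## Model representation and conventions

A model is a set of compartmented metabolites (`[c]` cytosol, `[e]`
extracellular), an ordered list of reactions with flux bounds in mmol
gDCW⁻¹ h⁻¹, GPR boolean rules over locus tags, and a linear objective.
Exchange pseudo-reactions `met[e] ⇌ ∅` connect the extracellular
compartment to the environment; their bounds encode the medium, with
uptake negative and secretion positive.  Two compartments suffice for
every analysis here; a periplasm is deliberately not modelled.
Reporting functions that mirror nutrient-consumption tables flip the
sign so that positive "supply" means consumption — the conversion is
centralized in `thermoflux.compare` to avoid double negations.

Defaults chosen where the field has conventions but no single standard:
reversible reactions get bounds (−1000, 1000) and irreversible (0,
1000) — an "effectively unbounded" sentinel; the steady-state and
elemental-balance tolerance is 10⁻⁶ absolute, a typical LP feasibility
tolerance.  Gene tokens are case-sensitive exact locus tags.  OD600 is
converted to dry cell weight with the fixed factor 0.34 g L⁻¹ per OD
unit used for *T. thermophilus* cultures.

## Linear programming

FBA and FVA are solved with scipy's HiGHS interface.  HiGHS is
deterministic under a fixed input, so repeated runs return identical
optimal vertices and the pipeline's TSV outputs are byte-reproducible.
Infeasible problems (e.g. an NGAM floor that a knockout can no longer
meet) are reported as growth 0 with the status preserved, so deletion
scans never abort; an unbounded objective is reported explicitly since
it signals a missing exchange closure, not biology.

FVA fixes the objective through the inequality c·v ≥ f·Z_obj − 10⁻⁹
max(1, |Z_obj|), with fraction-of-optimum f defaulting to 1.0.  Pure
equality is the textbook formulation but numerically brittle; because
the objective is maximized, the inequality at f = 1 pins the optimum to
solver precision while the tiny relative slack absorbs round-off.  The
resulting ranges satisfy the sandwich v_lo − ε ≤ v_FBA ≤ v_hi + ε with
ε = 10⁻⁶, asserted in the tests.

## Media and maintenance

A medium is a named map from exchange ids to (lower, upper) bounds plus
a list of exchanges left unconstrained at (−1000, 1000) — the water and
mineral supplies.  Applying a medium closes every unlisted exchange to
uptake only (lower bound 0); secretion stays open, since a medium
specifies what the environment offers, not what the cell may excrete.
NGAM is imposed as a lower bound on the ATP-maintenance reaction
(`ATPM` by convention); GAM is a stoichiometric ATP + H2O → ADP + Pi
term folded into the biomass reaction itself, the usual GSMM practice.
The loader does not try to guess whether an externally supplied biomass
equation already contains its GAM term; callers assembling a biomass
equation here control the GAM explicitly through the composition table.

## Biomass assembly

For any polymer class with mol% composition m_a, class mass fraction w
(g gDCW⁻¹), and monomer weights MW_a, the precursor coefficients are

    coeff_a = w · 1000 · m_a / Σ_b m_b (MW_b − MW_water)   [mmol gDCW⁻¹]

i.e. residue weights with the water of polymerization subtracted, so
that Σ coeff·residue-MW reconstructs exactly w.  The same scheme covers
protein (peptide bonds), nucleic acids (phosphodiester assembly,
residue = nucleoside monophosphate − water) and lipids (one water per
ester bond).  Nucleotide mole fractions derive from GC content — dG =
dC = gc/2, dA = dT = (1−gc)/2 — and RNA follows the same split with U
for T unless a measured RNA table is supplied; thermophile genomic data
usually offers GC content long before a measured RNA base composition.
Assembly fails loudly if the reconstructed dry mass deviates from the
covered mass fractions by more than 1 % (relative).  Classes without
monomer data (cell wall, soluble pool) are excluded from both the
equation and the closure target rather than faked.

## Gene deletions and essentiality

Deleting a gene closes every reaction whose GPR evaluates false without
it.  Growth ratios μ_KO/μ_WT are computed per medium with the wild type
re-solved in that same medium.  The classification rule is ratio ≤ 0.05
(essential at exactly the threshold), completely vs conditionally
essential distinguishing all-media from some-media essentiality.
Knockouts that render the LP infeasible score ratio 0: with an NGAM
floor, "cannot even pay maintenance" is the extreme form of growth
arrest, not an error.

## Network QC

Dead-end detection reports *root* gaps: metabolites no allowed reaction
direction can ever produce (or consume), with exchange metabolites
exempt.  An earlier propagation-based design (transitively marking
metabolites unreachable from the exchanges) was abandoned: on networks
with conserved cofactor pools (ATP/ADP, NAD/NADH) a least-fixpoint
propagation deadlocks — no cofactor is ever "reachable first" — while a
greatest-fixpoint variant wrongly lets conservative cycles absorb net
input.  The root definition is exact, solver-free, and matches what
gap-finding tools flag as root no-production/no-consumption metabolites;
everything downstream of a root gap is caught instead by
`find_blocked_reactions`, which asks the flux-level question (FVA with
the objective constraint dropped, every exchange open) that connectivity
reasoning cannot answer correctly.  Carbon-source checks open one
candidate exchange at a time over a mineral base medium and call a
source unusable below a growth of 10⁻⁶ — the signature of an
assimilation gap such as a missing disaccharide hydrolase.  Gap
*filling* is out of scope; the module verifies user-supplied repairs.

## Amino-acid supply/demand accounting

For each cytosolic amino acid in an optimal solution: supply is the net
delivery by transport reactions (positive = consumed from the medium),
demand is μ times the biomass coefficient, and the net production by
all other internal reactions is split one-sidedly into from_others
(positive part) and to_others (negative part), matching the one-sided
columns of published consumption tables.  The row identity supply +
from_others = demand + to_others is a theorem of steady state, so the
builder *asserts* it to 10⁻³ and raises on violation instead of
normalizing silently.  `close_balance_row` solves the same identity for
one unknown column, which is how the bundled published table is audited.
For rows with negative supply the value itself is the answer to the
secreted-versus-not-consumed ambiguity: net secretion appears as
supply < 0, pure non-consumption as supply = 0, so both interpretations
are readable from the same column.

## Synthetic data

**Planted-optimum networks.**  Parallel chains import substrate k at up
to u_k, convert it with molar yield y_k into a dedicated biomass
precursor consumed at coefficient a_k.  Because the chains share
nothing, the LP optimum is exactly μ* = min_k(u_k·y_k/a_k), computed in
`fractions.Fraction` arithmetic and compared against the solver at
10⁻⁸.  Blueprints are seed-deterministic; optional isozyme pairs ("or"),
complexes ("and") and planted defects exercise the GPR and QC paths.
This closed-form family stands in for measured uptake rates wherever a
quantitative oracle is needed, so FBA/FVA/deletion logic is checkable
with zero external data.

**Thermophile fixture.**  A deterministic ~45-reaction network with the
hallmarks of a *Thermus*-like system: ATP-coupled ABC import of glucose
and amino acids (no PTS), lumped glycolysis/TCA/oxidative
phosphorylation with an O₂ requirement, an ATPM reaction (NGAM 14 mmol
gDCW⁻¹ h⁻¹ in the standard runs), transaminase-mediated
valine/leucine/isoleucine metabolism feeding iso/anteiso fatty-acid
synthesis, a linear four-step carotenoid chain ending in a zeaxanthin
glucoside ester that biomass requires, and a deliberately dead-ended
zeaxanthin monoglucoside side branch as a planted QC target.  Metabolite
formulas carry simplified carbon-skeleton counts (cofactors count 0) so
every internal reaction is carbon-balanced by construction.  The biomass
draws five amino acids, two fatty acids, the carotenoid ester, a small
net phosphate (nucleic-acid phosphorus — without it phosphate would
only cycle through the adenylate pool and its exchange would be
blocked), and 40 mmol GAM ATP.  The two media are a glucose minimal
medium (glucose ≤ 2, O₂ ≤ 10 mmol gDCW⁻¹ h⁻¹, minerals unconstrained)
and a complex medium adding bounded uptakes of leucine, valine,
isoleucine and glutamate.  The fixture is constructed so that complex-
medium growth exceeds minimal-medium growth by ≥ 1.5× (measured: ~1.86),
every carotenoid-chain gene is completely essential, and the
branched-chain biosynthesis genes are essential on minimal medium only —
the qualitative physiology of interest.  What the fixture does *not*
emulate: genome scale (hundreds of reactions), full elemental balancing
(H/O/N/P), thermodynamic constraints, and measured uptake kinetics;
tests passing on it demonstrate algorithmic correctness and qualitative
behavior, not numerical agreement with any real organism.

**Composition table.**  The default thermophile composition (branched-
chain-rich fatty acids, Val/Ile-elevated protein, GC 0.694, GAM 58.34
mmol gDCW⁻¹) is synthetic-but-realistic: shaped like thermophile
measurements but not any organism's published numbers.

## File formats

Tabular models are 7-column TSVs (id, name, reaction string, GPR,
subsystem, bounds); reaction strings accept the spaced arrow variants
`"< = >"` / `"- >"` that appear in print but are always written
compactly.  SBML I/O targets level 2 version 1 with the pre-fbc
conventions: GPRs as `GENE_ASSOCIATION:` note lines, bounds and
objective coefficients as kinetic-law parameters; the reader tolerates
absent GPR notes (counting them) and unfamiliar subsystem labels rather
than failing on third-party files, but rejects other SBML levels
explicitly.  Media are JSON/YAML mappings `{name, bounds: {id: [lb,
ub]}, unconstrained: [ids]}`; an empty file is a fully closed medium.

## Problem sizes

The test suite and the acceptance script run entirely on the synthetic
generators: 100-network planted sweeps, the 28-gene × 2-media deletion
screen, and full-model FVA on the ~45-reaction fixture — sizes chosen
so every oracle (vertex enumeration, per-metabolite scans, cobrapy
cross-checks) stays exhaustive and the whole battery completes in
seconds on one CPU.

## Known limitations

No parsimonious FBA, MOMA/ROOM, loopless FVA, or dynamic FBA; no
double-deletion scans; no charge or proton balancing; no SBML
level-3/fbc.  The amino-acid accounting assumes one transport step per
amino acid between `[e]` and `[c]`; multi-compartment shuttles would
need the supply definition revisited.  Growth predictions for a real
organism require its measured exponential-phase uptake rates as medium
bounds — they are inputs, not constants of this package.
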