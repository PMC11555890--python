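# Methods

This note documents the models implemented in `nanosolv`, the defaults and
why they were chosen, what the synthetic structures do and do not emulate,
and the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Post-QM arithmetic

The electronic-structure stage is treated strictly as a data producer. Its
scalar outputs (species total energies, HOMO/LUMO energies, Mulliken
charges, optimized bond lengths, counterpoise corrections) are ingested from
delimited text tables; the package computes only closed-form quantities from
them.

**Binding energy.** `E_b = E(complex) − [E(drug) + E(carrier)] + BSSE`, all
in kcal/mol. Exactly linear in each argument.

**Recovery (desorption) time.** Transition-state theory,
`τ = ν₀⁻¹ exp(|E_b| / (R T))`. Two conventions matter:

- The Boltzmann constant is used on a *molar* energy scale,
  R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, because adsorption energies are tabulated
  per mole. The three-significant-figure value reproduces the reference
  desorption table to its printed precision (e.g. −26.27 kcal/mol at 298 K
  and ν₀ = 10¹² Hz gives 214.4 days); the CODATA 1.9872×10⁻³ value differs
  from those printed numbers by up to 0.5%. The constant is a field of
  `RecoveryParams` and fully overridable.
- The exponent uses |E_b|. A literal reading of the Arrhenius-type formula
  with a *negative* adsorption energy would give τ < 1/ν₀, i.e. binding that
  *accelerates* release, contradicting both physics and the tabulated times;
  the magnitude convention is the one consistent with them. Positive
  (unbound) energies are rejected rather than silently flipped.

τ is strictly increasing in |E_b| and strictly decreasing in T and ν₀, and
the ν₀ ladder scales exactly as 1/ν₀ — both are asserted in tests.

**Frontier orbitals.** `E_g = ε_LUMO − ε_HOMO`; percent changes are taken
against the pristine tube for functionalized tubes and against the
corresponding free carrier for drug complexes. Orbital energies are kept in
their tabulated "printed units" deliberately: every derived quantity is a
difference or a ratio, so no unit conversion is needed (the source tables
are headed eV while the magnitudes are hartree-like; the ambiguity is moot
for gaps and percentages). Donation gaps are
`|ε_HOMO(drug) − ε_LUMO(carrier)|` (forward) and the mirrored backward gap;
the smaller one marks the dominant charge-transfer direction.

Because the ingested orbital energies are printed to four decimals, a gap of
two such numbers carries a ±1×10⁻⁴ rounding envelope and a percent change of
two gaps near 0.08 carries roughly ±0.3 percentage points; comparisons
against published values use exactly these propagation bounds rather than a
tighter, unattainable "printed precision".

## Synthetic structures

**Nanotube.** A zigzag (n,0) tube is generated ring-by-ring: four rings of n
carbons per translational cell (period 3·a_CC), every atom exactly on the
cylinder of radius √3·n·a_CC/(2π). The default a_CC = 1.455 Å makes the
(9,0) radius 3.610 Å. The published geometry triple (180 atoms, 17.08 Å
length, 3.61 Å radius) is internally inconsistent at any single bond length,
so the builder holds atom count and radius exact and reports the realized
length (20.4 Å for 5 cells). Ends are left open and uncapped; pristine-tube
carbons carry zero partial charge (no charges are tabulated for them).

**Functional groups.** OH and COOH are planted on a sidewall carbon along
the outward radial direction with the tabulated optimized bond lengths
(C–O 1.476 / O–H 0.999 for OH; C1–O2 1.377, C1–O6 1.219, O2–H3 0.997 for
COOH; the anchor C–C1 bond uses a standard 1.52 Å single bond). Sites are
labeled C1/O2/H3/O6 to match the Mulliken charge table. A site must be a
pristine interior sidewall carbon (exactly three ring neighbours); repeated
functionalization of the same site is rejected.

**Drug surrogate.** The drug is represented by a deterministic rigid
surrogate — a planar pyridine + benzene scaffold with an amide arm — built
from standard bond geometry in code (it is synthetic, not a
quantum-chemistry output). It reproduces the two features the analysis
actually uses: a carbonyl oxygen tagged `O4` with the tabulated C=O bond of
1.228 Å, and a pyridine nitrogen tagged `N_py`. Tabulated Mulliken charges
are mapped onto the tagged sites and the residual is spread uniformly over
the remaining sites so the molecule carries its formal charge exactly. What
the surrogate does *not* emulate: imatinib's size (~25 vs ~90 atoms),
conformational flexibility, and realistic charge distribution away from the
binding motifs — so absolute solvation energies of the surrogate are not
comparable to the real drug, while the posing, sampling and estimator
machinery exercised by it is identical.

**Complex posing.** Hydrogen-bond poses place the tagged drug site at the
contact distance (default 1.8 Å) from the acidic H3 along the O–H direction;
π-stacking poses on the pristine tube lay the (planar) drug parallel to the
wall at the contact distance. A rigid spin search resolves clashes; any
pose with intermolecular contacts below 1 Å is rejected.

**Water.** Rigid TIP3P: O–H 0.9572 Å, H–O–H 104.52°, q_O = −0.834,
q_H = +0.417, oxygen-only LJ (σ 3.15061 Å, ε 0.1521 kcal/mol). Boxes are
filled with `N = round(ρ V N_A / M)` molecules on a jittered cubic lattice
with uniformly random orientations; the jitter is capped so no two molecules
start closer than 0.5 Å site-to-site. Solvation centers the solute and
deletes waters with any site within the clash cutoff (default 2.6 Å, a
heavy-atom contact just below hydrogen-bond distance).

## Force field and sampling

Only intermolecular terms exist (rigid molecules). Solute–water LJ uses
Lorentz–Berthelot mixing against the water oxygen; solute LJ parameters
default to a bundled generic aromatic-organic set (C 3.40/0.086,
N 3.25/0.17, O 2.96/0.21, H 2.42/0.03; σ in Å, ε in kcal/mol), overridable
per molecule. The Coulomb constant is 332.0636 kcal·Å·mol⁻¹·e⁻² with unit
dielectric — the solvent is explicit.

Electrostatics and LJ are plainly truncated under the minimum-image
convention (no Ewald, no switching, no tail corrections), mirroring the
simulation protocol this package models; this is a documented accuracy
limitation, not an oversight. The cutoff (default 12 Å, clamped to half the
smallest box edge) is *molecule-based between waters* — a pair interacts
with all nine site terms iff the O–O minimum-image distance is inside the
cutoff — which keeps each water's energy well defined under rigid moves.
Solute–water terms are always evaluated: the solutes of interest span a
large fraction of the box, so a reference-site cutoff would be meaningless
for them.

The Metropolis chain moves one randomly chosen water per step: uniform
translation in ±0.13 Å per axis plus rotation by a uniform angle in ±10°
about an isotropically random axis through the oxygen. The solute is fixed.
"Accepted with ~50% probability" is an *observation* about these step sizes
in bulk water, not a modification of the acceptance rule — the engine uses
textbook Metropolis and merely reports the realized ratio (≈0.57 in the
runs the test suite performs). Averages are taken over the post-equilibration
window (default fraction 0.2). Incremental energies are resynchronized
against full recomputations periodically and the worst drift is reported
(tests require < 10⁻⁶ kcal/mol over 10⁴ steps). The RNG is numpy's PCG64,
single stream per run, recorded in the result provenance; identical
configurations reproduce bit-identical trajectories.

**Equilibration moves.** The production step sizes above are far too small
to melt the initial lattice within desk-scale run lengths (a water attempts
~10² moves of ≤0.13 Å in 10⁵ steps). Since *any* rigid-move amplitude
satisfies detailed balance, the equilibration phase may use wider moves; the
hydration study uses 0.75 Å / 45° during equilibration and the standard
moves for all production sampling.

## Free-energy estimation

`ΔG(A→B) = −RT ln⟨exp(−ΔE/RT)⟩_A`, evaluated through a log-sum-exp (no
overflow) with a seeded bootstrap standard error. Solvation free energies
come from alchemical annihilation in solution; for a rigid solute with no
intramolecular terms the gas-phase leg is identically zero, so
`ΔG_sol = −ΔG_soln(A→0)`. A single-step annihilation has no phase-space
overlap, so the path is staged (default 10 + 10 windows): charges scale
linearly to zero first, then LJ is removed through the soft-core form
`U(λ) = 4ελ[(σ⁶/D)² − σ⁶/D]`, `D = ασ⁶(1−λ) + r⁶`, α = 0.5, which stays
finite as the ghost is uncovered. Every window state is sampled by its own
chain; forward ΔE (headline estimate) and backward ΔE (hysteresis
diagnostic) are recorded, and windows whose bootstrap error exceeds a
threshold are flagged rather than silently accepted. Association free
energies are pure cycle arithmetic over the three solvation legs.

The published *absolute* simulation numbers (solute–water energy tables,
ΔG_sol magnitudes) are reported without window counts, sample sizes, or an
energy-scale convention, so they are not desk-reproducible; the estimators
are therefore validated against
independent oracles instead: exactness on constant perturbations, the
Gaussian closed form μ − s²/2RT, zero cost for annihilating a
non-interacting solute, and agreement with a thermodynamic-integration
quadrature on a small LJ-particle toy. The association *cycle* column, which
is pure arithmetic over tabulated legs, is reproduced exactly.

## Cylindrical RDF and the reduced-scale hydration study

`g(r) = ρ(r)/ρ_bulk` with r the perpendicular distance of a water oxygen
from the tube axis, counted inside a slab of height (tube length + 2 Å) and
normalized by exact cylindrical shell volumes; default bins are 0.1 Å wide
(0.25 Å in the reduced study, matching its peak-location resolution).

ρ_bulk defaults to N/V over the whole box. In a reduced box this is a known
*underestimate* of the true far-field density — the tube excludes a
cylinder of roughly π·6.3²·L_tube ≈ 2600 Å³, about 6% of a 35 Å box versus
~2% at the 50 Å production scale — which would inflate the far-field g to
≈1.07–1.09 spuriously. The hydration study therefore normalizes by the
trajectory's own far-region density (bins with r ∈ [12 Å, r_max]), making
g a local/far-field density ratio; with that convention the convergence
check beyond 12 Å is a test of far-field *flatness* at the sampling noise
level, and the pooled multi-seed profile passes it at the 0.1 tolerance.

**Study conditions** (chosen once, stated as the package's defaults): (9,0)
tube of 5 cells, cubic box of 35 Å (top of the reduced-scale 30–35 Å range,
minimizing the excluded-volume bias) at 0.993 g/cm³ and 298 K (~1320 waters
after solvation), 5×10⁵ steps per seed — 2×10⁵ melt-equilibration steps then
3×10⁵ production steps at the standard ±0.13 Å/±10° moves — snapshots every
500 steps, ≥3 seeds pooled by summing raw shell counts (seeds have
independent initial configurations, so pooling reduces both noise and
residual initial-state bias).

**What the study shows and does not show.** The first exterior water shell
sits at 6.875 Å from the axis in every seed — about 3.3 Å above the wall,
which is the Lennard-Jones contact distance for aromatic-carbon/TIP3P-oxygen
mixing (σ_CO ≈ 3.28 Å). The published profile reads the first peak at 6 Å
from the axis, i.e. 2.3–2.4 Å above the wall; that distance lies *inside*
the LJ core of any standard carbon–water parameterization and is therefore
not reproducible by a physical parameter choice within this model class
(their unstated water-position or binning convention presumably differs).
The 14.6% discrepancy is reported as measured, not adjusted. The interior
channel of the tube empties at this reduced scale once the lattice melts;
interior water structure is not a claim of this package.

## Numerical choices and degenerate inputs

- Minimum image uses floor-based wrapping, mapping displacements into
  [−L/2, L/2) exactly at the boundary.
- Overlapping interaction sites (r < 10⁻⁶ Å) raise at full coupling; the
  soft-core path is the only place r → 0 is legal.
- Zwanzig on an empty sample set, or with all exponents infinite ("no
  overlap"), raises rather than returning ±inf.
- PDB round-trips are exact to 5×10⁻⁴ Å (three fixed decimals); XYZ to
  10⁻⁶ Å. The PDB writer is cross-checked against MDAnalysis in the tests.
- Duration formatting picks days from 10 days up, otherwise the largest of
  h/s/ms with a mantissa ≥ 0.1, rounded to one decimal — the convention that
  reproduces the mixed units of the desorption table.

## Known limitations

- Truncated electrostatics (no Ewald) bias absolute energies; acceptable for
  the structural and comparative quantities computed here, documented for
  anything absolute.
- The fixed solute ignores drug-carrier relative motion; the cycle's
  association free energies carry no standard-state or restraint correction.
- The drug surrogate's absolute solvation thermodynamics are not those of
  imatinib (see above).
- Desk-scale FEP runs (10³–10⁴ steps/window) demonstrate correctness of the
  machinery, not converged solvation free energies for 180-atom solutes; the
  window framework scales to production lengths unchanged.
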