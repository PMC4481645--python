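# Methods

`wsilk` re-implements, as a tested library, the quantitative analysis chain
used to characterise the repeat unit (the ~200-residue "W" unit) of
aciniform spider silk spidroin and its concatemers: diffusion NMR and
derived hydrodynamics, coordinate-ensemble structural metrics, chemical
shift and backbone-dynamics mapping, restraint bookkeeping, CD
denaturation analysis, and fibre Raman/tensile analytics. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic-data round trips do and do not demonstrate.

## Diffusion NMR and hydrodynamics (`wsilk.dosy`)

Echo attenuation in a pulsed-field-gradient experiment is modelled as a
single-component Stejskal–Tanner decay

    I(g) = I0 · exp(−(2π γ g δ)² · Dc · (Δ − δ/3 − τ/2)),

with γ = 4257.7 Hz/G (¹H), δ = 8 ms, Δ = 100 ms and g up to 53.5 G/cm at
100% amplitude by default. Because γ is carried in Hz/G, the 2π factor is
explicit; formulations quoting γ in rad·s⁻¹·G⁻¹ absorb it. The
bipolar-gradient correction term τ defaults to 0 (no correction) and is
exposed for acquisition schemes that need it.

Fitting is deterministic: I0 is initialised from the maximum intensity and
Dc from the slope of ln I against the squared-gradient factor, followed by
nonlinear least-squares refinement (lmfit, Levenberg–Marquardt). Curves
with no attenuation raise rather than returning a spurious fit.

Derived quantities use a dioxane internal standard (hydrodynamic diameter
0.424 nm): solvent viscosity comes from Stokes–Einstein applied to the
dioxane Dc; the protein hydrodynamic diameter is
0.424 nm × Dc(dioxane)/Dc(protein), which cancels viscosity and
calibration factors; and the radius of gyration is the Stokes–Einstein
hydrodynamic radius times a shape factor, default √(3/5) (exact for a
uniform solid sphere). The exact empirical Rg(T, η, Dc) correlation used
in some published workflows is not restated here; the shape factor is a
configurable convention, and all downstream code treats Rg as an input, so
the choice is isolated.

## Bead-model hydrodynamics (`wsilk.hydro`)

Ensemble diffusion coefficients use the Kirkwood double-sum approximation

    Dt = kB·T/(6π η) · (1/N²) · [Σᵢ 1/σᵢ + Σ_{i≠j} 1/R_ij],

with one bead per residue at Cα and a uniform effective radius of 3.8 Å by
default (≈ half the Cα–Cα spacing, hydration-inflated; configurable).
Kirkwood neglects rotational coupling and volume corrections, so accuracy
claims are limited to trends and closed-form limits: a single bead
reproduces Stokes–Einstein exactly; two touching beads give 0.75× the
single-bead value; beads spread on a spherical shell of radius R recover
Stokes–Einstein for that sphere (the mean inverse separation of points on
a sphere is exactly 1/R), while a uniformly *filled* sphere tends to the
classic 6/(5R) result, i.e. a ratio of 1.2. No numerical agreement with
shell-model codes (HYDROPRO) is claimed, and overlapping beads are
tolerated (the pair term uses centre distances regardless).

## Structural metrics (`wsilk.metrics`)

Superposition is the Kabsch SVD solution with a proper-rotation
determinant correction; collinear selections are rejected. Ensemble
r.m.s.d. supports two conventions, because published tables mix them:
`pairwise` (mean over all unordered model pairs, the default) and
`to_reference` (each model onto the first, conventionally the
lowest-energy structure). Backbone means N, CA, C, O; heavy means all
non-hydrogen atoms.

Secondary structure follows Kabsch–Sander: H-bond energy
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
E < −0.5, with a 9 Å Cα pre-filter, no bonds between sequence neighbours,
and proline excluded as donor. Missing amide protons are reconstructed
1.01 Å from N along the bisector opposite C(prev) and CA. Helices require
two consecutive i→i+k turns (k = 3, 4, 5); all helix classes are merged
into a single H label because only "% α-helix" is reported downstream, and
3₁₀/π are not separated. Bridges follow the parallel/antiparallel ladder
patterns and merge into E. The output alphabet is {H, E, C}; turns and
bends are out of scope. One test cross-checks the assignment against
mdtraj's DSSP implementation on a synthetic ensemble (agreement, not
identity, is asserted: end-residue conventions differ).

Backbone φ/ψ use the standard four-atom torsions with NaN at termini and
chain breaks. The α-region box defaults to φ ∈ [−100°, −30°],
ψ ∈ [−80°, −5°] — a common literature window, exposed in the API because
no single definition is canonical and the "fraction of residues with
α-helical dihedrals" statistic depends on it (the tolerance used in the
benchmark reflects this).

Solvent accessibility is Shrake–Rupley sphere sampling (deterministic
golden-spiral points, default 960, probe 1.4 Å) over heavy atoms with
standard van der Waals radii; hydrogens are ignored (united-atom).
Per-residue relative exposure divides by extended Gly-X-Gly reference
areas (Tien et al. 2013 theoretical set). With 960 points, per-atom areas
converge to ~3% and per-residue sums to <2% under point doubling. An
isolated residue scores above 1.0 against the tripeptide reference since
nothing occludes it.

## NMR observables (`wsilk.nmr`)

The combined chemical-shift displacement is
CSD = √(Σ(wᵢ·Δδᵢ)²/n) with gyromagnetic-ratio weights w_H = 1,
w_N = 0.102, w_C = 0.251 (configurable for users preferring 0.154/0.2-style
weights). The 1/n inside the root keeps H/N-only titration profiles and
four-nucleus (H, N, CA, CO) modularity comparisons on one scale; this
normalisation is a documented convention, as published variants differ.
Residues missing from either table are flagged absent, never scored zero.
Concatemer units are aligned to the isolated unit by constant residue
offsets; junction-adjacent residues are reported but can be excluded from
summary statistics.

Heteronuclear NOE enhancement factors are peak-height ratios
I(sat)/I(ref); zero-reference residues are excluded with a warning.
Ordered/disordered segmentation thresholds at 0.65 by default (the usual
rigid-core criterion; system-dependent, hence configurable) and absorbs
runs shorter than 3 residues into their neighbours so single-residue dips
do not fragment a domain. The output intervals partition the covered
range.

## Restraint bookkeeping (`wsilk.restraints`)

Distance restraints are categorised by sequence separation: intra
(|i−j| = 0), sequential (1), medium (2–4), long (≥5); ambiguous restraints
(multiple contributing pairs) are counted separately regardless of span.
Published category bounds are sometimes printed inconsistently as literal
set notation ("< 4" next to "> 5"); the 2–4/≥5 convention used here makes
the categories an exact partition, which is the invariant the tests
enforce.

H/D-exchange protection is converted to α-helical H-bond restraints: each
protected amide i inside a helix segment with room for i−4 emits
H(i)···O(i−4) bounds (1.8–2.3 Å) plus N···O bounds (2.8–3.3 Å) — common
practice values, since published bounds vary. Protection outside helices
emits nothing.

Concatemer propagation copies every restraint into each repeat unit with a
constant residue offset (repeat length 200 by default, 199 available for
strict concatemers of the 199-residue construct); no inter-unit restraints
are created, so |i−j| spans — and therefore category counts — scale
exactly with the number of units.

Violation scoring is max(0, d − upper, lower − d) per distance restraint,
with ambiguous restraints evaluated through the r⁻⁶-summed effective
distance, and angular excess beyond the stated tolerance for dihedrals;
statistics are computed per model and reported as ensemble mean ± s.d.,
matching the presentation of published refinement tables. Radius-of-
gyration restraints are serialisable specifications for external annealing
engines plus a score-only harmonic penalty; this package never folds
structures.

## CD denaturation (`wsilk.denaturation`)

Concentration from A₂₁₀ is Beer–Lambert with published ε values
(ε_W1 = 270 858, ε_W2 = 543 596 M⁻¹cm⁻¹) treated as given constants, never
recomputed from sequence. Mean-residue ellipticity is θ/(10·c·l·n) with n
the residue count (pass n−1 for the peptide-bond convention). The
two-state fraction folded F(C) = (θ(C) − θ_D)/(θ_N − θ_D) defaults θ_N to
the C = 0 point and θ_D to the highest-concentration point; values outside
[0, 1] are clamped and flagged, never silently truncated. F is invariant
under affine transforms of the ellipticity scale. Thermodynamic m-value/ΔG
fitting is out of scope. DPC (detergent) titrations are indexed by molar
ratio rather than molarity; the series type carries the axis kind.

## Fibre Raman and mechanics (`wsilk.fibre`)

Spectra are baseline-corrected with a cubic fitted to user-declared anchor
windows, then 5-point moving-average smoothed (window shrinking at the
ends). The orientation-insensitive spectrum is a weighted combination of
the symmetry-distinct polarized components (ZZ, XX, and the XZ/ZX
average — XZ and ZX are equivalent under fibre symmetry and averaged
first). The default weights (0.2, 0.4, 0.4) are an explicit, configurable
placeholder: the correct coefficients depend on the instrument geometry
and should be taken from the relevant polarized-Raman literature for
faithful reproduction. The synthetic generator imposes orientation such
that the *configured* weights invert it exactly, so round-trip tests are
weight-independent.

Amide I decomposition (1600–1700 cm⁻¹) fits a band table — default centers
1640/1685 (disorder), 1655 (α-helix), 1670 (β-sheet), Gaussian, σ 12 cm⁻¹,
centers bounded ±5 cm⁻¹ — and reports relative component areas as
percentages summing to 100. With floating centers and widths this default
table is only weakly identifiable: neighbouring components trade area at
near-zero residual cost, so recovered fractions are trustworthy only for
resolvable band configurations. When the band table is trusted,
amplitude-only fitting (`vary_centers=False, vary_widths=False`) is well
posed and recovers generated fractions to better than 1 point.

Tensile metrics assume the curve is truncated at failure (the breaking
point is the last sample; no failure-detection heuristics): breaking
strength is the maximum stress, toughness the trapezoidal ∫σ dε
(MPa·strain ≡ J·cm⁻³), and Young's modulus the least-squares slope over an
initial strain window (default [0, 0.02]). Fibre cross-sections are
circular by assumption, with the diameter averaged over the nine-estimate
protocol (three micrograph positions × three measurements).

## Synthetic data (`wsilk.synthetic`)

Every generator is a deterministic function of its seed. Defaults encode
the study system:

- **Sequence**: 199 residues, Gly+Ala+Ser fraction ~0.50, Phe at positions
  90 and 95, ten aromatics in total, and exactly 8 prolines with 6 confined
  to the 172–191 linker stretch. Constraint violations raise rather than
  silently degrade.
- **Ensembles**: backbone-only (N, CA, C, O) chains built by NeRF
  extension at ideal geometry. Helical segments (defaults: 12–39, 61–86,
  89–110, 113–132, 135–149 — only helix 5's bounds are experimentally
  pinned; the rest are illustrative) use φ = −57°, ψ = −47°. Non-helical
  core residues (the structured 40–60 stretch and short inter-helix turns)
  draw coil dihedrals once per ensemble, so the 12–149 core superposes
  across models; tail/linker residues are resampled per model as a simple
  self-avoiding walk (Cα–Cα ≥ 3.8 Å, bounded retries). Coil sampling uses
  β/ppII/left-handed-turn basins and never draws the turn basin twice in a
  row, so disordered segments cannot accumulate helical H-bond ladders.
  This is sufficient for hydrodynamic and r.m.s.d. contrast between core
  and tails; it is not a physical ensemble, carries no side chains, and
  its absolute Rg/Dc values should not be compared to experiment.
- **DOSY decays**: 16 gradient steps from 2% to 95% with Gaussian noise
  (default σ = 1% of I0) around a true Dc of 1.1×10⁻⁶ cm²/s (a ~19 kDa
  globular protein in water at 303 K).
- **Shift tables**: an isolated-unit table plus two concatemer-unit tables
  identical up to 0.002 ppm noise except for a 0.25 ppm perturbation on
  the 3 residues adjacent to the inter-unit link, emulating
  junction-localised perturbation.
- **hetNOE**: plateau 0.80 over residues 12–149, tails declining to −0.2,
  placed so the default profile segments into disordered [1, 11] and
  [150, 199] with ≥5σ margin to the 0.65 cutoff at default noise.
- **Titrations**: logistic two-state F(C) with midpoint 1.5 M and
  m = 8 kJ/mol/M between configurable native/denatured ellipticities.
- **Raman**: amide I synthesised from target fractions (default the
  fibre-like 32/28/40 α/β/disorder split), uniaxial orientation imposed as
  ZZ×(1+o), XX×(1−o) with the cross term solving the iso-weight
  constraint, plus optional cubic baseline and noise.
- **Stress–strain**: linear-elastic then linear-plastic to a configured
  breaking strain.
- **Restraints from an ensemble**: Cα–Cα contacts present in every model
  (upper bound = largest observed distance + 0.5 Å) plus φ/ψ restraints on
  helical residues at their circular-mean values — trivially satisfied by
  the source ensemble, which is the property the violation scorer is
  tested against.

Passing round trips demonstrate internal consistency of each
generator/analysis pair under the stated statistical structure; they do
not validate the analyses against real spectrometer output, peak-picking
errors, chemical-shift referencing problems, or fibre heterogeneity, none
of which the generators emulate.

## Problem sizes and benchmarks

Default test problem sizes are chosen for rapid, deterministic runs: 4–10
model ensembles of one or two 199-residue units, 200-replicate Monte-Carlo
checks of the DOSY fit, and 300-point spectra. The deposited 20-model
W-unit ensemble (PDB 2MU3) is the external benchmark for superposition,
secondary-structure and dihedral statistics; it is not redistributed with
the package, and the benchmark (`wsilk.benchmark`) runs on a locally
downloaded copy.

## Known limitations

- Structure calculation (simulated annealing, water refinement) is out of
  scope; restraints are generated, propagated and scored only.
- The Kirkwood bead model is a trend-level substitute for shell-model
  hydrodynamics.
- The {H, E, C} assignment omits turns/bends and merges helix classes.
- Amide I component fractions are identifiable only for resolvable band
  tables (see above).
- The orientation-insensitive-spectrum weights are placeholders pending
  instrument-specific coefficients.
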