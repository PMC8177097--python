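# Methods

## Binding model and its assumptions

All fitting assumes a single binding site with 1:1 stoichiometry at
equilibrium. The complex concentration follows the Morrison quadratic (the
depletion-corrected isotherm); activity coefficients are taken as unity and
incubation is assumed long enough that equilibrium holds at every titration
point. Binding kinetics, cooperative or multi-site models, and
time-dependent effects (ligand photodegradation, slow equilibration) are out
of scope.

The textbook smaller-root expression for [PL] subtracts two nearly equal
numbers when K_d ≫ L₀, P₀; we evaluate the algebraically identical form
2L₀P₀/(s + √(s² − 4L₀P₀)) instead, which is accurate across the whole
regime (verified against a bisection mass-action solver to 1e-8 relative
over a grid spanning four orders of magnitude in each of L₀, P₀, K_d).

### Absorbance observable (Soret band, 411 nm)

A₄₁₁ = [PL]·ε_PL + (L₀ − [PL])·ε_L(c). Free hemin aggregates in aqueous
buffer, so ε_L depends on concentration; we realize the free term as
A_free(c), the calibrated absorbance law evaluated at concentration c, so
(L₀ − [PL])·ε_L(c) ≡ A_free(c). The concentration at which the law is
evaluated is a genuine ambiguity: the default is the equilibrium *free*
concentration L₀ − [PL] (self-consistent with the equilibrium model), with
`free_eval="initial"` evaluating ε_L at L₀ instead. Both are supported
because a reference-read protocol (ligand-in-buffer measured alongside
ligand-plus-protein) corresponds more closely to the "initial" convention.

### Fluorescence observable (354 nm emission, 290 nm excitation)

I₃₅₄ = [PL]·I_PL + (P₀ − [PL])·I_P. Inner-filter effects are deliberately
ignored, matching the observable model above; at the 10 nM protein and
≤50 nM ligand concentrations of the quenching assay the absorbance of the
sample is negligible, but this is an assumption, not a correction. I_P is
fixed from the zero-ligand baseline by default (it is directly observed
there); passing `i_protein` overrides this.

### Extinction calibration

The free-ligand law is a least-squares polynomial with the constant term
fixed at zero (Beer–Lambert demands A_free(0) = 0 after blank subtraction).
Hemin uses degree 2 by default — the minimal curvature model for
aggregation — and hematoporphyrin uses a line; the degree is configurable.
Evaluation outside the calibrated concentration range extrapolates but
records a warning in the model diagnostics. The fit requires at least
degree + 1 distinct concentrations and fails loudly on rank deficiency.

### Optimization

K_d and the complex coefficient are fitted jointly by
`scipy.optimize.least_squares` (Levenberg–Marquardt) on θ = [log K_d,
coefficient]; the log parameterization enforces positivity without
constraints. Three starts span the schedule (0.1·L_min, √(L_min·L_max),
10·L_max); at each start the coefficient is initialized by its closed-form
linear solution at that K_d. Ties are broken by lowest residual sum of
squares, then lowest K_d. Function tolerance 1e-10, at most 10⁴
evaluations. A fit never silently fails: non-convergence is flagged on the
result, identically-zero observables and schedules with fewer than three
distinct concentrations raise.

When P₀/K̂_d exceeds 10 the fluorescence fit warns: in the tight-binding
regime the isotherm approaches the stoichiometric limit and the data
constrain K_d only weakly (the likelihood is nearly flat in K_d), so
estimates are noisy and downward-variance-prone. The warning is emitted for
the sub-nanomolar HP affinity at 10 nM protein (ratio ≈ 70).

### Uncertainty

Two estimators are provided, and neither is privileged: `replicate_sd`
refits each replicate independently and reports the sample SD of the
per-replicate K_d estimates (requires ≥ 2 replicates); `residual_bootstrap`
resamples fitted residuals with replacement, refits (single-start from the
solution), and reports the SD and the 2.5/97.5 percentile interval over B
resamples (default 200, seeded). On seeded simulations at the hemin
schedule the bootstrap SD agrees with the delta-method (linearized) standard
error to within ~15%, and the nominal-95% interval covers the truth at
80–99% over 100 simulations — adequate but slightly imperfect calibration,
as expected for a nonlinear model with n = 36.

## Synthetic data generator

The generator emulates the two assay geometries: a hemin absorbance
titration (5 μM protein; 0.5–11 μM ligand in 12 uniform steps; triplicate;
additive Gaussian noise, default σ = 0.003 AU) and an HP quenching
titration (10 nM protein; a zero-ligand baseline plus 0.8–50 nM in 12
log-spaced steps; complex emission 20% of free protein; 1% relative noise
plus additive noise at 1% of the unquenched baseline). Noiseless outputs
satisfy the forward models exactly (machine precision), and a fixed seed
makes the CSV output byte-identical across runs.

Coefficient values are stand-ins chosen to be physically plausible, not
measured values: ε_PL = 0.1 AU·μM⁻¹ (i.e. ~10⁵ M⁻¹cm⁻¹, a typical
protein-bound Soret extinction at 1 cm path), free-hemin law
0.05c − 0.001c² AU over the 0–11 μM window, I_P = 1000 counts·nM⁻¹.
Absorbance/emission coefficients are treated as molar (per-concentration)
coefficients with a 1 cm path throughout, keeping the observable equations
dimensionally consistent. Noise is homoscedastic Gaussian — the simplest
model consistent with spectrophotometer readout — and the 12-point
schedules with three replicates reflect a realistic bench titration rather
than an idealized dense design.

The free-hemin nonlinearity can alternatively be generated from an explicit
monomer–dimer equilibrium (2M ⇌ D, dissociation constant 20 μM, dimer
absorbing less per heme), in which case the downstream polynomial
calibration is a genuine approximation rather than a self-fulfilling one.

What the generator does *not* emulate: wavelength-resolved spectra beyond
single-readout values, photobleaching/photodegradation, incubation-time
effects, inner-filter attenuation, pipetting (x-axis) error, and
heteroscedastic detector noise. Passing recovery tests therefore shows the
estimator is correct and well-behaved under the stated noise model, not
that real titrations are free of these systematics.

## Mass identification

Monoisotopic masses use an embedded IUPAC 2021 isotope table (H, C, N, O,
Na, Mg, P, S, Cl, K, Fe, Zn); nothing is fetched at run time. Ion m/z adds
bare protons (m_p = 1.007276466621 Da) and removes electrons for any
remaining charge — [M]⁺ = M − m_e, [M+H]⁺ = M + m_p. The electron term
(0.000549 Da, ~0.9 ppm at m/z 616) is what reconciles the ferric heme
cation C₃₄H₃₂FeN₄O₄⁺ (616.1767) with observed precursors near 616.177 at
~1 ppm. Because ferric heme ionizes as the intact cation, a precursor
annotated "[M+H]⁺" at this mass is numerically indistinguishable from
[M]⁺ of the neutral formula; both hypotheses are computed and reported with
their ppm errors rather than deciding between them.

Isotopologue envelopes are computed by exponentiation-by-squaring
convolution of per-element distributions, aggregated in 1 Da (nominal-mass)
bins — the resolution at which Orbitrap precursor envelopes are compared
visually — with each bin's m/z the abundance-weighted mean of its
isotopologues. Terms below 1e-12 probability are pruned. The envelope is
checked against brute-force enumeration with multinomial weights for the
full heme formula, including the ⁵⁴Fe A−2 satellite (~6% of base peak).

## Structure analysis

Parsing (PDB/mmCIF) is delegated to gemmi; the first model is used and
alternate locations resolve to the highest-occupancy conformer. Coordinates
stay in Å on the depositor's residue numbering.

* **Contact shell**: a residue is in contact when any of its heavy atoms is
  within the cutoff (default 4.0 Å) of any ligand heavy atom; hydrogens are
  excluded on both sides. Amino acids form the census; waters and other
  non-protein entities are listed separately, since pocket censuses
  conventionally exclude them.
* **Hydrogen bonds**: crystallographic models at ~2 Å carry no hydrogens,
  so detection is geometric inference, not the depositor's criterion:
  donor–acceptor heavy-atom distance ≤ 3.5 Å plus a
  donor–acceptor–antecedent angle ≥ 90° wherever a covalent antecedent can
  be identified (nearest heavy atom within 1.8 Å in the same residue).
  Ligand N/O/S atoms are treated as both potential donors and acceptors
  because protonation is unresolved.
* **π-stacking**: protein aromatic rings (Phe, Tyr, His, both Trp rings)
  versus the four pyrrole rings; reported when ring-centroid distance
  ≤ 5.5 Å and interplanar angle ≤ 30° (parallel and parallel-displaced
  geometries; T-shaped contacts excluded by design). Pyrrole rings are
  defined by the chemical-component heme atom names NA–ND and reported with
  Fischer numerals (A→I, B→II, C→III, D→IV). Rings with missing atoms are
  skipped with a warning.
* **Superposition**: Kabsch SVD with the reflection-excluding determinant
  correction; collinear point sets and < 3 pairs are rejected. Pairing is
  by (residue number, insertion code) across the selected chains by
  default, or by global sequence alignment.
* **Heme-plane rotation**: after Cα superposition of the proteins, a
  best-fit plane (SVD) is put through each 24-atom porphyrin core (4 N +
  16 pyrrole C + 4 meso C); the reported angle is the unsigned in-plane
  rotation between the Fe→NA reference vectors projected into the first
  structure's plane. The plane normal is oriented by the NA/NB ring sense,
  so a mirrored porphyrin reports a 180° normal tilt (reported separately)
  instead of an undefined value. For iron-free porphyrins the core centroid
  replaces Fe as the vector origin.

Structure stages never access the network; coordinate files are supplied
locally by the user.

## Numerical and interface conventions

Titration CSVs use the header
`replicate,ligand_conc,conc_unit,observable,observable_kind` with
`observable_kind` ∈ {A411, I354}; calibration CSVs use
`ligand,conc,conc_unit,absorbance,wavelength_nm`. Concentration units are
carried as metadata and never converted implicitly — fits are
unit-invariant under consistent rescaling. All pipeline randomness flows
from a single integer seed through `numpy.random.default_rng` /
`SeedSequence`, and every CLI report embeds the package version, seed, and
a SHA-256 of the resolved configuration, so identical (config, seed) pairs
produce byte-identical outputs.

Soret peak localization refines the discrete argmax by a three-point
quadratic; a window in which the trace is monotone returns "no peak" rather
than an endpoint. Differential spectra require exactly matching wavelength
grids — no silent interpolation.

## Known limitations

* The recovery experiments quantify estimator behaviour under the
  generator's noise model only; systematic errors of real titrations
  (baseline drift, scattering, pipetting error) are not represented.
* In the tight-binding regime (P₀/K_d ≫ 10) the K_d estimate from a single
  titration is intrinsically imprecise; the package warns but cannot
  manufacture identifiability — lowering the protein concentration is the
  experimental remedy.
* Hydrogen-bond and stacking calls are geometric heuristics on hydrogen-free
  models; borderline geometries near the thresholds should be inspected.
* The isotopologue envelope is binned at nominal-mass resolution and does
  not model resolution-dependent peak shapes or fine structure within a bin.
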