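# porphyfit

Quantitative analysis of porphyrin binding to proteins, built around the
characterization of the *Escherichia coli* lipocalin Blc as a heme-binding
protein: depletion-corrected equilibrium binding fits (K_d) from
spectrophotometric and tryptophan-fluorescence titrations, free-ligand
extinction calibration, exact-mass identification of heme B with
isotopologue envelopes, and binding-pocket structural analysis
(contact shell, hydrogen bonds, π-stacking, Cα superposition, heme-plane
rotation). A synthetic-data generator with known ground truth makes every
stage testable end to end without any downloads.

It is intended for protein biochemists and structural biologists who titrate
chromophoric ligands (hemes, porphyrins) into proteins at concentrations
where the free-ligand approximation breaks down, and who want the fitting,
mass identification and pocket analysis in one scriptable, reproducible
toolchain.

## The model

For 1:1 binding P + L ⇌ PL with dissociation constant K_d, when K_d is
comparable to the reactant concentrations both species are depleted and the
equilibrium complex concentration is the smaller root of the Morrison
quadratic,

    [PL] = ( (L₀ + P₀ + K_d) − √((L₀ + P₀ + K_d)² − 4 L₀ P₀) ) / 2,

with L₀, P₀ the total ligand and protein concentrations (implemented in the
cancellation-free form 2L₀P₀ / (s + √(s² − 4L₀P₀)), s = L₀+P₀+K_d, which
stays accurate when K_d ≫ L₀, P₀). Two observables are modelled on top:

* **Absorbance at the 411 nm Soret band**
  A₄₁₁ = [PL]·ε_PL + A_free(L₀ − [PL]), where A_free(c) is the calibrated
  free-ligand absorbance law — a zero-intercept polynomial for hemin (which
  aggregates, so its extinction coefficient is concentration dependent) or a
  line for hematoporphyrin (HP).
* **Tryptophan emission at 354 nm** (290 nm excitation), quenched on binding:
  I₃₅₄ = [PL]·I_PL + (P₀ − [PL])·I_P, with I_P fixed from the zero-ligand
  baseline by default.

K_d and the complex coefficient are fitted jointly by nonlinear least
squares on log K_d (positivity by construction), multi-started from initial
K_d values spanning the titration schedule. Uncertainty comes from
per-replicate refits (`replicate_sd`) or a seeded residual bootstrap.

The mass module computes monoisotopic masses from an embedded IUPAC isotope
table, ion m/z with explicit proton/electron bookkeeping (the ~0.00055 Da
electron term matters at 1 ppm), ppm matching, and nominal-mass isotopologue
envelopes by per-element convolution — including the ⁵⁴Fe A−2 satellite
diagnostic for iron.

## Worked example

Simulate a triplicate hemin titration (5 μM protein, 0.5–11 μM hemin,
σ = 0.003 AU) at a true K_d of 1.4 μM, calibrate the free-hemin law, and
refit:

```sh
$ porphyfit run --seed 11 --out-dir run1
Kd = 1.424 uM (true 1.4), converged=True
```

The report (`run1/report.json`) contains the fitted K_d 1.424 μM with a
replicate SD of 0.26 μM and a complex extinction coefficient of
0.1001 AU·μM⁻¹ (the generator's truth is 0.1): the fit recovers the ground
truth well within its own uncertainty, which is the expected precision of a
12-point triplicate titration at this noise level.

Identify the copurifying small molecule from its observed precursor m/z:

```sh
$ porphyfit mass-id --observed 616.1774
[M]+ matches at +1.07 ppm
```

i.e. the intact ferric heme B cation (C₃₄H₃₂FeN₄O₄⁺, theoretical m/z
616.1767) explains the observed ion to about 1 ppm. The report also lists
the [M+H]⁺ hypothesis and the predicted isotopologue envelope.

Structural stages operate on local coordinate files (nothing is fetched at
run time), e.g.:

```sh
porphyfit contacts --structure 6vri.cif --ligand "E:HEM:201" --cutoff 4.0
porphyfit superpose --reference 6vri.cif --mobile 3mbt.pdb --ref-chains E,F --mob-chains A
```

All stages are also plain library functions (`porphyfit.fit_kd_absorbance`,
`porphyfit.contact_residues`, …); see `docs/methods.md` for the modelling
details and design choices.

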