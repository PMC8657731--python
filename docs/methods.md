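# Methods

This note documents the models, numerical choices and limitations of
tirekit, in the order data flow through the pipeline.

## Optical model

The sensor is modelled as a stratified planar multilayer: a semi-infinite
BK7 prism (incidence medium), a Cr adhesion film, the Au plasmonic film,
the biolayer, and semi-infinite aqueous buffer. A monochromatic plane wave
hits the stack at a fixed planar angle measured in the prism (default 68°;
prism-face refraction and beam walk are not modelled). For each
polarization the complex reflection coefficient is computed with the
characteristic-matrix (Abelès) method; the ellipsometric angles follow from
tan Ψ = |r_p/r_s| and Δ = arg r_p − arg r_s, with Δ wrapped to [0°, 360°).

*Conventions.* Complex indices are n − i·k (k ≥ 0) with time factor
e^{−iωt}. Internally the matrix product is assembled in the conjugate
pairing — where the natural square-root branch Im(k_z) ≤ 0 gives decaying
evanescent fields — and r_p, r_s are conjugated on output. This is an exact
transform, not an approximation; it leaves |r| and Ψ untouched and fixes
the sign of Δ so that Δ falls sharply through the plasmon resonance, as
TIRE instruments record. Passivity (|r| ≤ 1 for all-passive stacks) and
unitarity of lossless total internal reflection are enforced by tests, and
the whole matrix code is cross-checked against an independently coded
Parratt-style recursion to ~1e−14 on random stacks.

*Degenerate inputs.* Layers thinner than 1e−6 nm are dropped before matrix
assembly, so a zero-thickness layer is exactly a no-op. A zero refractive
index or a non-finite intermediate raises a numeric-domain error naming the
offending layer.

*Resonance location.* The SPR wavelength is the interior minimum of Ψ,
refined by a parabola through the three surrounding grid points; a minimum
on the grid edge raises a no-resonance error rather than returning an
extrapolation.

## Material data

- **BK7**: standard three-term Sellmeier coefficients.
- **Buffer**: water, two-term Cauchy (A = 1.3230, B = 0.00322 µm²).
- **Au**: packaged n,k table (400–1000 nm, 5 nm step, linearly
  interpolated) computed from the Drude + two-critical-point analytic model
  of Etchegoin, Le Ru & Meyer (2006; 2007 erratum), which closely tracks
  the Johnson & Christy measurements in this range.
- **Cr**: packaged table from the Rakić et al. (1998) Lorentz–Drude
  parameterization.

Tables carry provenance headers and can be regenerated with
`scripts/build_material_tables.py`; any CSV in the same
`wavelength_nm,n,k` format can be swapped in through the stack
configuration. Tabulated models refuse queries outside their wavelength
range — metal optical constants are not safely extrapolable.

A consequence of using literature gold constants with the thin films of
this sensor (Au 20–25 nm, well below the ~45 nm SPR optimum) is that the Ψ
minimum is broad and displaced to the red of the phase feature: for the
default Cr 4 / Au 23 nm stack the Ψ minimum sits at 862 nm while the sharp
Δ descent (the plasmon proper) is near 680 nm. Both move red with biolayer
thickness, which is the signal the analysis uses. The Δ slope reaches
~0.75°/nm at the phase swing; Ψ stays below 0.15°/nm everywhere on the
default grid.

## Biolayer dispersion and thickness fitting

The biolayer index is held fixed at the Cauchy model
n(λ) = 1.4 + 0.01/λ² (λ in µm, k = 0), i.e. n ≈ 1.42 at 700 nm — a typical
value for proteins and polynucleotides. Freezing the index resolves the
classic thickness/index trade-off of single-angle ellipsometry exactly:
only thickness floats.

The objective is χ² = Σ_λ [(Ψ_m−Ψ_c)/σ_Ψ]² + [circ(Δ_m−Δ_c)/σ_Δ]², with
circ the minimal circular difference (the 0/360 wrap point is irrelevant)
and default weights σ_Ψ = 0.1°, σ_Δ = 0.5° (Δ is noisier near resonance;
both user-overridable). Both channels are fitted jointly.

Optimization is deterministic by construction: an exhaustive 0.25 nm grid
over the bounds (ties broken toward the smallest thickness), then bounded
Powell refinement from the best grid point. No randomness enters, so
identical inputs give byte-identical results. Standard errors come from
the finite-difference curvature of χ² at the optimum (cov = 2H⁻¹) and are
approximate. A flat grid objective or an optimum on a bound flags the
result non-identifiable; metal calibration additionally warns, since a
bare spectrum without a plasmonic minimum cannot constrain the metals.

Metal calibration fits Cr ∈ [1, 8] nm and Au ∈ [15, 35] nm from a bare
(pre-functionalization) spectrum; the fitted values are then held fixed
for every biolayer fit of that sample. Titration series require a
concentration-0 baseline and report thickness changes relative to it.

## Binding isotherm

Equilibrium biolayer thickness vs analyte concentration C:

    d(C) = d₀ − Δ_wrap · C/(C + K_D)
              + d_ns,max · max(0, C − C_on) / (K_ns + max(0, C − C_on))

The first term is Langmuir occupancy scaled by the maximal specific
compaction Δ_wrap (receptors wrap around the captured target). The second
is a saturating non-specific overlayer that switches on at C_on, once the
specific sites are essentially full; a saturating form was chosen over a
linear one because an unbounded overlayer has no physical ceiling.
Defaults: d₀ = 7.5 nm, Δ_wrap = 2.0 nm, K_D = 2.58 nM, d_ns,max = 3.5 nm,
C_on = 10 nM, K_ns = 50 nM. d₀ and K_D mirror the emulated experiment;
the remaining values are generator choices picked so the titration shows a
clear compaction (blue shift) at low C and pile-up (red shift past the
baseline) at 100 nM. `saturation_concentration` inverts the specific term:
C(f) = K_D · f/(1−f), so f = 0.5 gives K_D by definition.

The qualitative observation that sparser receptor layers saturate earlier
is exposed only as alternative parameter sets (smaller effective K_D), not
as a fitted relationship — there is no quantitative receptor-density model
to calibrate against.

## Kinetics

Monolayer binding from an empty surface has the closed form
θ(t) = θ_eq (1 − e^{−t/τ}) with θ_eq = C/(C + K_D) and τ = 1/(k_a C + k_d);
after 3τ occupancy is within 1 − e⁻³ ≈ 95% of equilibrium, which is the
usual stopping rule for incubation.

Sensorgrams are fitted as Ψ(t) = baseline + A·e^{−t/τ} (three free
parameters; the baseline floats because real instruments drift). Initial
guesses come from a log-linearized regression with the baseline pinned just
below the trace minimum; refinement is unweighted least squares on the raw
samples, and the τ standard error comes from the fit curvature. A decay is
accepted only if the drop between the first and last segment means exceeds
three times its own noise estimate; flat or rising traces raise a fit
failure with a diagnostic.

Biphasic traces (specific decay followed by a non-specific rise at high
concentration) are segmented before fitting: the trace is smoothed with a
5-sample centred moving average, and if the global minimum falls before 80%
of the record and the net rise after it exceeds 3× the residual RMS, τ is
fitted on the pre-minimum window only. Smoothing is used for segmentation
only — never for the fit itself. The thresholds are configurable.

Affinity comes from unweighted ordinary least squares of 1/τ on C (a
variance-weighted option exists but is off by default, matching the plain
linear fit practitioners use): slope → k_a, intercept → k_d,
K_D = k_d/k_a, with the K_D standard error by first-order propagation using
the full slope/intercept covariance. A non-positive slope or intercept
flags the result non-identifiable instead of clamping, because clamping
would silently bias K_D.

## Synthetic data generator

The generator emulates one complete sensing experiment: the default stack
(BK7 / Cr 4 / Au 23 / aptamer 7.5 nm / buffer at 68°, 450–1000 nm grid at
2 nm), analyte concentrations 0.09, 0.5, 10 and 100 nM plus a C = 0
baseline, kinetics at 700 nm with k_a = 10⁶ M⁻¹s⁻¹ and
k_d = 2.58×10⁻³ s⁻¹ (K_D = 2.58 nM), 1 s sampling.

Titration spectra push the isotherm thickness through the full optical
model and add independent Gaussian noise (defaults σ_Ψ = 0.1°,
σ_Δ = 0.5°). Sensorgrams drive the thickness with θ(t) and evaluate Ψ at
700 nm through the full optical model rather than a linear Ψ–d shortcut,
so the exponential fit is exercised against the real (mildly nonlinear)
optical response; the residual bias on τ is below 2%. Trace duration is 5τ
with a 120 s floor; above C_on a slower overlayer ramp (time constant 5τ)
starts at 95% specific completion and the record is extended to resolve
the decay-then-rise shape. Trace noise is σ = 0.02° by default, or a
specified fraction of each trace's noise-free amplitude. All randomness
derives from a single seed via independent named streams; identical
configurations give byte-identical CSV files.

What the generator does **not** emulate: instrument drift, correlated or
wavelength-dependent noise, outliers, mass-transport limitation, bivalent
binding, depolarization, and angular spread of the real prism coupling.
Passing tests therefore demonstrate the correctness and stability of the
analysis chain under the stated noise model, not robustness to every
artifact of real instruments.

## File formats and reproducibility

Spectra: `#`-prefixed `key = value` metadata lines, then exactly
`wavelength_nm,psi_deg,delta_deg` and numeric rows. Traces: same style with
`time_s,psi_deg` and a required `concentration_M` metadata key.
Concentrations are S.I. molar in every file; nanomolar appears only in
logs. Values are written with 9 significant digits, so write→read→write
round trips are byte-identical. Stack and generator configurations are
YAML; validation errors name the file, field and reason.

`run_pipeline` writes `thickness.csv`, `affinity.csv` and a `manifest.json`
recording package version, input checksums, seed and timestamps; with the
same inputs the result files are regenerated byte-identically (the
manifest's timestamps are the only fields that differ between reruns).

## Problem sizes used in the test suite

Optimization-heavy tests run on a 5 nm wavelength grid (111 points) rather
than the 2 nm default — the physics is identical and fits agree to well
under the noise level. Monte-Carlo checks use 10–20 seeds for thickness
and affinity recovery and 200 replicates for the τ-noise regression study;
these sizes give stable medians for the stated tolerances.

## Known limitations

- Single fixed incidence angle; no angle scans, no anisotropic or
  graded-index layers, no Mueller/depolarization formalism.
- The Ψ-minimum and Δ-swing decoupling at thin gold (above) means
  resonance-wavelength shifts are smaller per nm of adlayer than they
  would be at optimal gold thickness; the fitting uses full spectra, not
  just the minimum, so sensitivity is not lost.
- Dispersion-model coefficients are never fitted; only thicknesses float.
- No mass-concentration conversion is performed anywhere: literature mass
  equivalences for nucleic-acid fragments are error-prone, and the
  pipeline works in molar units throughout.
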