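# tirekit

Analysis pipeline for **total internal reflection ellipsometry (TIRE)
aptasensors** — label-free optical biosensors in which receptor
oligonucleotides (aptamers) immobilized on a thin gold film capture an RNA
analyte, and the binding is read out through shifts of the
surface-plasmon-resonance feature in ellipsometric Ψ/Δ spectra.

The package was built around a prostate-cancer use case — an RNA aptamer
against the PCA3 transcript on a BK7-prism / Cr / Au / aptamer / buffer
stack at 68° incidence — but every component is generic multilayer optics
and Langmuir kinetics.

## What it computes

**Forward optics.** The stack's complex reflection coefficients r_p, r_s are
computed by the characteristic-matrix (Abelès) method, giving the
ellipsometric angles

    tan Ψ = |r_p| / |r_s|,        Δ = arg(r_p) − arg(r_s).

Beyond the prism/buffer critical angle the Ψ spectrum shows an SPR minimum
whose position red-shifts as the biolayer thickens.

**Inverse fitting.** Layer thicknesses are recovered by weighted
least squares on Ψ and Δ jointly,

    χ² = Σ_λ [(Ψ_m − Ψ_c)/σ_Ψ]² + [circ(Δ_m − Δ_c)/σ_Δ]²,

with the biolayer refractive index held at the fixed Cauchy dispersion
n(λ) = 1.4 + 0.01/λ² (λ in µm; n ≈ 1.42 at 700 nm, typical of proteins and
polynucleotides), so only thickness floats. Metal thicknesses are
calibrated once from a bare spectrum, then frozen.

**Binding kinetics.** Binding to a monolayer of independent sites obeys
dθ/dt = k_a C (1−θ) − k_d θ, so the sensorgram (Ψ at 700 nm vs time) decays
exponentially with relaxation time τ = 1/(k_a C + k_d). Fitting τ at each
analyte concentration and regressing 1/τ on C gives the association rate
k_a (slope), dissociation rate k_d (intercept) and affinity constant
K_D = k_d/k_a. Traces with a late non-specific rise are segmented first so
τ is fitted on the specific phase only.

**Binding isotherm.** Equilibrium biolayer thickness vs concentration:
specific capture compacts the layer (the aptamers wrap around the target)
following C/(C+K_D); above an onset concentration, non-specific pile-up on
the saturated layer thickens it again — reproducing the blue-then-red
spectral shift observed in titrations.

**Synthetic data.** No raw instrument data are bundled; `tirekit.synthetic`
emulates the experiment end to end (titration spectra and 700 nm
sensorgrams with Gaussian noise, seeded and byte-reproducible), so the
whole chain is testable.

## Worked example

```python
from tirekit import default_stack, forward_tire, resonance_wavelength
from tirekit.synthetic import GeneratorConfig, NoiseSpec, generate_trace
from tirekit.kinetics import fit_exponential, estimate_affinity

stack = default_stack()                      # BK7 / Cr 4 nm / Au 23 nm / aptamer 7.5 nm / buffer
print(f"resonance (d = 7.5 nm): {resonance_wavelength(forward_tire(stack)):.1f} nm")

config = GeneratorConfig(noise=NoiseSpec(seed=1))
fits = [(c, fit_exponential(generate_trace(config, c))) for c in config.concentrations_m]
for c, f in fits:
    print(f"C = {c*1e9:6.2f} nM   tau = {f.tau_s:7.1f} s")
aff = estimate_affinity(fits)
print(f"ka = {aff.ka:.3g} 1/(M s),  kd = {aff.kd:.3g} 1/s")
print(f"KD = {aff.KD*1e9:.2f} nM  (R^2 = {aff.r_squared:.5f})")
```

prints

```
resonance (d = 7.5 nm): 862.4 nm
C =   0.09 nM   tau =   403.9 s
C =   0.50 nM   tau =   319.2 s
C =  10.00 nM   tau =    80.6 s
C = 100.00 nM   tau =     9.8 s
ka = 9.94e+05 1/(M s),  kd = 0.0025 1/s
KD = 2.51 nM  (R^2 = 1.00000)
```

The resonance sits at 862 nm for the default stack; τ falls from ~400 s at
90 pM to ~10 s at 100 nM because the relaxation rate 1/τ = k_a C + k_d
grows with concentration; and the regression recovers the generating
affinity (k_a = 10⁶ M⁻¹s⁻¹, k_d = 2.58×10⁻³ s⁻¹, K_D = 2.58 nM) to within
the noise of a single synthetic run.

## Command line

```
tirekit generate all --outdir data/ --seed 0     # synthetic experiment
tirekit calibrate --bare data/bare.csv           # Cr/Au thicknesses
tirekit fit-thickness --spectrum data/spectrum_03.csv
tirekit fit-kinetics --traces data/ --out affinity.csv
tirekit run --indir data/ --outdir results/      # full pipeline + manifest
```

File formats (plain CSV with `#` metadata headers) and the YAML stack
configuration are documented in `docs/methods.md`.

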