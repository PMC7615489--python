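# lnpkit

Coupled analysis of **enzyme-responsive lipid nanoparticles** (LNPs):
single-particle Raman ratiometrics and conversion kinetics, small-angle
scattering model fitting and mesophase indexing with water-channel geometry,
and fluorescence-cascade enzyme-activity readout — plus a synthetic-data
generator with known ground truth so the entire chain is testable end to end.

## Who this is for

Biophysicists characterising lipid nanocarriers whose composition and internal
structure respond to an enzyme. The motivating system is a
monoolein/cholesterol/DOPC particle with internal bicontinuous cubic (Im3m)
structure: phospholipase D (PLD) cleaves the choline headgroup from DOPC,
producing anionic DOPA, which changes both the particle's Raman fingerprint
and its internal mesophase. The package covers the three measurement channels
such a study combines:

1. **Single-particle Raman** (`lnpkit.raman`, `lnpkit.kinetics`) — spectra of
   individually trapped particles are truncated to 340–1825 cm⁻¹, response
   corrected, despiked, baseline-subtracted with a Whittaker
   asymmetric-least-squares smoother (λ = 100 000), and Savitzky–Golay
   smoothed (7 points, order 2). Band heights are located by local parabolic
   fitting; the choline 718 cm⁻¹ band normalised to cholesterol 703 cm⁻¹ (or
   β-CH 990 cm⁻¹) quantifies the remaining DOPC substrate. Particle
   populations sampled over time after enzyme addition are fitted with
   first-order kinetics, `f(t) = A·exp(−k t)`, reporting the rate `k` and the
   half-time `t₅₀ = ln 2 / k`, alongside the model-free *band-crossing*
   estimator (the observation times of particles whose ratio falls between
   the 45% and 55% calibration levels).

2. **Small-angle scattering** (`lnpkit.sasfit`, `lnpkit.saxsindex`) — 1D SANS
   curves are fitted with a combined broad-peak + Lorentz-peak model

   ```
   I(q) = A/qⁿ + C / (1 + (|q − q₀| ξ)ᵐ) + B / (1 + ((q − q_B)/w)²) + bkg
   ```

   with the Porod prefactor A fixed at 1; the broad-peak position gives the
   d-spacing `d = 2π/q₀`, the Im3m lattice parameter `a = √2·d` (lowest
   allowed reflection), and the aqueous channel diameter
   `D_w = 2(√(σ₀/(−2πχ))·a − l)` from minimal-surface geometry
   (σ₀ = 2.3451, χ = −4 for the primitive surface). Bragg-resolved SAXS
   patterns are peak-picked and indexed greedily against the characteristic
   spacing ratios of Im3m, Pn3m, Ia3d, inverted-hexagonal and lamellar
   phases, resolving coexisting mixtures.

3. **Fluorescence cascade** (`lnpkit.fluor`) — plate-reader traces of the
   coupled PLD → choline oxidase → peroxidase → reporter cascade, modelled as
   two sequential first-order steps, yield the plateau `F_max` (proportional
   to substrate), the half-time `T₁/₂`, the local linear rate around the
   half-max point (5-point fit), and the plateau-vs-substrate calibration
   line.

Group comparisons follow a fixed decision tree (`lnpkit.stats`): Lilliefors
normality per group when n ≥ 4 (Monte-Carlo null), Kruskal–Wallis or Wilcoxon
rank-sum for non-normal data, one-way ANOVA when all groups are small, and
Tukey–Kramer post-hoc tests at α = 0.05, with a full audit trail.

## Worked example

```python
import numpy as np
from lnpkit import synthgen, raman, kinetics, sasfit

# --- enzymatic time-course: one fresh particle trapped per minute ---------
scenario = synthgen.ConversionScenario(k=0.1, t_window=30.0, n_particles=60,
                                       enzyme_label=280.0)
spectra = synthgen.gen_timecourse(scenario, seed=42)
times = np.array([s.meta["time_min"] for s in spectra])
ratios = np.array([raman.band_ratio(raman.preprocess(s), 718.0, 703.0).value
                   for s in spectra])
fit = kinetics.fit_first_order(times, ratios, include_offset=True)
print(fit.summary())

# --- SANS broad-peak fit and water-channel geometry -----------------------
curve = synthgen.gen_sas_curve(rel_noise=0.05, seed=1)
result = sasfit.fit_curve(curve)
geom = result.geometry(monolayer_length=17.0)
print(f"d = {result.d_spacing:.2f} A, a = {geom.lattice_a:.2f} A, "
      f"water channel = {geom.water_channel_diameter_nm:.2f} nm")
```

Output:

```
First-order conversion kinetics
==================================
k (1/min)            0.10116 +/- 0.00184
t50 (min)              6.852
amplitude            0.73821
offset               0.11955
residual rms        0.008724
n points                  60
d = 71.55 A, a = 101.18 A, water channel = 2.78 nm
```

The fitted rate recovers the generator's ground truth (k = 0.1 min⁻¹, i.e.
t₅₀ ≈ 6.93 min) within ~1% — the positive offset is the residual band-overlap
floor of the ratio, not a kinetic parameter — and the broad peak generated at
q₀ = 0.088 Å⁻¹ maps to d ≈ 71 Å, an Im3m lattice of ~101 Å and a ~2.8 nm
aqueous channel for a 17 Å lipid monolayer.

A reproducible multi-stage pipeline (simulation → analysis → reports with
embedded config hash and seed) is available through YAML configs:

```bash
lnpkit run config.yaml          # or: lnpkit simulate sans config.yaml, ...
```

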