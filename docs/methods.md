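# Methods

This note documents the models, numerical choices and design decisions behind
`lnpkit`, and what the synthetic-data generator does and does not emulate.

## Single-particle Raman analysis

### Preprocessing chain

Raw spectra are processed in a fixed order: truncation to the 340–1825 cm⁻¹
fingerprint window, point-wise division by an instrument response curve (if
supplied; zeros on the grid are rejected), cosmic-spike removal, Whittaker
asymmetric-least-squares (AsLS) baseline subtraction, and Savitzky–Golay
smoothing.

**Baseline.** The AsLS smoother minimises
`Σ wᵢ (yᵢ − zᵢ)² + λ Σ (Δ²z)ᵢ²` with `wᵢ = p` above the current baseline and
`1 − p` below, iterated 10 times. Defaults: λ = 100 000, p = 0.001. The small
asymmetry makes the baseline hug the noise minima, so a baseline-subtracted
spectrum carries a small constant uplift of order the noise level; this
cancels exactly in band ratios whenever it enters numerator and denominator
alike, and is absorbed by the free floor term in the kinetics fit (below).
λ is expressed per grid index, so it is tied to the default 1 cm⁻¹ sampling;
resampling a spectrum requires rescaling λ by the fourth power of the step
ratio.

**Spike removal.** A cosmic spike is an excursion above a 9-bin rolling
median exceeding 8 robust standard deviations. Two implementation details
matter. First, the noise scale is estimated from successive differences
(`σ = 1.4826 · median|Δy| / √2`) because the rolling-median residual is
identically zero wherever the data are locally monotone — true for most of a
sloped fluorescence background — which degenerates a MAD taken on the
residual itself. Second, the ≤ 2-bin width requirement is applied to the
3σ support of the excursion: a sharp band can poke above the 8σ level in a
one-bin sliver at its very top while remaining above the noise over its full
width, and must not be eaten as a spike. Flagged bins are replaced by linear
interpolation and recorded in the output metadata.

**Smoothing.** Savitzky–Golay, 7 points, order 2. On the default grid this
window spans 7 cm⁻¹; for 12 cm⁻¹-wide bands it attenuates parabolic peak
heights by well under 1% per pass, which keeps the full chain near-idempotent
(a second pass changes standard band heights by < 1%).

### Peak location and band ratios

Band heights are extracted by local parabolic fitting: the maximum bin inside
a search window and its two neighbours define a parabola whose vertex gives
the sub-bin centre and height. Refinement applies only where the maximum bin
is a genuine local maximum; on a flank (e.g. an absent band whose window
maximum sits at the window edge against a neighbouring band) the bin value is
used unchanged, so the feature never extrapolates outside its window.

Ratios use heights, not areas. The default search half-window for ratio
bands is 2 cm⁻¹ — deliberately tight. The closest ratio pair (703/718 cm⁻¹)
is separated by 15 cm⁻¹ while the bands are ~12 cm⁻¹ wide; a wider window
lets the maximum-bin search ride up the partner band's Lorentzian flank as
the band of interest weakens, which makes the ratio-vs-composition relation
progressively nonlinear at low substrate content. With the tight window the
relation is affine over essentially the whole conversion range, up to a small
constant overlap floor. The 548 and 1445 cm⁻¹ bands are supported as display
normalisation anchors only; no ratio depends on them.

A spectrum whose denominator band has non-positive height is excluded from
population statistics and counted, mirroring manual rejection of unusable
spectra; the package exposes only this objective criterion.

## Conversion kinetics

Per-particle ratios are mapped to substrate fraction by linear interpolation
between the medians of two control populations (all-substrate 15:0 and
all-product 0:15 PC:PA), clipped to [0, 1]. The population time-course is
fitted with `f(t) = offset + amplitude · exp(−k t)` by bounded least squares
(k ≥ 0, amplitude ∈ [0, 1.2], offset ∈ [0, 0.5]) with a multi-start over five
log-spaced rate initialisations. `t₅₀ = ln 2 / k`; all-constant data return
k = 0 flagged non-identifiable. An optional dead-time lag exists but is off
by default, and Michaelis–Menten parameters are deliberately not offered:
with enzyme in excess over substrate they are not identifiable from these
time-courses.

The pipeline's rate estimate is fitted **on the raw ratio scale with a free
non-negative offset**, not on calibrated fractions: the rate of a first-order
decay is invariant under any affine transformation of the observable, and the
offset absorbs the constant band-overlap floor. The two-point calibration
pins its zero endpoint to the fully converted control, which sits *on* that
floor; mapping through it and then forcing a zero asymptote would tilt the
whole decay and bias k upward by tens of percent. The calibrated fractions
feed the model-free band-crossing estimator instead: particles whose fraction
lies in [0.45, 0.55] contribute their observation times, summarised as
median ± IQR — an estimator that needs no functional form and inherits no
calibration tilt.

## Small-angle scattering

### Broad-peak model

`I(q) = A/qⁿ + C/(1 + (|q − q₀| ξ)ᵐ) + B/(1 + ((q − q_B)/w)²) + bkg`, with
the overall multiplier and the Porod prefactor A fixed at 1 and, when a curve
shows no narrow feature near 0.1 Å⁻¹, B frozen at 0. Fitting is weighted
least squares (weights 1/dI² when uncertainties are present), bounded, with
multi-start over five q₀ values spread across the data range plus one
data-driven start (maximum of the curve after removing the low-q power law).
Parameter uncertainties come from the Gauss–Newton covariance at the optimum;
the reduced chi-square is reported.

The B term is *defined* as a narrow Bragg-like feature signalling a
coexisting inverted-hexagonal phase, and its bounds encode that definition
(position 0.08–0.12 Å⁻¹, half-width ≤ 0.01 Å⁻¹). Without these bounds the
narrow and broad terms can swap roles in noisy fits — the narrow Lorentzian
widens to absorb the correlation peak while q₀ wanders off — which is a
parameterisation degeneracy, not a data feature.

`detect_hii_feature` decides the B-term default: the curve restricted to
0.07–0.13 Å⁻¹ is detrended with a quadratic Savitzky–Golay baseline over a
~0.015 Å⁻¹ window — wide enough to suppress a narrow Bragg-like peak, short
enough that the smooth Porod decay and the broad correlation peak (locally
parabolic on that scale) pass into the trend — and a residual local maximum
inside 0.08–0.12 Å⁻¹ above 3× the flanking noise plus a 0.5% relative floor
counts as a feature. A median filter is unsuitable here: the narrow shoulder
usually rides on a monotone flank, and a median filter returns locally
monotone data unchanged, leaving no residual maximum at all.

### Geometry

`d = 2π/q₀`. The broad-peak position is read as the lowest allowed Im3m
reflection, the (110), so `a = √2·d` by default; the factor is configurable
(1 or √2) and every output records which was used. The water-channel radius
follows minimal-surface geometry, `r_w = √(σ₀/(−2πχ))·a − l`, with the
primitive-surface constants σ₀ = 2.3451, χ = −4 (prefactor ≈ 0.3055) held in
an editable table that also carries the D (Pn3m) and G (Ia3d) surface
constants. The lipid monolayer length `l` is a required user parameter,
default 17 Å — it is a property of the lipid mixture, not of the scattering
data. A channel radius within 10⁻⁹·a of zero is reported as 0 and flagged
degenerate; a negative radius is an error ("channel closed / l
inconsistent"). Lengths are reported in both Å and nm.

### Bragg indexing

Candidate phases carry allowed-N sequences — Im3m: 2,4,6,8,10,12; Pn3m:
2,3,4,6,8,9; Ia3d: 6,8,14,16; H_II: 1,3,4,7 (on q₁ = 4π/(√3·a)); lamellar:
1,4,9 — in a user-extensible YAML-loadable table. Peaks are detected on a
median-filter-detrended curve with a prominence threshold (default 5× robust
noise) and refined with the same 3-point parabola used for Raman bands.

Indexing is greedy: for each candidate phase and each choice of anchor peak
as its first allowed reflection, the remaining reflections are predicted and
matched within a relative tolerance (default 1%); assignments are scored
lexicographically by (number matched, −rms relative residual); the best is
accepted, its peaks removed, and the search repeats. The lattice parameter
comes from the least-squares slope of q against √N constrained through the
origin. Cubic assignments require ≥ 2 matched reflections (ratio evidence);
single-reflection hexagonal/lamellar assignments are emitted but flagged
*tentative* and excluded from geometry calculations — a deliberate
quantitative convention where visual judgement would otherwise decide.
Anchor enumeration guards against a weak or absent lowest-order reflection.
Shrinking the tolerance can only reduce the number of matched reflections.

## Fluorescence cascade

The coupled assay (PLD releases choline; choline oxidase produces H₂O₂;
peroxidase converts a profluorophore) is modelled as two sequential
first-order steps:

`F(t) = F_max [1 − (k₂ e^(−k₁t) − k₁ e^(−k₂t)) / (k₂ − k₁)]`,

with `k₁ = k_pld` rate-limiting, `k₂` the lumped reporter step, and
`F_max = c·S₀` proportional to substrate. For `k₂/k₁ ≥ 100` this is within 1%
of a single exponential at all times, and `T₁/₂ ≥ ln 2 / k₁` always (the
cascade only delays).

`F_max` is the median of the last 5% of time-ordered points, flagged
*unsaturated* when the last 10% of the trace still rises faster than 1% of
`F_max` per minute — a slow scenario must be read out over a long enough
trace (the analysis of a 10×-slower "vesicle" cascade uses an overnight-style
window). `T₁/₂` is the first upward crossing of `F₀ + (F_max − F₀)/2`, linear
interpolation between the bracketing samples, where `F₀` is the median of the
first 5 points; the baseline-subtracted convention is the default and the
plain `F_max/2` convention is switchable. The local rate is the OLS slope
over 5 samples centred on the sample nearest the interpolated crossing
(shifted inward at trace boundaries, with the shift recorded). The
plateau-vs-substrate calibration is an OLS line over ≥ 3 distinct substrate
levels with R² reported. Well evaporation and enzyme decay over long
incubations are outside the model.

## Statistics decision tree

Reporting: median ± IQR for groups with n ≥ 10, mean ± sd below (threshold
configurable); the rule used is recorded per group. Testing: Lilliefors
normality per group whenever n ≥ 4, with the null distribution of the
statistic (KS distance after estimating mean and sd) simulated by Monte Carlo
— 10 000 replicates, seeded, cached per sample size so repeated calls don't
re-simulate; any non-normal group routes to Kruskal–Wallis (> 2 groups) or
Wilcoxon rank-sum (2 groups); when *all* groups are small (n ≤ 5), one-way
ANOVA is used regardless of normality outcomes — normality testing at such n
is uninformative, and this precedence resolves the overlap between the two
small-sample rules; zero-variance small groups fall back to the rank-based
test. Significant omnibus tests with > 2 groups are followed by Tukey–Kramer
pairwise comparisons at α = 0.05, computed on rank-transformed data after a
Kruskal–Wallis omnibus. Every branch taken is recorded in an audit trail that
is a pure function of the inputs and seed. Under null simulations (two normal
groups of 50, 2000 replicates) the tree's empirical type-I error sits within
[0.03, 0.07] at nominal α = 0.05.

## Synthetic-data generator

The generator is first-class, tested code; every stochastic call takes one
explicit seed and is bit-reproducible.

**Raman.** A particle's spectrum is a lognormal per-particle intensity scale
(σ = 0.2) times a sum of pseudo-Voigt bands (fixed 0.5 Gaussian fraction)
whose amplitudes are stylised weights times component mole fractions, plus a
3rd-order polynomial background reaching ~10× the tallest band, Gaussian
noise (σ = 0.02 counts) and Poisson-count cosmic spikes. The band table puts
choline at 718 cm⁻¹ (DOPC), cholesterol at 703 and 548 cm⁻¹, β-CH at
990 cm⁻¹ (DOPA, with a weak DOPC shoulder so the 718/990 denominator stays
usable at low conversion), CH₂/CH₃ at 1445 cm⁻¹ fed by every lipid, and
monoolein backbone/C=C bands at 1086/1302/1656 cm⁻¹. The 703/718 widths
(12 cm⁻¹ FWHM) are typical of lipid fingerprint bands and sit in the regime
where the 7-point smoothing is height-preserving. Weights are calibrated only
to reproduce monotone ratio-vs-composition behaviour, not absolute
cross-sections, which are not part of the model. Acquisition: 320–1840 cm⁻¹
at 1 cm⁻¹ steps; grids coarser than 5 cm⁻¹ are rejected as unable to resolve
the 703/718 pair.

**Time-courses.** One *fresh* particle per sampling time (never a repeated
measurement of one particle): at time t the particle's DOPC fraction is
`0.15·e^(−kt)` and DOPA is the complement, so DOPC + DOPA = 0.15 always.
Heterogeneity is overall-intensity scatter only; no compositional scatter
between particles at fixed time. Default design: 60 particles over 30 min.

**Scattering.** SANS curves come from the broad-peak forward model on a
200-point log grid over q = 0.005–0.725 Å⁻¹ with Gaussian noise of sd
`rel_noise · I(q)`, recorded in the dI column (omitted when rel_noise = 0,
where the curve equals the model exactly). With the Porod prefactor pinned at
1, the absolute intensity scale is dictated by the power law; the default
Lorentz scale (250) gives the correlation peak ~3× contrast over the
underlying decay at q₀ = 0.088 Å⁻¹ — a clearly resolved peak, as in measured
curves of well-ordered particles — and the default narrow peak (B = 25,
half-width 0.004 Å⁻¹ at 0.1 Å⁻¹) is a prominent, detectable H_II signature.
Bragg patterns are Gaussian peaks at the phase's allowed positions with
1/(1+j) amplitude decay on a smooth background.

**Fluorescence.** Cascade traces sampled once per minute for 300 min,
`k_pld = 0.05 min⁻¹` and `k_cascade = 0.5 min⁻¹` by default (reporter step
10× faster), plateau 100 a.u. per unit substrate, additive Gaussian noise.
Enzyme-concentration series use `k_pld` proportional to the nominal activity
label.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: instrument drift and wavelength-calibration error,
detector saturation, compositional scatter between particles, structured
(non-polynomial) fluorescence backgrounds, SANS resolution smearing and
incoherent-background structure, multi-phase Bragg intensity systematics
(structure factors), enzyme inactivation and well evaporation in long plate
reads, and any absolute Raman cross-section or absolute scattering scale.
Recovery percentages quoted by the tests are properties of this idealised
forward model at its default noise levels, not instrument specifications.

## Pipeline and reproducibility

`workbench.RunConfig` validates YAML/JSON configs strictly (unknown keys
anywhere are rejected; one explicit master seed is mandatory) and hashes the
canonical config into every JSON artifact together with the seed and package
version. Per-stage seeds derive deterministically from the master seed, so
rerunning an identical config is bit-identical; the CLI (`lnpkit run`,
`lnpkit simulate/analyze/fit/index/stats ...`) is a thin wrapper over the
same pipeline and produces identical artifacts. Data interchange is
plain text: two-column spectra CSV plus manifest, 3-column `#`-commented
whitespace-delimited scattering ASCII, CSV fluorescence traces, JSON reports.

## Problem sizes

The test suite and the acceptance script run the study designs at their
stated sizes: 50 fit replicates for scattering recovery, 4 × 50 particles
for the calibration series, 60-particle time-courses (plus three
enzyme-concentration series), 1000 draws for the d-spacing identity, 20
noiseless indexing round trips plus one coexistence mixture, five substrate
levels for the fluorescence calibration, and 2000 Monte-Carlo replicates for
the type-I calibration of the statistics tree.

## Known limitations

- The broad-peak → Im3m lattice step assumes the (110) assignment; if the
  broad peak instead tracks a different reflection or a non-cubic repeat, the
  √2 factor (and hence channel diameters) is off by a known factor — which is
  why the factor is configurable and recorded.
- The exact parameterisation of the combined scattering model ("A scale",
  "B scale") is a reconstruction; it is the only reading consistent with a
  varying Lorentz scale and fixed overall/Porod prefactors, and it is pinned
  down in one place (`BroadPeakParams`).
- The greedy indexer can mis-assign pathological peak sets whose ratios are
  consistent with two phases simultaneously; the (n_matched, −rms) score
  prefers the more complete explanation, and coexistence resolution is only
  guaranteed when reflections are separated by more than twice the peak
  width.
- The Lilliefors Monte-Carlo null is cached per sample size within a
  process; extremely many distinct group sizes in one session cost one
  10 000-replicate simulation each.
- First-order kinetics assume a single homogeneous rate; a lagging reaction
  can be accommodated by the optional dead-time parameter but no autocatalytic
  or enzyme-binding mechanism is modelled.
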