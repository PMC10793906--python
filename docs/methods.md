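# Methods

## The measurement being emulated

A resected specimen carrying an NIR fluorescent tracer is imaged face-on
at its basal (deep) cut surface. Two acquisitions are made with the same
detector geometry: wide aperture (NA 0.3, 5 s) and narrow aperture
(NA 0.03, 45 s), both at 205 µm/pixel over a 512×512 grid
(10.5 × 10.5 cm) under 5 mW/cm² excitation. Single-aperture fluorescence
(sAF) is quantified as the mean wide-aperture intensity in a ~1.5 mm test
ROI divided by a clinician-chosen background ROI (an SBR). The
dual-aperture fluorescence ratio (dAFR) is the per-pixel ratio of the
flat-field-corrected wide image over the flat-field-corrected,
3×3-median-filtered narrow image, averaged over the test ROI with no
background normalisation. Ground truth is the pathology margin thickness
at each ROI; classes are positive (< 1 mm), close (1–5 mm, inclusive at
both ends) and clear (> 5 mm).

## Forward model

Photon transport is a weighted random walk in a homogeneous half-space:

- Emission origins are sampled proportional to fluorophore yield times an
  excitation fluence attenuated as exp(−μ_eff z), with
  μ_eff = √(3 μ_a (μ_a + μ_s')). Full excitation transport is not
  simulated; excitation detail scales absolute brightness, not the
  angular physics the dAFR exploits.
- Photons launch isotropically, take exponential steps at rate μ_s,
  deflect by the Henyey–Greenstein phase function with anisotropy g, and
  carry a multiplicative survival weight exp(−μ_a · path).
- At the basal surface, Snell refraction into air applies with
  total-internal-reflection and probabilistic unpolarised Fresnel
  reflection. A photon is *detected* iff its exit angle in air lies
  within the acceptance cone sin θ ≤ NA (ideal thin lens; no vignetting
  or aberrations).

### Estimator

Analog acceptance at NA 0.03 is hopeless (~10⁻³ of escaping photons), so
the expected images are estimated in three parts:

1. **First flight (analytic).** The unscattered escape of every emission
   column is integrated deterministically per pixel: a 16-node
   Gauss–Legendre quadrature over the cone in cos θ, with exact
   piecewise-exponential column integrals. Narrow-cone splats are
   laterally sub-pixel at all depths of interest and bin at the pixel
   itself; annulus (wide-minus-narrow) rays are displaced by z·tan θ and
   find the tumour-front crossing along the slanted ray. This component —
   which carries the depth signal — is noise-free.
2. **Scattered light (Monte Carlo, next-event estimation).** At every
   collision vertex the expected direct Fresnel-transmitted escape into
   the narrow cone and the annulus is tallied by small quadratures
   (denser when the photon points near-vertical, where the forward phase
   peak sweeps across the cones). Surface reflections are not collisions
   and do not tally. The scattered component is smooth on the transport
   scale (≥ 1/μ_s' ≈ 6.7 mm), so it is regularised with a 2.5-pixel
   (0.5 mm) Gaussian before being added to the first-flight images.
3. **Stratification.** One emission stratum per annotated ROI site (a
   10 mm disc, ≥ 10⁶ photons each) plus one for the rest of the field
   guarantees every ROI its photon budget; stratified depth and radius
   quantiles reduce variance further.

Because the wide image is accumulated as narrow + annulus, the
aperture-nesting property (wide ≥ narrow pixelwise per unit exposure)
holds by construction. Expected counts scale exactly linearly with
exposure, illumination power and fluorophore yield. Detector noise is
Poisson(expected) + N(0, 2.3² e⁻), clipped at zero and quantised;
detector conversion is fixed so the wide image fills a comfortable part
of the 16-bit range while the narrow image stays dim.

## Why the dAFR encodes depth here

For laterally extended sources the per-pixel ratio of two concentric
acceptance cones is pinned near the solid-angle ratio by shift
invariance; the usable depth information in this model comes from
*slant-path attenuation*: an annulus photon exits along a path longer by
a factor 1/cos θ, so the unscattered wide-annulus signal decays faster
with source depth than the near-normal narrow-cone signal. The effect
persists as long as first-flight light still reaches the surface —
i.e. within the sub-diffuse window — and saturates once multiple
scattering dominates. With the default optics the ROI-mean dAFR falls
strictly monotonically by ~18% as the margin thickness grows from 0.5 to
10 mm, which is the basis of close-vs-clear discrimination. Deeper
margins are *less* attenuated in the narrow channel only in relative
terms; the absolute images dim with depth as expected.

Clinical reports of this technique quote dAFR values below 1 that *rise*
with margin thickness, which is consistent with a reciprocal or
reference-normalised variant of the wide/narrow formula; the absolute
dAFR scale depends on an instrument normalisation that such reports do
not describe and that is not reproduced here. This package computes the
ratio as wide over narrow, so its dAFR falls with thickness, and the score
orientation used for classification ("cases score high") is an explicit,
reported calibration parameter rather than an assumption.

## Default parameters

| parameter | value | why |
|---|---|---|
| μ_a | 0.05 mm⁻¹ | NIR absorption of soft tissue |
| μ_s, g | 0.25 mm⁻¹, 0.4 | μ_s' = 0.15 mm⁻¹ → reduced mean free path ≈ 6.7 mm, inside the 5–10 mm sub-diffuse window the method assumes. A low-anisotropy, similarity-equivalent pair is used because strongly forward-peaked phase functions make shadow-ray tallies heavy-tailed |
| n_tissue | 1.4 | soft tissue refractive index |
| background front | 25 mm | "clear everywhere else"; deep enough that its glow does not contaminate 8–10 mm margins |
| background uptake ratio | 0.002 | off-target tracer in the overlying tissue |
| site geometry | 1.5 mm plateau + 3 mm taper | the tumour front rises to the requested thickness under each ROI and relaxes smoothly (dome-like apex); optional mm-scale front roughness is off by default |
| ROI | 1.5 mm circle, center-in rule | matches the clinical annotation practice |
| exposures, NA, pixel pitch, read noise, power | 5 s / 45 s, 0.3 / 0.03, 205 µm, 2.3 e⁻, 5 mW/cm² | instrument values |
| thickness draws | uniform per class, quantised to 0.25 / 0.5 / 1 mm (positive / close / clear) | pathology reports margins at finite granularity |
| heterogeneity | ±30% smooth uptake field, ±15% illumination gain, μ_s ±10% / μ_a ±15% per specimen | plausible within-study variability |
| narrow-signal floor | 3 × read-noise equivalent | pixel-level analogue of the study's SNR-based exclusion; 0 reproduces a literal unguarded ratio |

The default study design is 3 specimens × 4 test ROIs with class counts
{positive 1, close 5, clear 6}, plus one background ROI per specimen (a
site with no tumour apex) for the sAF denominator. All randomness derives
from a single seed through documented SeedSequence spawning (thicknesses,
then per specimen: optics jitter, uptake field, transport, flats, noise);
identical seeds give bit-identical fixtures.

## Statistics

Every margin is treated as an independent sample, mirroring the study
design being emulated (four locations per specimen); this assumption is
recorded in the report rather than hidden. AUC is the Mann–Whitney
pair-ordering statistic (ties ½) with operating points at all score
midpoints plus ±∞; the Youden threshold maximises sensitivity +
specificity − 1 with ties broken toward higher specificity; confusion
proportions are reported as whole percents rounded half-up and are
*undefined* (never 0) on empty denominators. Pearson p-values use the
two-sided t transform on n − 2 degrees of freedom. The paired AUC
comparison is DeLong's structural-components test on the same subjects —
a deliberate substitution for the multi-reader multi-case software used
clinically, which has no reader factor to model here; its exact p-values
and confidence intervals are therefore not comparable. No
multiple-testing correction is applied, matching the emulated analysis.

## What the synthetic data does and does not show

The generator reproduces the *mechanics* of the study — acquisition
geometry, noise, processing chain, class structure and sample size — and
a physically motivated depth signal with realistic nuisance variation.
Passing tests therefore demonstrate that the pipeline and statistics are
correct and that the dAFR's depth encoding and optical-property
insensitivity hold in this transport model. They do not demonstrate
clinical performance: real specimens add surface topography, spatially
structured optical properties, inter-patient uptake variation far larger
than modelled (which is why the simulated sAF performs much better here
than clinically), co-registration error between pathology and image
space, and an instrument dAFR normalisation not described in print.

## Numerical choices and degenerate inputs

Roulette termination uses a weight × diffuse-escape-bound trigger
(unbiased for any trigger) plus depth and lateral kill zones well outside
the imaged volume; tallies are skipped once the direct-escape factor
underflows (μ_t z > 40). Flat-field division flags non-positive flat
pixels invalid instead of dividing; ratio pixels below the narrow floor
are invalid and excluded from ROI means; an ROI with no valid pixels
yields an explicit undefined-measurement record. Tasks whose case or
control set is empty are skipped with a logged reason, as is the paired
AUC comparison when either marker has fewer than two defined cases or
controls (the positive task, with its single positive margin, always
skips it). Degenerate DeLong variance returns p = 1 for a zero difference
with a collapsed interval.

## Problem sizes

Default runs use 10⁶ photons per ROI stratum at 512×512 (a full study
simulates in well under a minute on one CPU). The property tests use a
160-pixel (33 mm) single-site field for depth sweeps and perturbation
grids, and 27 Monte-Carlo repeats (3×3 optical-property grid × 3 seeds)
for the insensitivity check.

## Known limitations

- Homogeneous bulk optics per specimen (heterogeneity enters through the
  uptake field, illumination gain and per-specimen jitter, not through a
  spatially varying μ map inside one specimen).
- No polarisation, fluorophore lifetime, spectral resolution, camera
  PRNU, lens distortion, excitation-light Monte Carlo or tomography.
- The absolute dAFR scale is arbitrary (no attempt to match the printed
  0.63 threshold) and its sign convention follows the printed formula,
  not the printed plot (see above).
- Basal-margin segmentation is an input mask, not an algorithm; ROI
  placement is taken from the annotation file.
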