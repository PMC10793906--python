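# dafr — dual-aperture fluorescence ratio margin assessment

`dafr` is a desk-scale re-creation of depth-sensitive fluorescence imaging
for intraoperative assessment of surgical margins in head-and-neck cancer
resections. After administration of an NIR tracer (e.g. an EGFR-targeted
antibody–IRDye 800CW conjugate), the resected specimen's basal surface is
imaged twice with the same camera: once at a **wide** numerical aperture
(NA = 0.3, 5 s) and once at a **narrow** aperture (NA = 0.03, 45 s). The
pixel-by-pixel ratio of the flat-field-corrected wide image over the
median-filtered narrow image — the **dual-aperture fluorescence ratio
(dAFR)** — encodes how deeply the fluorescent tumour lies beneath the
surface (the *margin thickness*), while cancelling illumination, exposure
and tracer-uptake variation that confound conventional single-aperture
fluorescence (sAF) read as a signal-to-background ratio (SBR).

Margins are classed clinically by thickness: **positive** < 1 mm,
**close** 1–5 mm, **clear** > 5 mm; positive ∪ close = *inadequate*.

The package provides, in `dafr.core`:

1. **Synthetic data** — a Monte-Carlo photon-transport simulator
   (Henyey–Greenstein scattering, exponential absorption weighting,
   Snell/Fresnel refraction at the basal surface, ideal-thin-lens
   acceptance cones) that renders paired wide/narrow 16-bit images of
   virtual specimen phantoms with known margin thickness, heterogeneous
   illumination and uptake, shot noise and 2.3 e⁻ rms read noise. The
   unscattered component is computed analytically per pixel; a
   next-event (shadow-ray) estimator handles the scattered remainder.
2. **Image pipeline** — flat-field division, 3×3 median filtering of the
   narrow image, the dAFR ratio image with a narrow-signal validity floor,
   and circular-ROI (~1.5 mm) quantification against a basal-margin mask,
   yielding per-margin sAF SBR and mean dAFR values.
3. **Statistics** — Mann–Whitney ROC/AUC per classification task
   (positive, close-vs-clear, inadequate), Youden-index thresholds with
   confusion metrics (whole percents, half-up), Pearson correlation of
   each marker with margin thickness, and a DeLong-style paired test of
   the two correlated AUCs.

## Worked example

Reproduce the default simulated study (3 specimens × 4 margin locations;
1 positive, 5 close and 6 clear margins; ≥10⁶ photons per ROI):

```sh
dafr reproduce-study --seed 1 --out study/
```

(or `python -m dafr reproduce-study ...`). This writes the simulated
images, `measurements.csv`, `report.json`, per-task metrics and ROC-point
CSVs, and a provenance file that allows a bit-identical re-run. The
measurement table for seed 1 begins:

```
specimen_id,roi_id,true_thickness_mm,margin_class,saf_sbr,dafr_value,...
S1,S1R1,0.75,positive,123.60,11.068,...
S1,S1R2,1.5,close,95.90,10.910,...
S1,S1R4,7.0,clear,7.85,9.792,...
```

`dafr_value` falls monotonically with margin thickness (Pearson
r = −0.96, p = 7.6e−07 at seed 1): in this forward model the wide
aperture's annular acceptance collects photons on longer slant paths, so
its signal is attenuated faster with fluorophore depth than the
near-normal narrow-cone signal. Thin (inadequate) margins therefore score
*high* on dAFR; the score orientation is an explicit, reported calibration
parameter. For the close-vs-clear task at seed 1 the report contains:

```
close dAFR: AUC 1.0, Youden threshold 10.48,
            sensitivity 100%, specificity 100%, PPV 100%, NPV 100%
```

i.e. the dAFR separates all 5 close from all 6 clear margins. The sAF SBR
is also reported per margin, with its own ROC/Youden analysis and a paired
AUC comparison per task.

Individual stages are composable from the shell: `dafr simulate`,
`dafr process` (TIFF + ROI JSON → measurements CSV) and `dafr analyze`
(measurements CSV → report).

## Layout

```
src/dafr/core.py     the whole implementation, in the order the method
                     runs: constants, domain types, photon transport,
                     synthetic data, image pipeline, statistics, I/O
src/dafr/__main__.py thin click CLI (`dafr`)
docs/methods.md      model, assumptions, parameter choices, limitations
tests/               pytest suite (unit, property/oracle, acceptance)
```
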