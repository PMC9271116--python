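# rtcine

Retrospective binning of free-breathing **real-time cardiac MRI** into an
expiratory cine stack, with everything needed to exercise and validate the
pipeline on a digital beating-heart phantom.

## The problem

Standard cine MRI reconstructs one representative heart cycle from a
segmented, ECG-gated acquisition and needs repeated breath-holds — a poor
fit for children and for anyone who cannot hold their breath. Real-time MRI
instead streams single images continuously (~30 frames/s for ~30 s per
short-axis slice) during free breathing. To make those streams quantifiable
they must be reorganized after the fact: each frame carries the ECG-derived
time since the last R wave (DICOM Trigger Time), and a respiratory-bellows
belt logs a 1-D surrogate of lung volume. `rtcine` implements that
reorganization and the analysis that follows it:

1. **Bellows preprocessing** — zero-phase low-pass Butterworth denoising
   (default order 4, 1 Hz cutoff), robust rescaling to a fixed [0, 4000]
   a.u. scale, and linear interpolation onto each frame's acquisition time.
2. **Respiratory gating + ECG binning** — the mean R-R interval is split
   into 25 equal half-open phase windows of width `mean_RR / 25`. Within a
   window, frames at low lung volume (bellows < 2000 a.u.) compete and the
   frame closest to the expiratory class median (1000 a.u.) becomes the
   phase representative. The output is a 25-phase cine stack per slice,
   written as standard single-frame cine DICOM.
3. **Auto-windowing** — display window from the intensity histogram:
   `threshold_count = total_pixels / 2500`, threshold intensity = the
   largest intensity with at least that many pixels,
   `width = threshold − min`, `center = width/2 + min`.
4. **Volumetry** — blood-pool areas per slice, disc summation
   `V = Σ areaᵢ · thickness`, EDV/ESV as the extremes of the 25-phase
   volume curve, `SV = EDV − ESV`, `EF = 100 · SV / EDV`, indexed to body
   surface area by DuBois (`0.007184 · W^0.425 · H^0.725`).
5. **Agreement statistics** — Bland–Altman bias and 1.96-SD limits of
   agreement, OLS regression, Shapiro–Wilk-guided paired t / Wilcoxon
   tests, ICC with poor/fair/good/excellent bands (0.5/0.75/0.9), Spearman
   rho with Cohen bands (0.1/0.3/0.5).

A seeded **phantom simulator** generates the whole input side — a beating,
breathing two-ventricle heart rendered into real-time frames with trigger
times and a noisy bellows trace — with analytic ground-truth volumes, so
the full pipeline can be tested end to end without patient data.

## Worked example

Run the full pipeline on a reduced phantom (8 slices, 128² matrix, 20 s per
slice; ground truth LV 150/54 ml, RV 126/53 ml):

```sh
cat > demo.yaml <<EOF
phantom:
  matrix: 128
  pixel_mm: 2.5
  n_slices: 8
  duration_s: 20.0
EOF
rtcine --config demo.yaml pipeline --seed 1 --out demo --weight 52 --height 160
```

The manifest (`demo/manifest.json`) reports, per ventricle:

```
LV  EDV 150.2 ml  ESV 54.9 ml  SV 95.4 ml  EF 63.5 %   EDVi 98.4  ESVi 35.9  SVi 62.5 ml/m²
RV  EDV 125.8 ml  ESV 53.6 ml  SV 72.2 ml  EF 57.4 %   EDVi 82.5  ESVi 35.1  SVi 47.3 ml/m²
```

against analytic truth of EF 64.0 % (LV) and 57.9 % (RV) — the retrospective
binning plus threshold segmentation recovers ejection fraction to well
within one EF point here, and every one of the 8 × 25 bins was filled from
gated (low-lung-volume) frames (`n_fallback: 0`, phase duration 30 ms from
the 750 ms mean RR). The stages can also be run separately
(`rtcine simulate / bin / window / volumetry / agree`).

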