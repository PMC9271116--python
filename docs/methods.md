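# Methods

## Binning model

The pipeline assumes each real-time frame carries two timing tags on a
common millisecond clock: the acquisition time and the ECG-derived time
since the last R wave (DICOM Trigger Time, as written by the scanner).
One reconstructed heart cycle of length `mean_RR` is divided into
`n_phases = 25` half-open windows `[k·w, (k+1)·w)`, `w = mean_RR / 25`.
Frames whose trigger time reaches or exceeds `mean_RR` come from beats
longer than the mean cycle; they are **discarded** rather than clamped into
the last phase, since clamping would mix late-diastolic content into phase
24. `mean_RR` is taken from configuration when known (the per-patient
value), otherwise reconstructed from trigger-time resets: at a reset the R
instant is `acq_time − trigger_time` exactly, so successive resets give
exact R-R gaps (`estimate_mean_rr`).

Within a phase window the respiratory gate keeps frames with bellows
strictly below `gate_threshold` (default 2000 a.u. = half of the working
scale), and the representative is the frame minimizing
`|bellows − median_target|` (default 1000 a.u.), ties resolved by earliest
acquisition time so the result is deterministic. A window whose gated set
is empty falls back to the ungated candidates and is flagged — surfaced in
the per-bin log and a DICOM private tag — because a 30-s acquisition cannot
guarantee every phase × expiration combination; a window empty even before
gating is a hard "insufficient coverage" error. `bin_series` is verified
frame-for-frame against an exhaustive filter-then-argmin oracle in the
test suite.

## Bellows scale

Vendor bellows units are arbitrary and undocumented, so the absolute gating
rules are made reproducible by convention: after zero-phase Butterworth
low-pass filtering (order 4, cutoff 1.0 Hz — comfortably above respiratory
rates, well below cardiac frequencies), the trace is rescaled so its
1st/99th percentiles map to 0/4000 and clipped. On that scale the gate
(< 2000) is half range and the representative target (1000) quarter range.
Robust percentiles rather than min/max keep isolated spikes from
stretching the scale. Filtering is forward–backward (`filtfilt`) so the
gate is not phase-delayed relative to the frames; its boundary transients
are the usual `filtfilt` edge effect, which is why the simulator logs
physio for 2 s beyond the imaging window on each side. Synchronization is
a constant clock offset (default 0) plus linear interpolation; no
cross-correlation refinement is attempted.

## Auto-windowing

`threshold_count = max(1, floor(total_pixels / 2500))` on the integer
histogram (1-unit bins, background included); the threshold signal
intensity is the **largest** intensity with at least `threshold_count`
pixels, read as an upper display bound that excludes sparse bright
outliers — that reading matches the formula's purpose of adapting contrast
for real-time images. Division is floored; if no intensity qualifies the
image maximum is used. `width = threshold − min`,
`center = width/2 + min`, both kept as floats.

## Phantom

The simulator emulates a slice-by-slice free-breathing short-axis
acquisition (defaults: 200² matrix at 1.6 mm/px, 12 slices × 8 mm,
30 frames/s × 30 s per slice, bellows sampled at 50 Hz):

* **Rhythm** — R-R gaps drawn Normal(750 ms, 25 ms), floored at 60 % of
  the mean; cardiac phase is time-since-R over the current (not mean) RR,
  so binning against the mean RR sees realistic jitter.
* **Volume curve** — raised-cosine between EDV (phase 0) and ESV
  (mid-cycle) with the smooth warp `φ' = (1 − cos πφ)/2`. Only
  periodicity and flat ED/ES extremes matter for validating binning; the
  flatness bounds the volume error from a representative frame landing
  anywhere inside its 30 ms bin to ≪ 1 %.
* **Geometry** — LV as a disc with an 8 mm myocardial ring, RV as a
  vertically elongated 0.6-ratio ellipse with a thin rim; total volume is
  spread base-to-apex with a fixed `1 − 0.8 z²` taper so per-slice areas
  are analytic. Structures are rendered with sub-pixel edge coverage;
  intensities blood 800 / myocardium 300 / background 50 with Gaussian
  pixel noise (SD 20).
* **Respiration** — rigid in-plane translation of the whole heart along
  the column axis, amplitude 10 mm, period 4 s; the bellows is the
  displacement scaled to [0, 4000] plus Gaussian noise (SD 60 a.u.).
  In-plane (rather than through-plane) motion conserves slice content, so
  disc summation recovers the analytic volumes exactly in the continuum
  limit and any residual error isolates the gating itself.
* **Determinism** — a single seed drives rhythm, noise and rendering; all
  times are quantized to 1 µs so writing frames to DICOM (TM/DS tags) and
  reading them back is bit-exact, a property the round-trip tests rely on.

What the phantom does **not** emulate: MR physics (bSSFP contrast, coils,
banding), arrhythmia, through-plane motion, hysteresis between bellows and
heart position, and realistic anatomy. Passing the end-to-end tests shows
the binning/volumetry chain is internally correct under known ground
truth, not that threshold segmentation would work on patient images —
clinical contouring is explicitly out of scope.

## Volumetry

Blood pools are segmented by thresholding at the myocardium/blood midpoint
and keeping connected components whose centroid falls in a per-ventricle
ROI box; areas × slice thickness are disc-summed. ED and ES are the
extremes of the 25-phase volume curve (not fixed phase indices), which is
the reproducible reading when contours exist at every phase. BSA uses the
DuBois–DuBois constants `0.007184 · W^0.425 · H^0.725`; EF is invariant
under indexing, and indexed values scale as 1/BSA.

## Statistics

Bland–Altman uses first-minus-second differences, sample SD (divisor
n−1) and bias ± 1.96 SD limits. Descriptive summaries of the reference
cohort use divisor-n SDs, which is what reproduces the cohort's printed
R-R (747.0 ± 132.3 ms) and age (12.8 ± 3.5 y) summaries; both divisors are
explicit parameters. The paired comparison chain tests normality of the
differences (Shapiro–Wilk at α = 0.05) and then applies the paired t test
or the Wilcoxon test; the signed-rank variant is the default because the
data are paired, with the rank-sum variant available behind a flag. ICC
defaults to the two-way, single-measure, absolute-agreement model
(configurable: consistency and one-way models), computed via pingouin.
Classification bands are pure threshold functions with boundary values
assigned to the higher class (ICC 0.75 → "good", rho 0.5 → "strong"),
since the interval notation of the conventional bands is ambiguous at the
cutpoints.

## Problem sizes in the test suite

Single-run protocol checks use the full default phantom (12 × 900 frames
at 200²). Multi-seed suites (oracle equivalence over 20 seeds, parameter
recovery over 10 seeds, coverage-law over 40 runs) use reduced phantoms —
128² matrix at 2.5 mm / 8 slices / 15–20 s, or a 32² miniature for pure
timing/binning logic — chosen so the whole suite and the acceptance script
each complete in a few minutes while preserving the quantities under test
(bin occupancy statistics scale with frames-per-bin, segmentation error
with boundary-pixels-per-area). The statistical calibration uses 500
replicates at n = 200 pairs, where the Shapiro–Wilk p-value is well
calibrated.

## Known limitations

* The bellows→frame offset is a config constant; no automatic
  synchronization refinement.
* Threshold/ROI segmentation is phantom-only by design.
* The cine DICOM writer produces minimal single-frame MR objects (enough
  for standard cine viewers), not full IOD-conformant patient studies.
* Whether the original gating rules were meant on a raw or a normalized
  bellows scale is unknowable from their description; the [0, 4000]
  normalization convention here makes them reproducible by construction.
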