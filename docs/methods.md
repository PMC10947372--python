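# Methods

This note documents the models, conventions and numerical choices behind
`rbdmotion`, in the spirit of a package methods appendix. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Timing conventions

All times are seconds; intervals are half-open `[start, end)`. Frame `i`
of a sequence at `fps` covers `[start_time + i/fps, start_time +
(i+1)/fps)` on the hypnogram clock. Sleep stages use 30-s epochs with
codes W/N1/N2/N3/R; REM intervals are maximal runs of R epochs, and their
lengths always sum to `3600 × rem_hours`. A video/hypnogram clock mismatch
beyond one epoch raises a warning, not an error — the alignment contract
between polysomnograph and camera is a package convention, not a recording
standard.

## Motion detection

**Frame differencing.** A pixel changes between consecutive frames when
its depth moves by more than `pixel_delta_mm` (default 10 mm). Depth is
16-bit millimetres in [0, 8000]. Differencing consecutive frames means a
*held* posture is invisible; only ongoing motion registers, which is the
desired semantics for movement events.

**Region precedence.** Head and hand regions are dynamic boxes from an
external body-part detector and take precedence over the static upper-body
polygon: valid boxes are subtracted from the upper-body mask; where boxes
are missing (detector dropout) the pixels fall back to the upper body, so
no movement is lost and none is double-counted. Head wins over hands where
boxes overlap; the four masks partition the changed pixels. Boxes are used
as plain rectangles.

**Area threshold.** A region is flagged in a frame when its changed-pixel
count reaches `min_area_px` (defaults 50 px for upper/lower body, 20 px
for head/hands, stated for the nominal 512×424 frame; at reduced
resolutions the thresholds should be scaled with pixel count, which is
what the test suite does). These thresholds are screening knobs, not
calibrated constants; they are configurable and recorded in outputs.

**Respiration suppression.** Respiration appears in a region's
changed-area signal as a *sustained narrowband tone*: an oscillation of
the chest at `f` Hz is rectified by differencing into an area signature at
`2f` plus harmonics riding on a baseline pedestal. Genuine movements are
broadband transients. A linear band-stop filter cannot serve both facts:
removing 0.15–0.5 Hz outright would cut the peak of a 1-s movement pulse
to roughly 40 %. The filter is therefore adaptive: it searches the band
(extended to twice its upper edge, for the rectification doubling) for a
spectral line that (a) exceeds 4× the median in-band magnitude and (b)
carries at least 5 % of the signal's AC spectral power — a sparse train of
movement pulses has prominent but individually weak lines and must not
trigger. Only when such a tone exists are the line, its harmonics (4 by
default, notch half-width 0.03 Hz, at least two FFT bins) and the DC
pedestal removed. Signals with no tonal peak pass through untouched,
preserving transients exactly. Consequences verified by tests: a pure
in-band tone loses ≥ 20 dB; a 1-s rectangular pulse keeps ≥ 70 % of its
peak (≈ 90 % in practice); white noise is essentially untouched; a
rendered respiration-only clip yields zero events while the unfiltered
path would flag tens of thousands of frames.

The filter is nonlinear, so the monotonicity guarantee (raising
`pixel_delta_mm` or `min_area_px` never increases flagged frames) is
strict only on the unfiltered path; `min_area_px` monotonicity holds
always.

## Events and features

Pipeline order is fixed: run-length extraction → merge → REM restriction →
duration binning. Merging before REM restriction avoids fragmenting a
movement that straddles a REM boundary. Two movements are separate only
when the inter-movement gap *exceeds* 1 s (a gap of exactly 1 s merges).
REM membership is decided by event *onset*; durations are not clipped at
the REM boundary (onset is order-independent and simple; the original
pipeline's convention is unknowable from the outside). Bins are half-open
at 2 s and 15 s and closed at 300 s; durations below 0.1 s or above 300 s
are dropped. Features per subject × region × bin:
`rate = events / h REM`, `ratio = event-seconds / h REM` (the fraction of
REM spent moving × 3600). Zero REM time is an error, not a zero.

## Synthetic scene generator

The renderer emulates a ceiling time-of-flight camera: bed plane at
`bed_depth` (2000 mm), body silhouette raised by `body_depth_offset`
(300 mm), per-pixel Gaussian sensor noise (σ = 5 mm), chest respiration
(4 mm at 0.25 Hz by default) and per-event patch displacement (50 mm) —
plausible Kinect-v2-class magnitudes; no movement-amplitude statistics are
published to calibrate against, so these are configurable defaults.
Two rendering details matter for detector semantics:

* an active event *wobbles* between the full and half displacement on
  alternate frames, because a moving limb keeps changing depth — a static
  raised patch would be invisible to consecutive-frame differencing except
  at onset/offset;
* the chest profile is a raised cosine, not a rigid plate, so chest pixels
  cross a detector threshold at staggered times and the respiration area
  signal is smooth and narrowband rather than an all-or-nothing square
  wave.

Planted events are homogeneous Poisson processes within REM per region ×
duration bin, with durations drawn log-uniformly inside the bin (kept
clear of bin edges so ±1-frame detection jitter cannot re-bin an event)
and a minimum gap (default 2 s) so the 1-s merge rule cannot fuse distinct
ground-truth events. Placement is longest-first with per-event rejection,
preserving the drawn Poisson count. Head/hand tracks are emitted per frame
with dropout probability 0.584, reproducing the ~41.6 % hands-detection
coverage of the real external detector. Rendering is deterministic given
the seed.

Hypnograms place `n_rem_periods` contiguous REM blocks (total R time
within one epoch of `total_min × rem_fraction`) among i.i.d. NREM/wake
epochs with proportions W/N1/N2/N3 = 0.08/0.10/0.52/0.30.

**Scale.** Video-path tests render at reduced resolution (64×53 or
128×106) with area thresholds scaled by pixel count; a full night at the
nominal 512×424 is a multi-gigabyte raster and adds nothing to the
contracts being tested. Clips are 10–40 min.

## Cohort sampler

Feature cells are zero-inflated log-normals quantile-matched to the
reference group medians and quartiles of a clinical 53-iRBD vs 128-no-RBD
cohort:

* fully positive cells (`q25 > 0`): zero inflation 0, location
  `ln(median)`, scale `ln(q75/q25) / (2 × 0.67449)`;
* `q25 = 0 < median`: at least a quarter of subjects are zero, so zero
  inflation defaults to 0.25 and the log-normal is matched to the
  conditional quantile levels of the printed median and q75;
* `median = 0`: zero inflation defaults to 0.6 (must be ≥ 0.5 — a
  log-normal cannot reach median 0, and a spec'd error enforces this),
  with the positive tail matched to q75 when printed, or a small
  essentially signal-free tail (`ln 0.5`, σ = 1) for all-zero cells.

Draws are independent across cells by default; an optional shared
per-subject log-normal severity factor induces positive cross-cell
correlation (the joint distribution of a real cohort is unknown). REM
duration per subject is Gaussian (66.1 ± 31.4 min iRBD, 71.3 ± 31.8 min
no-RBD, floored at 10 min) and the SINBAR RWA index is sampled from the
same quantile-matching family (61.4 [48.4, 74.4] % iRBD vs 15.2
[10.7, 23.9] %), clipped to [0, 100].

The no-RBD subgroups (SRBD 51, RLS 20, INS 20, PLMS 12, NREMP 6, NRSD 19)
multiply the pooled no-RBD cells by 1.2 / 1.0 / 0.55 / 1.0 / 1.0 / 0.55
respectively: breathing-disorder patients move most among the negatives
(post-apnea arousal movements), insomnia and no-relevant-disorder sleepers
least, and the mixture median stays close to the pooled cells. This
subgroup structure is a generator choice, not a published fact.

**What passing tests do and do not show.** The sampler reproduces marginal
medians/IQRs per cell; it does not model within-subject correlation
structure, night-to-night variability, age/sex/medication confounding, PAP
tube artifacts or detector-specific noise. Classifier accuracies obtained
on this cohort therefore validate the *pipeline machinery* (no leakage,
correct pooling, sane behaviour at realistic effect sizes), not clinical
performance.

## Classification

Ridge logistic regression minimises the mean negative log-likelihood plus
`(λ/2)‖w‖²` with an unpenalised intercept, solved by damped Newton
iteration to gradient norm < 1e-8 (deterministic; non-convergence is an
error reporting the final gradient norm). The default λ = 0.01 is the
standard mild penalty scale for n ≈ 180 subjects (the `C = 1` sklearn
equivalent); on this objective a λ of order 1 collapses the model to the
intercept. λ is configurable and recorded in result metadata.

Cross-validation: 10 runs × 10 stratified folds (stratification keeps
folds from losing the 29 %-prevalence positive class), run seeds derived
from a base seed via `SeedSequence`. The 5th/95th-percentile normaliser is
fitted per training fold (linear interpolation percentiles); out-of-range
values are not clipped. Metrics are computed per run on pooled out-of-fold
predictions and aggregated as mean ± SD across the 10 runs; per-fold
values are also stored (they are the pairing unit for classifier
comparisons, 100 values per configuration). Ratios with zero denominators
are NaN and excluded from aggregation with a warning, not coerced to 0.
The decision threshold is 0.5. Subgroup performance restricts the pooled
predictions to iRBD ∪ subgroup without retraining.

## Statistics

* **Mann–Whitney U** (two-sided): full permutation enumeration — correct
  under ties — whenever `C(n_a+n_b, n_a) ≤ 200 000`; the classical no-ties
  exact distribution for `n_a·n_b ≤ 400`; otherwise the tie-corrected
  normal approximation with continuity correction.
* **Wilcoxon signed-rank** (two-sided): zero differences dropped; exact
  sign-flip distribution via convolution over doubled midranks (tie-safe)
  for n ≤ 25; normal approximation beyond. All-zero differences return a
  flagged degenerate result (p = 1) rather than an error.
* **Benjamini–Hochberg**: step-up procedure (adjusted p =
  min over j ≥ i of `m·p(j)/j`, capped at 1); families are one per metric
  per experiment.
* **Spearman**: average ranks on ties, t-approximation p; constant input
  is an error.
* **Demographic tables**: Shapiro–Wilk at α = 0.05 per group gates t-test
  (mean ± SD) vs Mann–Whitney (median [IQR]); categoricals use
  continuity-corrected chi-squared, with empty cells flagged.
* **Classifier comparisons** pair the 100 fold-level metric values of two
  configurations under an identical CV plan; mismatched plans are an
  error. Degenerate (identical) pairs never count as rejections.

## Known limitations

* The motion detector is contract-equivalent to, not bit-equivalent with,
  the clinical pipeline it reconstructs; internal thresholds, morphology
  and the original respiration filter are not public.
* Hands are a single pooled region ("one or both hands"); left/right are
  not distinguished.
* No posture changes, blanket physics, PAP-tube artifacts or photoreal
  body shapes in the renderer; events displace fixed rectangular patches.
* The classifier layer deliberately omits alternative models, feature
  selection, calibration curves and ROC analysis.
* Printed-cohort confounder adjustment (age/sex regression) is out of
  scope.
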