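# rbdmotion

Automatic analysis of 3D time-of-flight depth video for screening
**isolated REM sleep behavior disorder (iRBD)**.

iRBD — dream enactment with loss of the normal REM-sleep muscle atonia —
is an early stage of alpha-synucleinopathy, and its objective detection is
a clinical priority. A ceiling-mounted depth camera over the bed records
per-pixel distance images of the sleeping patient at 30 fps; movements
during REM sleep, detected separately in four body regions (head **HE**,
hands **HAs**, upper body **UB**, lower body **LB**), carry enough signal
to separate people with iRBD from patients with other sleep disorders
(sleep-related breathing disorder, RLS, periodic limb movements, insomnia,
NREM parasomnia) and from undiagnosed sleepers.

This package is aimed at sleep-research groups who want a tested,
end-to-end reimplementation of that pipeline that runs on synthetic data
out of the box and on their own depth recordings via simple text formats.

## The method

1. **Motion detection.** Consecutive depth frames are differenced; a pixel
   counts as moving when its depth changes by more than `pixel_delta_mm`.
   Changed pixels are assigned to regions with a precedence rule: when the
   external head/hand detector supplies a valid bounding box, those pixels
   belong to the head/hand regions and are removed from the upper body;
   when the detector drops out, they fall back into the upper-body region.
   Respiration oscillation in the per-region changed-area signal is
   removed with an adaptive spectral notch, and a region is flagged as
   moving when its (filtered) changed area reaches `min_area_px`.

2. **Events and features.** Runs of flagged frames become movement events;
   events separated by at most 1 s are merged; events are kept when their
   onset falls in manually scored REM sleep and assigned a duration bin —
   short [0.1, 2) s, medium [2, 15) s, long [15, 300] s. Per region × bin,

   * **3D rate** = movements per hour of REM sleep,
   * **3D ratio** = seconds of movement per hour of REM sleep
     (full occupancy ⇒ 3600).

3. **Classification.** For a duration bin, the 3D rate and ratio of one of
   seven region sets ({HE}, {HAs}, {UB}, {LB}, {HE,HAs,UB}, {HE,HAs,LB},
   {HE,HAs,UB,LB} — 2, 2, 2, 2, 6, 6, 8 predictors) feed a logistic
   regression with ridge penalty,

   min<sub>w,b</sub> (1/n) Σᵢ log(1 + e<sup>−yᵢ(wᵀxᵢ+b)</sup>) + (λ/2)‖w‖²,

   inside 10 runs of stratified 10-fold cross-validation; each feature is
   rescaled by the training fold's 5th/95th percentiles. Pooled
   out-of-fold predictions give accuracy, F1, sensitivity, specificity,
   PPV and NPV (mean ± SD across runs), plus subgroup performance against
   each differential-diagnosis group without retraining.

4. **Statistics.** Feature tables are compared with Mann–Whitney U tests
   (exact at small n, tie-safe), classifiers with paired Wilcoxon
   signed-rank tests under Benjamini–Hochberg FDR control (q = 0.05), and
   the model's iRBD probability can be correlated (Spearman) with the
   SINBAR REM-without-atonia index.

Because clinical depth video is not publicly distributable, the package
ships a first-class synthetic layer: a depth-scene renderer with planted
ground-truth movements (Poisson processes within REM) and a cohort sampler
drawing feature tables from zero-inflated log-normal distributions
quantile-matched to published group medians/IQRs of a 53-iRBD vs
128-no-RBD clinical cohort.

## Worked example

```python
from rbdmotion import MovementClassifier, default_cohort_spec, sample_cohort_features

cohort = sample_cohort_features(default_cohort_spec(), seed=11)
features = cohort.drop(columns=["rem_hours", "sinbar_index"])
model = MovementClassifier.from_dataframe(features)   # short bin, all four regions
res = model.fit(seed=42)
print(res.summary())
```

```
Cross-validated movement classification (iRBD vs rest)
========================================================
predictors : HE_short_rate, HE_short_ratio, HAs_short_rate, HAs_short_ratio, UB_short_rate, UB_short_ratio, LB_short_rate, LB_short_ratio
duration   : short   regions: HE+HAs+UB+LB
ridge lambda = 0.01, threshold = 0.5
CV         : 10 runs x 10 folds (stratified=True, base_seed=42)
subjects   : 181 (53 positive)
--------------------------------------------------------
metric            mean       sd
accuracy         0.875    0.003
f1               0.772    0.006
sensitivity      0.721    0.012
specificity      0.939    0.005
ppv              0.831    0.010
npv              0.890    0.004
========================================================
```

Short movements in all four regions separate the synthetic iRBD group from
the 128 synthetic controls with ~0.88 accuracy; `res.subgroup_metrics(["INS",
"NRSD"])` recomputes the same pooled out-of-fold predictions against the
quiet control subgroup only (accuracy 0.839 ± 0.007 in this run), and
`rbdmotion.stats.compare_classifiers` tests configurations against each
other with the Wilcoxon/BH machinery.

The video path mirrors the same API at the frame level:

```python
from rbdmotion import SceneConfig, generate_hypnogram, plant_events, render_depth_video, detect_motion

scene = SceneConfig(frame_width=64, frame_height=53, noise_sigma=0.0)
hypno = generate_hypnogram(total_min=30, rem_fraction=0.5, n_rem_periods=1, seed=1)
events = plant_events(hypno, {("LB", "short"): 120.0}, seed=2)
video, tracks = render_depth_video(events, hypno, scene, seed=3)
trace = detect_motion(video, scene.roi_geometry, tracks)
```

A `rbdmotion` console script exposes the same steps
(`simulate-cohort`, `detect`, `featurize`, `classify`, `report`).

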