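# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `mobileqrs` pipeline and of the synthetic data generator
it is validated on.

## Problem setting

A mobile single-lead ECG (ear area or similar) has peak-to-peak amplitude
around 2–5 % of a chest lead and is strongly contaminated by baseline
wander, broadband noise, motion-artifact bursts, and occasional non-cardiac
spikes. The clinical quantity of interest is the QRS duration (ventricular
depolarization time, onset→offset, in ms). The pipeline estimates it
per beat from the mobile lead and maps the estimates onto the chest-lead
scale. All learning is strictly per subject and uses only the training
session; testing applies the frozen model.

## Preprocessing

* Bandpass: 6th-order Butterworth, 2–30 Hz, applied forward–backward
  (`sosfiltfilt`). Zero-phase filtering is essential because the target is a
  *duration*: any phase lag would shift QRS landmarks. The effective
  magnitude response is the square of the single-pass design; tests verify
  measured sine gains against |H(f)|² and a zero cross-correlation lag.
* Sampling rate: the pipeline is rate-agnostic (all duration math in ms);
  500 Hz is the default used throughout the synthetic studies.

## Stage I: heartbeat identification

* **Candidate detection.** Local maxima of |x| above `frac = 0.5` times a
  moving 95th-percentile envelope of |x| (window 2 s), with a 250 ms
  refractory period (larger peak wins). The envelope is evaluated on
  half-window hops and linearly interpolated to sample resolution; a true
  per-sample sliding percentile would cost O(n·w) for no practical gain.
* **Features.** Ten per candidate, mixing amplitude (apex height,
  ±60 ms peak-to-peak), local SNR (apex over ±1 s median absolute signal,
  ±60 ms/±500 ms energy ratio), morphology (half-max width, max slope,
  excess kurtosis, correlation with the running mean of preceding candidate
  windows), and rhythm (previous-candidate interval, its ratio to the
  running median interval). Edge-truncated windows are computed on the
  available samples and flagged.
* **Classifier.** Soft-margin linear SVM (C = 1) on standardized features
  (training mean/SD stored with the model). The decision function is kept
  and evaluated in support-vector form, with sign(0) := +1. The dual is
  solved by scikit-learn; a direct QP solve of the dual is the oracle in the
  test suite. If the training labels are single-class (possible on
  noise-free data where every candidate matches a reference beat), there is
  nothing to discriminate and the pipeline accepts all candidates.
* Training labels come from greedy one-to-one nearest matching of candidates
  to reference R peaks within ±75 ms. Downstream training stages use the
  SVM's *predictions*, not the labels, so training and testing traverse the
  same path.

## Stage II: template learning, multiview DTW, purification

* **Segmentation.** Beats are R-to-R segments `[R_j, R_{j+1})`: the R peaks
  are the only reliably detectable landmarks in the weak signal, so one
  segment holds the *offset* of beat j (near its start) and the *onset* of
  beat j+1 (near its end). Segments are min-max scaled to [0, 1] and
  resampled (linear interpolation) to a common 256 samples. Flat-line
  (saturated) segments are flagged degenerate and kept as placeholders with
  infinite distortion so cross-segment alignment survives.
* **Views.** (1) amplitude; (2) first difference, last value repeated to
  preserve length; (3) local angle: the vertex angle at (i, x[i]) formed
  with the samples ±10 indices away, computed in coordinates where the
  10-sample gap spans one index unit, edges padded with the nearest valid
  angle. Each view is min-max scaled per beat. The derivative and angle
  views emphasize slope and curvature structure that survives amplitude
  distortion.
* **Template.** K-means++-style seeding (first seed uniform; subsequent
  seeds drawn proportionally to the Euclidean distance to the closest chosen
  seed) followed by PAM with best-improvement swaps on the concatenated
  three-view vectors (plain Euclidean distance, K = 3). The medoid of the
  most populous cluster becomes the template (ties: lower within-cluster
  cost, then lower index). Template QRS boundaries are mapped in from a
  boundary-annotated reference track through the resampling ratio. The API
  accepts either chest-referenced or mobile-referenced boundary annotations;
  the synthetic pipeline annotates the mobile medoid with mobile-channel
  truth, because chest-boundary annotation would cancel the lead bias by
  construction and leave Stage III nothing to estimate.
* **Warping.** Local cost d(m,n) = Σₗ (θₗ[m] − Tₗ[n])² (squared, no root),
  standard DTW recurrence over predecessors (m−1,n), (m−1,n−1), (m,n−1), no
  global band. Backtracking prefers the diagonal on ties, then (m−1,n),
  then (m,n−1). Boundary transfer collects all test indices warped onto a
  template boundary column and takes the outer bound (last for the offset,
  first for the onset), widening rather than narrowing the QRS when the path
  runs vertically through a boundary column. The DP fill is a numba-compiled
  loop; an exhaustive path-enumeration oracle checks it on small instances.
* **Purification.** Distortion π = D[M−1,N−1], normalized by the maximum
  training-session distortion (clipped to [0, 1]; the anchor is persisted so
  the threshold transfers to testing). The threshold τ is the center of the
  histogram bin (50 bins over [0, 1]) with maximum perpendicular distance to
  the line from the histogram peak to its rightmost nonempty bin, searched
  between those two bins. η is the order-10 trailing moving average of π
  (shrinking start-up window). SQI = 1 iff π ≤ τ and η ≤ τ; only SQI = 1
  beats contribute durations.
* **Degenerate-distribution guard.** The triangle search presumes a
  left-skewed histogram: a dominant low-distortion mode plus an artifact
  tail. When the *median* normalized training distortion exceeds 0.5 there
  is no low-distortion mode — max-normalization has merely stretched
  quantization-level scatter across [0, 1], which happens exactly in the
  noise-free limit — and no threshold separates quality classes. The
  pipeline then disables purification (τ = 1). On any realistically noisy
  session the median normalized distortion is far below 0.5 and the guard is
  inert.

## Stage III: durations, minutes, calibration, metrics

* Beat j's duration = time(offset in segment j) − time(onset in segment
  j−1), requiring SQI = 1 on both segments; boundary indices are mapped back
  from resampled to original coordinates by rounding. Durations outside
  (0, 300) ms are discarded as warp pathologies.
* Minute estimates are arithmetic means over each trial's evaluation minute;
  empty minutes give NaN and are propagated, never imputed.
* Calibration: additive bias = mean(chest) − mean(mobile) over paired
  non-missing training minutes. Nothing richer is fitted, deliberately:
  a single offset cannot overfit and directly expresses a lead-geometry
  difference. Training mean error after calibration is zero by construction,
  and the Pearson correlation is invariant to the shift; both properties are
  asserted in the suite.
* Metrics: Pearson CR; ME and sample (n−1) STD of pred−ref; MAE;
  RMSE = √(mean e²); Bland–Altman limits ME ± 1.96·STD. Under these
  conventions RMSE² = ME² + STD²·(n−1)/n and RMSE ≥ |ME|; RMSE ≥ MAE is
  *not* asserted (false in general).

## Synthetic data generator

Each heartbeat is a sum of five Gaussian wavelets at the P/Q/R/S/T
characteristic points. For a beat with QRS duration d: Q center −0.25 d
(σ = 0.10 d), R center 0 (σ = 0.11 d), S center +0.30 d (σ = 0.125 d), with
P and T at fixed latencies (−180 ms, +270 ms). Ground-truth boundaries are
defined analytically at two SDs outside the Q and S wavelets: onset
= −0.45 d, offset = +0.55 d from the R peak, so the truth is exact by
construction — the property a recorded dataset cannot offer.

Per-session structure and defaults:

| parameter | default | meaning |
|---|---|---|
| fs | 500 Hz | sampling rate |
| layout | 15 trials × 2 min | per session; two sessions per subject |
| heart rate | 70 bpm ± 3 bpm slow drift; RR jitter SD 20 ms | beat schedule |
| QRS duration | 100 ms mean, 4 ms beat SD, 4 ms slow drift (600 s period) | chest truth |
| lead bias | +8 ms | mobile-minus-chest duration offset |
| mobile scale | 0.03 | ear-lead amplitude relative to chest |
| noise | chest SD 0.005, mobile SD 0.004, wander 0.01 @ 0.33 Hz | additive corruption |
| artifacts | 20 s burst per trial, starting 20 s into the evaluation minute, noise ×8 plus 1–3 Hz shake | motion bursts |
| false spikes | 4 / min, 0.9–1.6 × R amplitude, σ 8–20 ms | non-cardiac transients |

The slow QRS-duration drift emulates exercise-induced modulation across a
session; it is what gives the reference minute means real between-minute
variance, without which a minute-level correlation coefficient would be
measuring nothing. The mobile channel re-synthesizes the same beat schedule
with durations widened by the lead bias, then scales and corrupts it.
Training and testing sessions share the subject-level parameters (rate,
scale, bias) with fresh schedules and noise; everything is bit-reproducible
from one seed.

What the generator does *not* emulate: real ear-lead morphology changes,
electrode impedance drift, respiration coupling, ectopy and conduction
abnormalities, or correlated multi-subject structure. Passing tests
therefore demonstrate correctness of the algorithms under controlled
conditions and graceful behavior under the modeled artifact types — not
clinical performance.

## Numerical and degenerate-input choices

* sign(0) := +1 in the SVM; diagonal-first tie-break in DTW backtracking;
  lower-index tie-breaks in template selection.
* Constant segments: min-max scaling returns zeros plus a degenerate flag
  rather than raising; such beats are excluded from clustering and receive
  infinite distortion.
* τ sits at a bin *center*; the threshold comparison is inclusive (≤) on
  both π and η, so a beat exactly at τ passes.
* Single-class SVM labels → accept-all fallback (see Stage I).
* Problem sizes in the validation suite are chosen for single-CPU runs:
  3-trial subjects for unit-level checks, the full 15-trial default subject
  for the end-to-end recovery and purification checks, and n ≤ 12 / M,N ≤ 8
  instances for the exhaustive clustering and warping oracles.

## Known limitations

* The outer-bound boundary-transfer rule biases durations slightly wide;
  the additive calibration absorbs the constant part of that bias (the
  learned bias on synthetic defaults is ≈ −18 ms: −8 ms of true lead bias
  plus ≈ −10 ms of systematic widening).
* Minute-level CR degrades when between-minute duration variance is small
  relative to residual estimation noise; ME/MAE/RMSE are the more stable
  figures at desk scale.
* The triangle threshold assumes a unimodal low-distortion mode; heavily
  multimodal distortion histograms (e.g. two alternating beat morphologies)
  may purify one mode away.
* No global DTW band: pathological warps are possible for badly corrupted
  beats; they are caught downstream by the distortion threshold and the
  300 ms duration sanity bound rather than prevented.
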