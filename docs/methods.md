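# Methods

## Signal processing

Acceleration is handled in g until the MAD boundary, where the magnitude is
converted with exactly 1 g = 9.81 m/s². The band of interest is 0.5–8 Hz at
a 16 Hz sampling rate, i.e. the upper edge sits exactly at Nyquist. A digital
band-pass cannot place a cutoff at Nyquist, so the design clamps the upper
edge to 99.5 % of Nyquist (7.96 Hz); `FilterSpec.effective_band_hz` exposes
the clamped value and the −3 dB points land on 0.5 Hz and the clamped edge.
Between 0.05 and 6 Hz the designed response tracks the closed-form 5th-order
Butterworth band-pass magnitude to well within 5 %; above ~6.5 Hz bilinear
warping of the Nyquist-adjacent edge makes the comparison meaningless, which
is why response checks probe 0.05–6 Hz.

Filtering is applied per 160-sample batch, forward–backward (zero phase), so
the *applied* steady-state gain is the square of the designed magnitude
response; everything that needs the applied gain (notably the simulator's
amplitude calibration) uses `applied_gain`. Windows are anchored to
contiguous sample runs: a gap larger than 1.5 sample intervals starts a new
run and no window ever spans it. "1-second overlap" is read literally —
consecutive windows share 1 s, stride 9 s (configurable). For time
accounting each window is credited its stride, with the last window of a run
credited its full 10 s, so credits tile the covered time exactly and
posture/walking time percentages close to 100 % of uptime up to the
(≤ 10 s per wear block) uncovered tail.

MAD is computed on the filtered magnitude in m/s² so the 0.02 m/s²
(2 cm/s²) active/idle threshold applies in SI units; the threshold is
inclusive (MAD = 0.02 is active).

## Activity recognition

Seven features per window: population moments (mean, median, variance,
skewness, kurtosis) and the peak of the one-sided power spectrum over
(0, 8] Hz (frequency and power; DC excluded). Zero-variance windows get
skewness/kurtosis 0 rather than NaN so degenerate windows remain
classifiable. The hierarchy is walking-vs-stationary, then the MAD threshold
for active/idle, then a 3-class posture stage; the active/idle split is the
explicit threshold rather than a learned stage because the threshold is part
of the method's definition (a learned binary stage can be plugged in by
algorithm id). The default base learner is a shallow random forest
(60 trees, depth 8) — robust on 7-feature tabular windows; training records
10-fold cross-validated per-class precision/recall/F.

The pipeline trains on a *scripted calibration cohort* (separately seeded,
full wear, walking over-represented at ~8 % of time, postures balanced),
standing in for the dedicated labelled training collection a real deployment
would gather. Free-living draws leave walking so rare (< 1 % of time) that a
classifier trained on them has almost no walking examples.

## Indoor localization

RSSI is clipped (not discarded) to [−100, −50] dBm and median-smoothed per
window — the median is robust to the dropout and body-absorption artifacts
BLE suffers from. Assignment is nearest-beacon by summary RSSI with a
deterministic tie-break (smallest beacon id); windows without observations
are `unknown`, keep their uptime, and are excluded from location-feature
denominators. Canonical aggregation maps bathroom fixtures to `bathroom`,
numbered walls to `wall` and numbered beds to per-room `bed` locations.

## Feature engineering

Energy is windowed MAD on the cm/s² scale accumulated over window minutes;
no attempt is made to calibrate the absolute scale against metabolic units.
Energy intensity divides a state's/location's energy by the minutes spent in
that same state/location (per-state denominators — the convention consistent
with walking intensities far above standing), while energy percentages
divide by the day's total energy; both variants are therefore available.
States that never occur are *absent* (NaN), not zero, so availability counts
can be read off the feature table. The light vs moderate-to-vigorous cutoff
is 90 per-minute intensity units, boundary inclusive upward; it is a
configurable constant. Baseline selection: earliest of the first three days
with ≥ 240 min wear and ≥ 15 min therapy-room wear.

## Synthetic cohort

The generator emulates the study protocol, not a gait laboratory:

* **Wear**: 9 am–6 pm; each day an early removal happens with probability
  0.5 (removal time uniform between 11 am and 6 pm) and an occasional
  15–45 min midday non-wear gap with probability 0.25. Some days therefore
  fall below the 4 h inclusion bar, exercising the exclusion logic.
* **Schedule**: one therapy block per day (~60 ± 10 min, clipped 40–80,
  random morning/afternoon start); the rest of the day is resident-room
  dwells (lognormal, ~6 min median). Posture dwell fractions are drawn per
  patient from group-conditional normals whose defaults are the population's
  community/hospital time-percentage summaries (e.g. laying 46.83 vs 60.99 %);
  walking bouts (30–120 s) occur only while standing and are calibrated to
  the drawn walking share (< 1 % of uptime). Active bouts follow
  posture-dependent propensities (stand 1.0 : sit 0.45 : lay 0.12, rescaled
  to the patient's overall active share) so standing carries the dominant
  energy share at the population level. Therapy dwells are mostly active;
  because the drawn daily active share is spent mainly on the resident day,
  the realized window-level active fraction runs a few points above the
  drawn parameter — a known, documented bias of the waveform path.
* **Accelerometer**: gravity (1 g) along a fixed per-posture wrist
  orientation (laying's dominant axis orthogonal to standing's); dynamic
  movement is a sinusoid collinear with gravity in a posture-specific band
  (stand ≈ 4.2–4.8 Hz, sit ≈ 2.8–3.3 Hz, lay ≈ 0.7–1.1 Hz, walking cadence
  1.6–2.4 Hz inside the filter passband) — the distinct carriers are what
  make postures separable from a wrist magnitude signal. Amplitudes are
  solved per room so the measured room energy intensity matches the
  patient's drawn target (community resident-room mean 43.32, hospital
  26.99, SD 13.06 — a programmed standardized difference of 1.25), through
  the applied filter gain at the carrier; idle windows sit at a 0.8 cm/s²
  MAD floor, white sensor noise is 0.5 mg per axis, and samples clip at
  ±2 g (dynamic amplitudes are capped at 0.95 g to stay inside the range).
* **Beacons**: every beacon advertises on a 250 ms grid; received power
  follows log-distance path loss with exponent 2.0 anchored at −66 dBm at
  1 ft, minus a 15 dB wall penalty across rooms, plus 4 dBm Gaussian noise;
  receptions below −105 dBm are lost. The patient stands 0.2–0.8 m from the
  occupied sublocation's beacon, and beacons are ≥ 1.5 m apart, so the
  occupied beacon has the highest mean RSSI. Multipath, diffraction and
  body-orientation effects are *not* modelled — passing localization tests
  show the rule works under log-distance noise, not under real RF
  propagation.

`simulate_feature_cohort` realises the same per-patient parameter draws
directly as a baseline feature table (plus a 0.5-unit Gaussian measurement
error standing in for windowing noise). Monte-Carlo studies of effect-size
recovery use this path because the sampling distribution of Cohen's d at
n = (145, 9) depends only on the patient-level draws; the waveform path is
exercised end to end on small cohorts.

What passing synthetic tests do **not** show: real wrist kinematics (the
posture carriers are a stylised signature), real RF propagation, true
wear-time distributions (the dropout model is a stand-in, not an inference),
and any absolute energy calibration.

## Statistics

Kruskal–Wallis with tie correction (all-tied input returns H = 0, p = 1);
Pearson chi-square without continuity correction by default (flag exposed);
Spearman correlations with NaN for constant columns. Cohen's d uses the
unweighted average of group variances — with a 145:9 imbalance this is the
convention that reproduces group-summary effect sizes such as 1.51 for
standing time percentage; n-weighted pooling does not. No multiple-testing
correction by default (a Benjamini–Hochberg option exists). Outcome models:
random forest with max_depth 2, random_state 40, class_weight balanced,
stratified 3-fold CV (each fold keeps ≥ 1 hospital case whenever n_H ≥ 3);
sensitivity is the hospital-class recall only, fold summaries are mean and
population SD across the 3 folds; folds whose validation part lacks the
positive class are flagged, never silently dropped.

## Problem sizes and determinism

Default pipeline runs and the test suite use small cohorts (≈ 3–6 patients,
1–3 days) for the waveform path and full study size (145 + 9) only on the
feature-level path; these sizes are the package's defaults, chosen so a
complete run stays desk-scale while every stage is exercised. All randomness
flows from explicit seeds (`numpy` `SeedSequence` spawned per patient, day
and stream), so identical seed + config reproduces identical outputs down to
serialized CSV bytes; the provenance log records seed, config digest and
package version.

## Known limitations

* Posture separation from a wrist magnitude signal is only as good as the
  spectral signatures the simulator plants; on real data sit/stand/lay
  confusion from a wrist sensor is a recognised hard problem.
* The energy scale is internally consistent but uncalibrated; intensities
  are comparable within the package, not across devices or studies.
* The Methods-vs-Results ambiguity in the intensity denominator (uptime vs
  per-state minutes) is resolved in favour of per-state minutes; the uptime
  variant is available as `ei_total` and the energy-percentage features.
* Localization granularity is the beacon grid; sublocation confusion between
  adjacent beacons is expected and only room-level agreement is guaranteed
  by tests.
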