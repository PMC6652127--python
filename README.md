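# rehabsense

Wrist-accelerometer and BLE-beacon analysis of physical activity and indoor
location for older adults in subacute rehabilitation.

Patients in a skilled-nursing rehabilitation stay wear a smartwatch from 9 am
to about 6 pm; stationary Bluetooth low-energy beacons mark the sublocations
of a resident room and a therapy room. From these two streams the package
derives, per patient, a baseline-day profile of *where* the patient was,
*what* they were doing, and *how vigorously* — and asks which of those
features separate patients who return to the community from patients who are
re-admitted to hospital. Because raw clinical sensor recordings of this kind
are not publicly available, the package includes a first-class synthetic
cohort generator that reproduces the wear protocol, so every stage is
testable end to end.

## The method

**Activity quantification.** The triaxial acceleration (16 Hz, ±2 g, gravity
included) is reduced to its signal magnitude
SM = √(accₓ² + acc_y² + acc_z²), band-pass filtered (5th-order Butterworth,
0.5–8 Hz) in 10-second batches of 160 samples (1 s overlap), and each window
is summarised by the mean absolute deviation of the filtered magnitude,

MAD = (1/n) Σ |xᵢ − x̄|,  in m/s².

A window is **active** when MAD ≥ 0.02 m/s² (under constant acceleration at
that threshold, a hand starting at rest moves s = ½at² = 1 m in 10 s),
otherwise **idle**. MAD accumulated over window minutes is the day's
**energy**; step counting is deliberately avoided because this population
walks for well under 1 % of the day.

**Activity recognition.** Seven window features (mean, median, variance,
skewness, kurtosis, peak frequency, peak power) feed a three-stage hierarchy:
walking vs stationary (random forest), active vs idle (the MAD threshold),
and posture — stand / sit / lay (second random forest). Walking always counts
as active.

**Indoor localization.** Beacon RSSI values are clipped to [−100, −50] dBm,
median-smoothed per window, and the window is assigned to the sublocation of
the strongest beacon (calibration anchor: −66 dBm at 1 ft line of sight).
Sublocations aggregate to canonical locations (shower/toilet/sink → bathroom,
numbered walls → wall, numbered beds → bed).

**Features and statistics.** On the baseline day (earliest of the first three
admission days with ≥ 4 h wear and ≥ 15 min therapy-room wear) the package
computes time percentages (minutes/uptime × 100), energy intensities
(energy / minutes in the same state or location) and energy percentages
(state energy / total daily energy × 100) per activity state and location.
Groups are compared with Kruskal–Wallis tests and Cohen's d under
average-variance pooling, d = (m_C − m_H)/√((s_C² + s_H²)/2); outcomes are
modelled with shallow random forests (max_depth 2, random_state 40,
class_weight balanced) under stratified 3-fold cross-validation, reporting
sensitivity of the minority (hospital) class, specificity, accuracy and AUC.

## Worked example

```bash
python examples/group_statistics.py
```

simulates a study-size cohort (145 community, 9 hospital) at the feature
level and prints:

```
          feature  mean_c  mean_h  p_value  cohen_d
 ei_resident_room  44.382  27.182    0.001    1.289
  time_pct_laying  46.144  54.961    0.001   -1.275
  time_pct_active  13.738   8.858    0.007    1.034
time_pct_standing  43.179  35.352    0.009    1.018
  ei_therapy_room  74.145  66.097    0.619    0.270
 time_pct_sitting  10.240   9.935    0.972    0.064

resident-room intensity model (3-fold CV, max_depth 2, random_state 40):
               mean      sd
sensitivity  77.778  15.713
specificity  75.822   5.334
accuracy     75.943   4.173
auc           0.756   0.092

effect size from printed group summaries (standing time %): 1.51
```

Resident-room energy intensity — programmed with a standardized group
difference of 1.25 — comes out on top (estimated d ≈ 1.29 in this draw, p ≈
.001), hospital-bound patients lie down more, and a single-feature forest on
that intensity separates the groups well above chance. Therapy-room
intensity does not discriminate: therapists drive all patients through
similar exercises, so the signal lives in what patients do *on their own*.
The other example scripts (`simulate_patient_day.py`, `process_signals.py`,
`localize_day.py`, `baseline_features.py`) walk through the sensor-level
stages the same way, and the `rehabsense` CLI (`simulate`, `run-all`,
`stats`, `predict`) chains them from the shell.

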