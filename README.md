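# vibrotap

Tactile P300 brain–computer interface (BCI) assessment of **covert command
following** in patients with disorders of consciousness — as a tested,
reusable Python library.

Severely brain-injured patients who show no behavioral response to command
at the bedside (unresponsive wakefulness syndrome, UWS, or minimally
conscious state "minus", MCS−) may still comply with instructions
covertly. A vibrotactile oddball BCI probes this: tactors on the wrists
(and foot) deliver trains of frequent *standard* and rare *deviant*
vibrations, the patient is asked to silently count the deviants on one
wrist, and attention to the counted wrist modulates the P3 event-related
potential (a positive EEG deflection ~300–500 ms after a rare stimulus).
A classifier that detects that modulation turns "can the patient follow
commands?" into a measurable detection rate. `vibrotap` implements the
full workflow for researchers and clinician-engineers who want to study,
calibrate, or extend it — with a synthetic EEG generator standing in for
patient recordings, so every stage is testable end to end.

## What it implements

- **Paradigms** (`vibrotap.paradigm`) — exact-count stimulus schedules:
  VT2 (480 stimuli, left-wrist standards p = 7/8, right-wrist target
  deviants p = 1/8, 300 ms SOA → 2.4 min), VT3 (4 blocks × 15 target +
  15 non-target deviants + 90 foot standards, attended wrist per block),
  and 30 s yes/no communication blocks (attend left = "yes", right = "no").
- **Synthetic sessions** (`vibrotap.simulate`) — 8-channel (Fz, Cz, C3,
  C4, CPz, CP1, CP2, Pz), 256 Hz, microvolt EEG: pink noise + narrowband
  alpha + a parametric P3 (Gaussian bump, centro-parietal topography,
  per-trial compliance) on attended deviants only, plus high-amplitude
  mechanical-artifact bursts. EDF I/O with a tab-separated events sidecar.
- **ERP chain** (`vibrotap.preprocessing`) — 0.1–30 Hz Butterworth
  (order 4, zero-phase by default), epochs from −100 to 600 ms, rejection
  of trials exceeding ±100 μV, 100 ms baseline correction, and
  downsampling of the post-stimulus window to 7 bin means per channel:
  a 56-feature matrix.
- **Decoding** (`vibrotap.decoding`) — shrinkage-regularized LDA
  (Ledoit–Wolf by default); *BCI performance* = percentage of deviant
  (VT2) or target-deviant (VT3) trials detected over held-out folds of a
  seeded stratified 10-fold cross-validation; yes/no answer decoding by a
  label-permutation test on classifier scores, abstaining when not
  significant.
- **Assessment** (`vibrotap.assessment`) — the gated clinical workflow:
  escalate to VT3 only when VT2 performance exceeds 70% (the minimum
  considered sufficient for effective BCI communication) on a recording
  not dominated by mechanical artifacts; conclude covert command
  following when VT3 also reaches threshold; then attempt communication.
- **Cohort statistics** (`vibrotap.group_stats`) — a packaged 12-patient
  table (behavioral and FDG-PET diagnoses, VT2/VT3 performance,
  rejected-trial counts) with median / Tukey-hinge-IQR summaries and a
  tie-corrected Wilcoxon rank-sum comparison of VT2 performance between
  diagnosis groups.

## Worked example

`examples/` holds one short script per capability. The full workflow
(`python examples/04_full_assessment.py`) simulates a strongly responding
subject (8 μV P3, 1 μV noise) and prints:

```
VT2 performance : 100.0% (0 trials rejected)
escalated to VT3: True (artifact flag: False)
VT3 performance : 100.0%
covert command following concluded: True
decoded answers : ['yes', 'no', 'yes', 'no', 'yes', 'no'] (intended: ['yes', 'no', 'yes', 'no', 'yes', 'no'] )
```

VT2 performance is the cross-validated detection rate of right-wrist
deviants; passing the 70% gate triggers the VT3 stage, whose
target-deviant detection rate concludes covert command following; the six
decoded answers match the simulated subject's intent. The cohort script
(`python examples/05_cohort_statistics.py`) reproduces the group
summaries from the packaged table — behavioral grouping: MCS− median
22.5% (IQR 47.5) vs UWS median 10% (IQR 30); metabolic grouping: MCS
median 20% (IQR 15) vs UWS median 10% (IQR 40).

A thin CLI mirrors the library:

```bash
vibrotap paradigm --type vt2 --seed 1 --out events.tsv
vibrotap simulate --paradigm vt2 --seed 1 --out session.edf
vibrotap decode session.edf session_events.tsv --cv 10 --seed 1
vibrotap groupstats --grouping fdgpet
vibrotap demo --out demo_run
```

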