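# Methods

This note documents the models, conventions and design choices behind
`vibrotap`: what is simulated, how the ERP chain and the decoder are
defined, where the design was genuinely open and what was decided, and
what the synthetic benchmark does and does not establish about real
patient data.

## Paradigms

Stimulus schedules are generated with **exact counts**, not i.i.d. draws:
a VT2 run of 480 stimuli contains exactly 60 right-wrist deviants
(fraction 1/8) in a seeded uniform shuffle, and each VT3 block contains
exactly 15 target deviants, 15 non-target deviants and 90 foot standards.
The stated deviant *probabilities* are thus realized as deterministic
proportions; this makes every downstream tally test exact, and matches
the fixed per-block counts of the three-tactor paradigm. The
stimulus-onset asynchrony is 300 ms (30 ms vibration + 270 ms
inter-stimulus interval), fixed without jitter; event *k* starts at
exactly *k*·SOA, so 480 stimuli span 2.4 min. No minimum spacing between
consecutive deviants is imposed (simplest reproducible rule). The 225 Hz
vibration carrier is tactor hardware metadata and is not simulated.

Attended wrists in VT3 are balanced — two left and two right blocks in
seeded random order — so both hands contribute equally to training; the
protocol description requires only "random" assignment, and balance makes
left/right symmetry testable. Communication blocks are 30 s trains with
VT3 statistics: 100 SOA slots per block, ⌊100/8⌋ = 12 deviants per wrist
and 76 standards (1/8 does not divide 100; flooring keeps counts exact
with the remainder assigned to standards). Attending the left wrist means
"yes", the right wrist "no".

## Synthetic EEG

The simulator exists so that the complete chain — including failure modes
— is exercisable without patient recordings. It produces the default
montage (Fz, Cz, C3, C4, CPz, CP1, CP2, Pz) at 256 Hz in microvolts,
mastoid reference treated as already applied, 1 s padding around the
schedule. The signal model is the minimal one containing exactly the
structure the decoder exploits:

- **Background**: seeded pink (1/f) noise per channel
  (`noise_sd_uv`, default 5 μV SD), plus a narrowband 8–12 Hz alpha
  rhythm (`alpha_amplitude_uv`, default 2 μV peak-equivalent). Alpha is
  band-limited Gaussian noise rather than a sinusoid on purpose: the
  300 ms SOA spans exactly three cycles of 10 Hz, so a fixed sinusoid
  would be phase-locked to stimulus onset and would survive trial
  averaging, which real (non-stimulus-locked) alpha does not.
- **Evoked response**: every *attended* deviant elicits, with probability
  `compliance` (default 1; models vigilance fluctuation), an additive
  positive Gaussian bump of peak `p3_amplitude_uv` (default 5 μV; 0 =
  non-responder) at `p3_latency_s` (default 0.35 s, inside the canonical
  300–500 ms window) with SD `p3_width_s` (default 60 ms), scaled per
  channel by a centro-parietal topography (gain 1.0 at CPz, 0.9 at
  Cz/Pz, down to 0.4 laterally). Unattended deviants and standards evoke
  nothing: early somatosensory components common to all stimuli are
  deliberately absent, because the decoder only uses what *differs*
  between classes.
- **Artifacts**: square bursts of 300 μV (three times the rejection
  threshold) lasting 200 ms, inserted at a Poisson rate
  (`artifact_rate_per_min`, default 0.5/min), emulating the mechanical
  contamination that forced one cohort recording to lose all 480 trials.

Everything is driven by one explicit seed per call; there is no global
random state, and identical (schedule, profile, seed) triples give
bit-identical recordings.

**What passing tests on this model show — and what they do not.** The
synthetic benchmark establishes that the chain is *correct*: it recovers
a planted attention-modulated response, abstains at the calibrated rate
when none exists, and degrades monotonically with SNR. It does not
establish clinical sensitivity or specificity: real EEG has
somatosensory evoked potentials on every stimulus, ocular/EMG artifacts
with structure, non-stationary vigilance, electrode drift and mains
interference, none of which are modeled. Null-calibration results
transfer only to the extent that real noise is exchangeable across
deviants and standards after filtering and rejection.

## ERP chain

Fixed order: band-pass → epoch → reject → baseline → features.

- **Filter**: Butterworth band-pass 0.1–30 Hz, order 4, applied
  forward–backward by default (zero phase; squares the magnitude
  response). The bedside system is presumably causal; offline, zero-phase
  filtering preserves component latencies. A `zero_phase=False` /
  `--causal` switch restores the single-pass behavior.
- **Epochs**: −100 to 600 ms around onset is realized at 256 Hz as 25
  pre-onset samples (≈97.7 ms — 100 ms is not representable exactly) and
  154 post-onset samples (onset sample + 153, ≈601.6 ms). 154 was chosen
  over the ±1-sample alternatives because it divides exactly into the 7
  downsampling bins of 22 samples. Events whose window crosses a
  recording edge are kept but flagged rejected with reason `edge`.
- **Rejection**: an epoch is rejected when its absolute value exceeds
  100 μV on any channel at any sample. "Amplitude exceeding 100 μV" is
  read as absolute value, not peak-to-peak — the simplest literal
  reading; the threshold is a parameter, and rejected epochs keep their
  data under the mask so nothing is silently dropped.
- **Baseline**: per epoch and channel, subtract the mean of the 25
  pre-onset samples.
- **Features**: the 154 post-onset samples are averaged in 7 consecutive
  bins of 22 (boxcar downsampling — robust to noise and standard in P3
  BCIs; decimation would be noisier), ordered channel-major: 7 × 8 = 56
  features. Only non-rejected trials contribute rows.

## Decoding

Pooled-covariance LDA on the 56 features. With roughly 54 deviant
training trials per cross-validation fold, the pooled covariance is
near-singular, so **shrinkage toward the scaled identity is on by
default** (Ledoit–Wolf analytic estimate; a scalar in [0, 1] can be
fixed, and shrinkage 0 demands a well-posed covariance or raises).

**Performance** is the percentage of positive-class trials (deviants in
VT2; target deviants in VT3, against non-target deviants and standards
pooled) classified as positive on held-out folds of a seeded, stratified
10-fold cross-validation — i.e. held-out sensitivity, in [0, 100].
Stratification keeps the rare class in every fold; whether the original
system stratified is unknown. Tie scores classify as non-deviant
(deterministic tie-break). Class priors default to **empirical** (1:7):
absent signal, the prior-weighted discriminant detects almost nothing,
which reproduces the near-zero null scores typical of non-responders;
`priors="equal"` is available and moves chance-level sensitivity toward
50%.

**Answer decoding** for a communication block: the statistic is the mean
classifier score over left-wrist deviant epochs minus the right-wrist
mean; its two-sided permutation null (≥999 shuffles of the wrist labels)
gives a p-value, and the block abstains ("none") unless p ≤ α (default
0.05). The original system's abstention rule is unpublished; a
calibrated permutation test is the package's own choice, with the
abstention rate under the null verified by simulation. Attended-wrist
*recovery* (no abstention) uses the same score difference with
leave-one-block-out training.

## Assessment workflow

VT3 is attempted only when VT2 performance is **strictly above 70%** —
the threshold regarded as the minimum for effective BCI communication —
and the recording is not artifact-dominated. The bedside judgment
"without mechanical artifacts" has no published numeric rule; it is
operationalized as a ceiling on the rejected-trial fraction (default
50%), which correctly quarantines a run with all 480 trials rejected
regardless of its nominal score. At the VT3 stage the threshold is
applied **inclusively** (≥ 70%), because a VT3 run of exactly 70% was
clinically classified as covert command following; the two stages'
conventions are deliberately different and both configurable. If every
trial is rejected, performance is undefined (NaN) and the gate cannot
pass. Communication is attempted only after a completed VT3, with the
LDA trained on the full VT3 session. The outcome is a pure function of
inputs, config and seeds; re-running a config reproduces the report
byte for byte.

## Cohort statistics

The packaged table carries the 12-patient cohort: 4 MCS− / 8 UWS by
behavioral (CRS-R) diagnosis, 6 MCS / 6 UWS by FDG-PET, with VT2/VT3
performance and rejected-trial counts. Group summaries use the median
and the **Tukey-hinge IQR** (hinges = medians of the sorted halves,
halves including the overall median for odd n). Among the common
quartile conventions this is the one under which all four group IQRs of
the cohort come out as the round values quoted with it, so the module
standardizes on it. The Wilcoxon rank-sum test uses midranks,
tie-corrected variance and the normal approximation, without continuity
correction by default (a flag enables it); it is validated against an
exact-permutation oracle and scipy's asymptotic Mann–Whitney. The Z
values this yields on the cohort (≈1.3 for the behavioral grouping) are
reported as computed; they are **not** forced to agree with any
previously quoted test statistics, whose exact computation is unknown.
FDG-PET image processing itself is out of scope — the scan enters only
as a per-patient diagnosis label. Disease-duration columns are carried
as data but are summarized nowhere, as their published group summaries
are internally inconsistent.

## I/O and problem sizes

Continuous data use classic EDF (ASCII header, 16-bit samples in 1 s
records, symmetric physical range derived from the data → quantization
step = range/65535; recordings are zero-padded to whole records).
Writing is a small self-contained encoder; reading goes through MNE,
which doubles as an independent check on the writer. Events travel in a
BIDS-style tab-separated sidecar (onset, duration, trial_type, site,
is_target, block). Reports are single self-describing JSON files
embedding seeds and the config hash.

The acceptance script simulates full-length sessions (480 stimuli,
146 s) throughout; the null calibration uses 200 independent sessions
and wrist recovery 25 VT3 sessions (100 blocks), sizes at which the
binomial uncertainty of the reported rates is a few percent. Unit tests
use shorter runs (32–160 stimuli) where only correctness, not
statistical power, is at stake.

## Known limitations

- The P3 is the only evoked component; real somatosensory responses on
  standards would lower decodable contrast at fixed amplitude.
- The mechanical artifact's real waveform is unknown; generic square
  bursts only ensure the rejection and gating logic is exercised.
- Epoch timing quantizes stimulus onsets to the 256 Hz grid (≤ 2 ms
  error); the simulator places bumps in continuous time, so sub-sample
  jitter of that size is inherent.
- The non-integer-second EDF tail is zero-padded on write and not
  truncated on read.
- With empirical priors, "performance" is a sensitivity against a
  prior-weighted decision rule; comparisons across priors modes are not
  meaningful.
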