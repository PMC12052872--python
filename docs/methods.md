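# Methods

This note documents the measurement model implemented by `emgchrono`,
the choices made where the procedure was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Signal model and preprocessing

The input is a two-channel surface EMG recording (one channel per
response hand, thenar eminence) at a known sampling rate (default
1000 Hz), plus a per-trial event table (stimulus onset, press time or
no-response, responding and correct hand, instruction condition,
lexicality).  Amplitudes are treated as microvolts; every detection
step is scale-invariant, so the unit only matters for the reported
curve-amplitude metric.

Preprocessing applies a 10-Hz order-2 Butterworth high-pass and a 50-Hz
notch (second-order IIR, −3 dB bandwidth 2 Hz) to the continuous signal
before epoching.  The high-pass runs forward–backward (zero-phase) so
that burst onsets are not delayed; its effective magnitude response is
the squared single-pass response.  The notch, in contrast, runs
**causally** by default: a Q = 25 notch rings for roughly 160 ms, and a
zero-phase pass smears the burst's 50-Hz energy backward by over
100 ms.  Measured at study-typical burst amplitudes this backward leak
is ≈2.4 µV RMS at 100 ms before the true onset — enough to cross the
activity threshold in rectified peaks spaced ~10 ms apart, which the
<25-ms merge rule then chains into spurious windows starting far before
the burst.  A causal notch removes this failure mode at the cost of a
sub-millisecond group delay away from 50 Hz.  Both phase modes are
configurable (`zero_phase`, `notch_zero_phase`).

Stimulus-locked epochs span −500 ms to the condition's response
deadline + 1000 ms (neutral 2500, speed 1800, accuracy 6000 ms
post-stimulus), so the slowest admissible response's burst is fully
contained.  Epochs that would overrun the recording are flagged and
excluded per trial, never fatally.

## Onset detection: the integrated profile

For a rectified segment `x`, the integrated profile is
`c_i = Σ_{j≤i} |x_j|`; subtracting the chord
`L_i = c_0 + (c_{n−1} − c_0) · i/(n−1)` yields a curve that drifts
downward at rate (local mean − segment mean) while the channel is
quiescent and turns upward inside the burst.  The onset is the index of
the global minimum, ties broken toward the earliest index.  Two
consequences are documented rather than patched:

* on an ideal step the argmin lands on the *last quiescent* sample, a
  bias of at most one sample toward early;
* the argmin of a weakly-drifting noisy profile is a random-walk
  minimum, so precision degrades as the burst's share of the segment
  shrinks (long epochs, low SNR).  At the default synthetic SNR the
  per-trial onset error is ~2 ms median, ~4 ms SD.

The profile is evaluated over the full epoch including the baseline
(restrictable via a span argument).  A segment whose profile-minus-
chord difference is identically zero (constant rectified amplitude) has
no defined onset and raises a degenerate-input error.

## Activity windows and automatic validity screening

Per channel and epoch, the detection threshold is
`mean(|x|) + 3.5 · SD(|x|)` over the [−500, 0) ms baseline (SD with
denominator n−1).  Window construction applies, in fixed order:
maximal supra-threshold runs → merge runs separated by gaps strictly
shorter than 25 ms → discard merged windows shorter than 50 ms →
discard windows starting at or after the press.  "Shorter than" is
read strictly: a gap of exactly 25 ms does not merge.

The original protocol validated onsets by visual inspection; here a
reproducible criterion replaces it: an onset is valid iff it falls
within `[start − 10 ms, end)` of the **last** retained window before
the press.  The 10-ms tolerance absorbs the ≤1-sample argmin bias and
the stochastic lag between the physiological onset and the first
supra-threshold sample.  Reason codes (`no_window`,
`onset_outside_last_window`) are recorded per trial and excluded trials
are exported for optional human review.  At default settings ~1–3% of
epochs are excluded, matching the ~2% loss the visual protocol
reported.

Covert activations are windows surviving the same rules on the
non-responding channel.  Their latency is the integrated-profile onset
of a local segment from 50 ms before the window start (quiescent
context for the profile) to the window end.  A covert window on a
correctly-ended trial is a partial error; on an overt-error trial, a
partial correct.

## Trial classes and chronometry

`PMT = onset_ms`, `MT = RT − onset_ms`; both must be strictly positive,
otherwise the trial is excluded (`onset_after_rt`,
`onset_before_stimulus`).  Each trial receives exactly one class:
pure_correct / partial_error_trial / overt_error / partial_correct_trial
/ no_response / excluded.  No-response trials are a class of their own,
not errors (deadline misses plausibly arise from a different generative
process); a config switch re-counts them as errors for sensitivity
analyses.  Chronometric means and EMG curves use pure-correct trials
with validated onsets only; accuracy-type analyses use every responded
trial, since correctness needs no EMG.

## Conditional functions and summaries

Quantile binning is rank-based equal-count: the trial of 0-based rank
`r` among `n` goes to bin `⌊r·K/n⌋ + 1` (K = 5 by default), ties broken
by stable input order.  This is the standard CAF construction; it makes
the functions invariant to monotone latency transforms and keeps bin
sizes within one trial of each other.  The CIAF event set pools every
overt response (latency = RT, flagged if erroneous) with one event per
partial error (latency = covert onset, always flagged), so corrected
impulses surface at the latency where they occurred.

Rates per cell: partial-error rate = partial / (partial + pure
correct); correction likelihood = partial / (partial + overt errors,
including partial-correct trials).  Cells with fewer trials than bins
are skipped with a warning, undefined rates are reported missing.

Within-participant CI half-widths use the two-step Cousineau–Morey
procedure: per-participant centering plus grand mean, per-condition SE
of the normalized scores, multiplied by `√(J/(J−1))` for J conditions,
times the two-sided t quantile at n−1 df.  Bayes factors from BICs use
`BF(a over b) = exp((BIC_b − BIC_a)/2)`; values below 1 favour model b.
Mixed-model fitting itself is out of scope: the pipeline exports a
model-ready long table with centred-quantile and orthonormal
linear/quadratic quantile contrasts for external fitting.

## EMG curves

Onset-locked segments (lags −500…+1000 ms) of pure-correct trials are
rectified, then averaged per participant × condition, ignoring
pad-masked lags where the source epoch ended early.  Rectification
before averaging is deliberate: motor-unit phase varies across trials,
so a signed mean would cancel; a config switch provides the signed
variant.  The amplitude metric is the mean of the curve from lag 0 to
the first post-peak sample at or below 30% of the absolute peak (peak
searched at lags ≥ 0); a curve that never returns uses its full span
and carries a `no_return` flag.  The slope metric is the OLS
coefficient of amplitude on lag over 0–30 ms inclusive (31 samples at
1 kHz), in µV/ms.  Note the curve at lag 0 sits near the detection
threshold, not near zero or near the peak — an expected property of
onset-locked averages of rectified noise-driven bursts.

## Synthetic data generator

The generator exists so every stage is testable against ground truth
without recordings.  It emulates the 3 (SAT) × 2 (lexicality) design
with per-condition deadlines (1500/800/5000 ms) and renders, per trial:

* baseline Gaussian noise (default SD 2 µV) on both channels;
* a responding-hand burst: 20–250 Hz band-limited noise carrier under a
  raised-cosine rise (15 ms) / plateau (until press + 20 ms) /
  raised-cosine decay (80 ms) envelope, carrier SD 25× baseline at the
  plateau.  The 15-ms rise and 25× gain reflect ballistic thenar
  button-press bursts, which reach a full interference pattern within
  ~10–20 ms at 20–40× baseline RMS; at substantially slower or weaker
  settings the integrated profile degrades in ways incompatible with
  the ~2% exclusion rate the emulated protocol achieved;
* PMT and MT drawn from log-normal distributions parameterized by cell
  mean and SD (PMT SD 90 ms, MT SD 20 ms — typical within-participant
  lexical-decision spreads).  Cell means follow the additive pattern
  PMT: 524.27 + 61.64·pseudoword + 172.41·accuracy − 94.87·speed ms;
  MT: 132.59 + 5.94·pseudoword + 23.07·accuracy − 24.37·speed ms.
  Participant random intercepts (SD 30 / 8 ms) shift both; condition
  effects carry no random slopes — the generator emulates the design's
  mean structure, not its full covariance;
* accuracy per cell from the additive log-odds pattern 3.95 +
  0.27·pseudoword + 0.84·accuracy − 1.14·speed; overt errors swap the
  responding hand, and with mixture weight 0.5 draw their PMT from a
  component shifted 150 ms earlier (fast, impulsive errors — the
  mechanism that loads the first CIAF quantile under speed);
* with probability 0.05, a correct trial carries a partial error: a
  100-ms burst on the incorrect channel at half the press gain,
  starting 50–200 ms before the correct-hand onset.  Overt-error trials
  carry the mirror-image partial correct with conditional probability
  0.25, yielding ≈1% of all trials — the rate is parameterized
  conditionally because overt errors are only a few percent of trials;
* a trial whose programmed RT exceeds the deadline becomes a
  no-response trial and its burst is suppressed.

Ground truth (programmed PMT/MT/RT, onset sample, error and covert
flags and latencies) is returned alongside; `RT = PMT + MT` holds
exactly.  Identical seeds reproduce recordings bitwise.

What the generator does **not** emulate: tonic background activity and
its acquisition-time feedback, motor-unit structure (the carrier is
noise, not action-potential trains), amplitude drift, movement
artifacts, electrode noise spectra, line-noise contamination, trial
history effects, and any lexical processing model (latencies are drawn,
not accumulated).  Passing recovery tests therefore demonstrates that
the measurement chain is correct under its stated signal model — not
that it is robust to every artifact class of real recordings, which is
exactly what the review export and configurable thresholds are for.

## Problem sizes and tolerances in the test suite

The suite validates the algorithmic core exactly (brute-force oracles
for the profile argmin and the window rules; closed forms for the curve
metrics, Bayes factor and Morey CIs) and the chain statistically:
chronometric conservation on a 5,040-trial run; programmed-effect
recovery (±3 ms) at 40 participants × 100 trials/cell; partial-error
sensitivity ≥ 0.90 with false alarms ≤ 0.02 at 3,000 trials; CIAF
fast-error enrichment at 400 events per speed cell.  These sizes keep
the Monte-Carlo error of each check well inside its tolerance while the
full suite runs in a couple of minutes.  The acceptance script uses 12
participants × 60 trials/cell for the same reason.

## Known limitations

* The integrated profile has no explicit noise model; its random-walk
  minimum makes single-trial onsets on very long, low-SNR epochs
  unreliable (mitigated, as in the emulated protocol, by the
  last-window validity check).
* The onset search spans the full epoch by default; strong pre-stimulus
  activity can capture the minimum (such epochs fail validation).
* Speed-condition cell means are computed from within-deadline
  responses only, so the deadline right-censors slow trials and the
  estimated speed effects exceed the programmed shifts by several
  milliseconds — a property of the design, not an estimator defect.
* Equal-count quantile binning is one of several CAF conventions; with
  heavy ties the stable-order assignment is deterministic but
  arbitrary.
* The Bayes-factor approximation inherits the BIC's unit-information
  prior; it is a summary device, not a substitute for model comparison.
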