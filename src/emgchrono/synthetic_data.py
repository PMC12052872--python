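"""Synthetic two-channel EMG recordings with known ground truth.

The generator emulates a two-choice lexical-decision experiment run under
three speed–accuracy instruction regimes (neutral / accuracy / speed,
with 1500 / 5000 / 800 ms response deadlines) crossed with stimulus
lexicality (word / pseudoword).  For every trial it draws a premotor time
(PMT) and a motor time (MT) from log-normal distributions whose cell
means follow the additive effect pattern of the reference design
(PMT: base 524.27 ms, pseudoword +61.64, accuracy +172.41, speed −94.87;
MT: base 132.59 ms, pseudoword +5.94, accuracy +23.07, speed −24.37) and
renders the responding hand's channel as baseline Gaussian noise plus a
burst — band-limited noise carrier under a smooth rise–plateau–decay
envelope — starting at the PMT and lasting until just past the press.

Accuracy follows a per-cell logistic pattern; overt errors swap the
responding hand and, with the fast-error mixture weight, draw their PMT
from a left-shifted component (impulsive errors).  With probability
``p_partial_error`` a correct trial additionally carries a short,
sub-press-amplitude burst on the incorrect hand starting 50–200 ms before
the correct burst (a partial error); overt-error trials can carry the
mirror-image covert correct-hand burst (a partial correct).  Trials whose
RT exceeds the condition deadline become no-response trials and their
burst is suppressed.  Every trial's programmed PMT/MT/RT, flags and
covert latency are returned as a ground-truth table, with
``RT = PMT + MT`` holding exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_formats import (
    DEADLINE_MS,
    EPOCH_POST_MS,
    EPOCH_PRE_MS,
    HANDS,
    LEXICALITIES,
    SAT_CONDITIONS,
    ContinuousRecording,
    ValidationError,
    write_events,
    write_recording,
    write_table,
)

TRUTH_COLUMNS = [
    "participant", "trial", "sat", "lexicality", "correct_hand",
    "responding_hand", "true_pmt_ms", "true_mt_ms", "true_rt_ms",
    "true_onset_sample", "overt_error", "fast_error", "partial_error",
    "partial_latency_ms", "partial_correct", "no_response",
]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic experiment (defaults = study pattern)."""

    n_participants: int = 8
    trials_per_cell: int = 40
    sampling_rate: int = 1000
    baseline_sd: float = 2.0            # µV, quiescent-channel noise SD

    # burst rendering
    burst_gain: float = 25.0            # carrier SD at plateau, × baseline_sd
    burst_rise_ms: float = 15.0
    burst_plateau_after_press_ms: float = 20.0
    burst_decay_ms: float = 80.0
    carrier_band_hz: tuple = (20.0, 250.0)

    # chronometric structure (ms); effects are additive over the base
    pmt_base_ms: float = 524.27
    pmt_lexicality_ms: float = 61.64
    pmt_accuracy_ms: float = 172.41
    pmt_speed_ms: float = -94.87
    pmt_sd_ms: float = 90.0
    mt_base_ms: float = 132.59
    mt_lexicality_ms: float = 5.94
    mt_accuracy_ms: float = 23.07
    mt_speed_ms: float = -24.37
    mt_sd_ms: float = 20.0
    participant_pmt_sd_ms: float = 30.0
    participant_mt_sd_ms: float = 8.0

    # accuracy structure (log-odds of a correct press)
    acc_logit_base: float = 3.95
    acc_logit_lexicality: float = 0.27
    acc_logit_accuracy: float = 0.84
    acc_logit_speed: float = -1.14

    # error and covert-activation mixture
    fast_error_weight: float = 0.5
    fast_error_shift_ms: float = 150.0
    fast_error_sd_ms: float = 40.0
    p_partial_error: float = 0.05
    p_partial_correct_given_error: float = 0.25
    partial_gain_fraction: float = 0.5
    partial_duration_ms: float = 100.0
    partial_rise_ms: float = 15.0
    partial_decay_ms: float = 30.0
    partial_lead_lo_ms: float = 50.0
    partial_lead_hi_ms: float = 200.0

    # continuous-recording layout
    pre_gap_ms: float = 600.0
    post_gap_ms: float = 400.0

    sat_conditions: tuple = SAT_CONDITIONS
    lexicalities: tuple = LEXICALITIES

    def __post_init__(self):
        probs = [self.p_partial_error, self.p_partial_correct_given_error,
                 self.fast_error_weight]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        for sat in self.sat_conditions:
            if self.pmt_mean(sat, "word") <= 0 or self.mt_mean(sat, "word") <= 0:
                raise ValidationError("PMT/MT cell means must be positive")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")

    # -- cell-level structure ------------------------------------------------

    def pmt_mean(self, sat: str, lexicality: str) -> float:
        return (self.pmt_base_ms
                + (self.pmt_lexicality_ms if lexicality == "pseudoword" else 0.0)
                + (self.pmt_accuracy_ms if sat == "accuracy" else 0.0)
                + (self.pmt_speed_ms if sat == "speed" else 0.0))

    def mt_mean(self, sat: str, lexicality: str) -> float:
        return (self.mt_base_ms
                + (self.mt_lexicality_ms if lexicality == "pseudoword" else 0.0)
                + (self.mt_accuracy_ms if sat == "accuracy" else 0.0)
                + (self.mt_speed_ms if sat == "speed" else 0.0))

    def error_probability(self, sat: str, lexicality: str) -> float:
        logit = (self.acc_logit_base
                 + (self.acc_logit_lexicality if lexicality == "pseudoword" else 0.0)
                 + (self.acc_logit_accuracy if sat == "accuracy" else 0.0)
                 + (self.acc_logit_speed if sat == "speed" else 0.0))
        return float(1.0 - 1.0 / (1.0 + np.exp(-logit)))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("carrier_band_hz", "sat_conditions", "lexicalities"):
            d[key] = list(d[key])
        return d


def _lognormal(rng: np.random.Generator, mean: float, sd: float,
               size=None) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _envelope(n_rise: int, n_plateau: int, n_decay: int) -> np.ndarray:
    """Raised-cosine rise, flat plateau, raised-cosine decay (0..1..0)."""
    rise = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / max(n_rise, 1)))
    decay = 0.5 * (1 + np.cos(np.pi * np.arange(1, n_decay + 1) / max(n_decay, 1)))
    return np.concatenate([rise, np.ones(n_plateau), decay])


def _carrier(rng: np.random.Generator, n: int, band: tuple, rate: float
             ) -> np.ndarray:
    """Unit-SD band-limited noise carrier for burst rendering."""
    white = rng.standard_normal(n)
    if n < 30:
        return white
    low, high = band
    high = min(high, 0.45 * rate)
    sos = sps.butter(4, (low, high), btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else white


@dataclass
class _TrialPlan:
    """Programmed latent variables for one trial (pre-rendering)."""

    sat: str
    lexicality: str
    correct_hand: str
    responding_hand: str
    pmt: float
    mt: float
    overt_error: bool
    fast_error: bool
    partial_error: bool
    partial_latency: float
    partial_correct: bool
    no_response: bool

    @property
    def rt(self) -> float:
        return self.pmt + self.mt


def _plan_trial(spec: GeneratorSpec, sat: str, lexicality: str,
                rng: np.random.Generator,
                pmt_shift: float = 0.0, mt_shift: float = 0.0) -> _TrialPlan:
    correct_hand = HANDS[rng.integers(2)]
    overt_error = rng.random() < spec.error_probability(sat, lexicality)
    fast = False
    pmt_mean = spec.pmt_mean(sat, lexicality) + pmt_shift
    if overt_error and rng.random() < spec.fast_error_weight:
        fast = True
        pmt = float(_lognormal(rng, max(pmt_mean - spec.fast_error_shift_ms, 120.0),
                               spec.fast_error_sd_ms))
    else:
        pmt = float(_lognormal(rng, pmt_mean, spec.pmt_sd_ms))
    mt = float(_lognormal(rng, spec.mt_mean(sat, lexicality) + mt_shift,
                          spec.mt_sd_ms))
    responding = correct_hand if not overt_error else (
        "left" if correct_hand == "right" else "right")
    no_response = (pmt + mt) > DEADLINE_MS[sat]

    partial_error = partial_correct = False
    partial_latency = np.nan
    if not no_response:
        if not overt_error and rng.random() < spec.p_partial_error:
            partial_error = True
        elif overt_error and rng.random() < spec.p_partial_correct_given_error:
            partial_correct = True
        if partial_error or partial_correct:
            lead = rng.uniform(spec.partial_lead_lo_ms, spec.partial_lead_hi_ms)
            partial_latency = float(np.clip(pmt - lead, 30.0, pmt - 10.0))
    return _TrialPlan(sat=sat, lexicality=lexicality, correct_hand=correct_hand,
                      responding_hand=responding, pmt=pmt, mt=mt,
                      overt_error=overt_error, fast_error=fast,
                      partial_error=partial_error,
                      partial_latency=partial_latency,
                      partial_correct=partial_correct, no_response=no_response)


def _render_burst(signal: np.ndarray, col: int, onset_sample: int,
                  mt_ms: float, gain: float, spec: GeneratorSpec,
                  rng: np.random.Generator) -> None:
    rate = spec.sampling_rate
    per_ms = rate / 1000.0
    n_rise = int(round(spec.burst_rise_ms * per_ms))
    n_plateau = max(int(round((mt_ms + spec.burst_plateau_after_press_ms)
                              * per_ms)) - n_rise, 0)
    n_decay = int(round(spec.burst_decay_ms * per_ms))
    env = _envelope(n_rise, n_plateau, n_decay)
    end = min(onset_sample + env.size, signal.shape[0])
    span = end - onset_sample
    if span <= 0:
        return
    carrier = _carrier(rng, span, spec.carrier_band_hz, rate)
    signal[onset_sample:end, col] += gain * env[:span] * carrier


def _render_partial(signal: np.ndarray, col: int, onset_sample: int,
                    spec: GeneratorSpec, rng: np.random.Generator) -> None:
    per_ms = spec.sampling_rate / 1000.0
    n_rise = int(round(spec.partial_rise_ms * per_ms))
    n_decay = int(round(spec.partial_decay_ms * per_ms))
    n_plateau = max(int(round(spec.partial_duration_ms * per_ms))
                    - n_rise - n_decay, 0)
    env = _envelope(n_rise, n_plateau, n_decay)
    end = min(onset_sample + env.size, signal.shape[0])
    span = end - onset_sample
    if span <= 0:
        return
    carrier = _carrier(rng, span, spec.carrier_band_hz, spec.sampling_rate)
    gain = spec.partial_gain_fraction * spec.burst_gain * spec.baseline_sd
    signal[onset_sample:end, col] += gain * env[:span] * carrier


def generate_trial(spec: GeneratorSpec, sat: str, lexicality: str,
                   rng: np.random.Generator):
    """One epoch-length trial: ``(signal, event_row, truth_row)``.

    `signal` spans the stimulus-locked epoch ``[-500, post_ms)`` with the
    stimulus at sample 500 (at 1 kHz); event and truth rows are dicts in
    the events / ground-truth table layouts with ``stimulus_onset_ms``
    left at the epoch-relative value 0 (datasets re-base it).
    """
    plan = _plan_trial(spec, sat, lexicality, rng)
    rate = spec.sampling_rate
    per_ms = rate / 1000.0
    n = int(round((EPOCH_PRE_MS + EPOCH_POST_MS[sat]) * per_ms))
    signal = rng.standard_normal((n, 2)) * spec.baseline_sd
    _fill_trial_signal(signal, plan, spec, rng, pre_samples=int(EPOCH_PRE_MS * per_ms))
    event, truth = _trial_rows(plan, spec, participant="sim", trial=0,
                               stimulus_onset_ms=0.0)
    return signal, event, truth


def _fill_trial_signal(signal: np.ndarray, plan: _TrialPlan,
                       spec: GeneratorSpec, rng: np.random.Generator,
                       pre_samples: int) -> None:
    """Add programmed bursts to a noise-filled stimulus-locked span."""
    col = {"left": 0, "right": 1}
    if not plan.no_response:
        onset = pre_samples + int(round(plan.pmt * spec.sampling_rate / 1000.0))
        _render_burst(signal, col[plan.responding_hand], onset, plan.mt,
                      spec.burst_gain * spec.baseline_sd, spec, rng)
        if plan.partial_error or plan.partial_correct:
            covert_hand = (plan.correct_hand if plan.partial_correct
                           else ("left" if plan.correct_hand == "right" else "right"))
            ponset = pre_samples + int(round(plan.partial_latency
                                             * spec.sampling_rate / 1000.0))
            _render_partial(signal, col[covert_hand], ponset, spec, rng)


def _trial_rows(plan: _TrialPlan, spec: GeneratorSpec, participant, trial,
                stimulus_onset_ms: float) -> tuple[dict, dict]:
    event = {
        "participant": participant,
        "trial": trial,
        "stimulus_onset_ms": stimulus_onset_ms,
        "rt_ms": np.nan if plan.no_response else plan.rt,
        "responding_hand": np.nan if plan.no_response else plan.responding_hand,
        "correct_hand": plan.correct_hand,
        "sat": plan.sat,
        "lexicality": plan.lexicality,
    }
    truth = {
        "participant": participant,
        "trial": trial,
        "sat": plan.sat,
        "lexicality": plan.lexicality,
        "correct_hand": plan.correct_hand,
        "responding_hand": np.nan if plan.no_response else plan.responding_hand,
        "true_pmt_ms": plan.pmt,
        "true_mt_ms": plan.mt,
        "true_rt_ms": plan.rt,
        "true_onset_sample": int(round((EPOCH_PRE_MS + plan.pmt)
                                       * spec.sampling_rate / 1000.0)),
        "overt_error": plan.overt_error,
        "fast_error": plan.fast_error,
        "partial_error": plan.partial_error,
        "partial_latency_ms": plan.partial_latency,
        "partial_correct": plan.partial_correct,
        "no_response": plan.no_response,
    }
    return event, truth


def generate_participant(spec: GeneratorSpec, participant: str,
                         rng: np.random.Generator):
    """Continuous recording + event and truth tables for one participant.

    Trials are laid out sequentially with quiescent gaps (``pre_gap_ms``
    before each stimulus, ``post_gap_ms`` after each epoch), grouped in
    SAT blocks with lexicality interleaved, mirroring a blocked session.
    """
    pmt_shift = rng.normal(0.0, spec.participant_pmt_sd_ms)
    mt_shift = rng.normal(0.0, spec.participant_mt_sd_ms)
    rate = spec.sampling_rate
    per_ms = rate / 1000.0

    plans: list[_TrialPlan] = []
    for sat in spec.sat_conditions:
        for _ in range(spec.trials_per_cell):
            for lex in spec.lexicalities:
                plans.append(_plan_trial(spec, sat, lex, rng,
                                         pmt_shift, mt_shift))

    spans = [int(round((spec.pre_gap_ms + EPOCH_POST_MS[p.sat]
                        + spec.post_gap_ms) * per_ms)) for p in plans]
    total = int(sum(spans))
    signal = rng.standard_normal((total, 2)) * spec.baseline_sd

    events, truths = [], []
    cursor = 0
    for i, (plan, span) in enumerate(zip(plans, spans)):
        stim = cursor + int(round(spec.pre_gap_ms * per_ms))
        stim_ms = stim * 1000.0 / rate
        pre_samples = stim  # absolute index of stimulus onset
        _fill_trial_signal(signal, plan, spec, rng, pre_samples=pre_samples)
        event, truth = _trial_rows(plan, spec, participant, i + 1, stim_ms)
        truth["true_onset_sample"] = (np.nan if plan.no_response else
                                      stim + int(round(plan.pmt * per_ms)))
        events.append(event)
        truths.append(truth)
        cursor += span

    recording = ContinuousRecording(
        sampling_rate=rate, signal=signal,
        channel_map={"emg_left": "left", "emg_right": "right"},
    )
    return (recording,
            pd.DataFrame(events),
            pd.DataFrame(truths, columns=TRUTH_COLUMNS))


def generate_dataset(spec: GeneratorSpec, seed: int, out_dir=None):
    """Full synthetic dataset: recordings, events, and ground truth.

    Returns ``(recordings, events, truth)`` where `recordings` maps
    participant id -> ContinuousRecording and the tables pool all
    participants.  With `out_dir` the io_formats layouts are also
    written (``recording_<id>.tsv`` + sidecars, ``events.tsv``,
    ``truth.tsv``); identical seeds yield identical outputs.
    """
    rng = np.random.default_rng(seed)
    recordings: dict[str, ContinuousRecording] = {}
    events, truths = [], []
    for p in range(1, spec.n_participants + 1):
        pid = f"p{p:02d}"
        rec, ev, tr = generate_participant(spec, pid, rng)
        recordings[pid] = rec
        events.append(ev)
        truths.append(tr)
    events = pd.concat(events, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid, rec in recordings.items():
            write_recording(rec, out / f"recording_{pid}.tsv")
        write_events(events, out / "events.tsv")
        write_table(truth, out / "truth.tsv")
    return recordings, events, truth
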