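"""Filtering of continuous EMG and epoch extraction.

The continuous recording is filtered first (10-Hz order-2 Butterworth
high-pass and a 50-Hz notch), and stimulus-locked epochs are cut from the
filtered signal: each epoch runs from 500 ms before stimulus onset to
1000 ms past the condition's response deadline, so even the slowest
admissible burst is fully contained.  Filters run forward–backward
(zero-phase) by default so burst onsets are not delayed; the effective
magnitude response is then the squared single-pass response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_formats import (
    ContinuousRecording,
    RunConfig,
    ValidationError,
    other_hand,
)


class ParameterError(ValueError):
    """A filter parameter is inconsistent with the sampling rate."""


def highpass_filter(recording: ContinuousRecording, cutoff: float = 10.0,
                    order: int = 2, zero_phase: bool = True) -> ContinuousRecording:
    """Butterworth high-pass; removes DC and slow drift.

    With ``zero_phase`` the filter is applied forward and backward
    (``sosfiltfilt``), doubling the attenuation in dB but keeping onset
    latencies undelayed.
    """
    nyquist = recording.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {nyquist} Hz")
    sos = sps.butter(order, cutoff, btype="highpass", fs=recording.sampling_rate,
                     output="sos")
    if zero_phase:
        out = sps.sosfiltfilt(sos, recording.signal, axis=0)
    else:
        out = sps.sosfilt(sos, recording.signal, axis=0)
    return recording.replace_signal(out)


def notch_filter(recording: ContinuousRecording, freq: float = 50.0,
                 bandwidth: float = 2.0, zero_phase: bool = True) -> ContinuousRecording:
    """Second-order IIR notch at `freq` Hz (−3 dB bandwidth `bandwidth`)."""
    nyquist = recording.sampling_rate / 2.0
    if freq >= nyquist:
        raise ParameterError(f"notch frequency {freq} Hz >= Nyquist {nyquist} Hz")
    b, a = sps.iirnotch(freq, freq / bandwidth, fs=recording.sampling_rate)
    if zero_phase:
        out = sps.filtfilt(b, a, recording.signal, axis=0)
    else:
        out = sps.lfilter(b, a, recording.signal, axis=0)
    return recording.replace_signal(out)


def filter_recording(recording: ContinuousRecording,
                     config: RunConfig) -> ContinuousRecording:
    """High-pass then notch, with the configured settings."""
    rec = highpass_filter(recording, config.highpass_hz, config.highpass_order,
                          config.zero_phase)
    return notch_filter(rec, config.notch_hz, config.notch_bandwidth_hz,
                        config.notch_zero_phase)


@dataclass
class TrialEpoch:
    """Stimulus-locked two-channel segment with trial metadata.

    The time axis is milliseconds relative to stimulus onset; the sample
    at index ``pre_samples`` sits at 0 ms.  The baseline span is
    ``[-pre_ms, 0)``.  ``rt_ms`` is None on no-response trials.
    """

    signal: np.ndarray  # (n_samples, 2) or empty when excluded
    sampling_rate: float
    pre_ms: float
    participant: object
    trial: int
    sat: str
    lexicality: str
    correct_hand: str
    responding_hand: str | None
    rt_ms: float | None
    channel_hands: tuple[str, str] = ("left", "right")
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def n_samples(self) -> int:
        return 0 if self.signal is None else self.signal.shape[0]

    @property
    def pre_samples(self) -> int:
        return int(round(self.pre_ms * self.sampling_rate / 1000.0))

    def index_of_ms(self, t_ms: float) -> int:
        """Epoch sample index of a latency given in ms post-stimulus."""
        return int(round((t_ms + self.pre_ms) * self.sampling_rate / 1000.0))

    def ms_of_index(self, i: int) -> float:
        return i * 1000.0 / self.sampling_rate - self.pre_ms

    @property
    def rt_sample(self) -> int | None:
        return None if self.rt_ms is None else self.index_of_ms(self.rt_ms)

    def channel_index(self, hand: str) -> int:
        return self.channel_hands.index(hand)

    def channel(self, hand: str) -> np.ndarray:
        return self.signal[:, self.channel_index(hand)]

    @property
    def nonresponding_hand(self) -> str | None:
        return None if self.responding_hand is None else other_hand(self.responding_hand)


def epoch_stimulus_locked(recording: ContinuousRecording, events: pd.DataFrame,
                          config: RunConfig) -> list[TrialEpoch]:
    """Cut one stimulus-locked epoch per event row.

    Epoch spans are per-condition: ``[-pre_ms, post_ms[sat])`` around each
    stimulus onset.  A trial whose span falls outside the recording is
    returned flagged ``excluded`` (reason ``epoch_out_of_bounds``) rather
    than raising.
    """
    rate = recording.sampling_rate
    hands = tuple(recording.channel_map[lab] for lab in recording.channel_labels)
    epochs = []
    for row in events.itertuples(index=False):
        rt = None if pd.isna(row.rt_ms) else float(row.rt_ms)
        resp = None if pd.isna(row.responding_hand) else str(row.responding_hand)
        post = config.post_ms[row.sat]
        start_ms = row.stimulus_onset_ms - config.pre_ms - recording.start_time_ms
        start = int(round(start_ms * rate / 1000.0))
        n = int(round((config.pre_ms + post) * rate / 1000.0))
        common = dict(
            sampling_rate=rate, pre_ms=config.pre_ms,
            participant=row.participant, trial=int(row.trial),
            sat=row.sat, lexicality=row.lexicality,
            correct_hand=row.correct_hand, responding_hand=resp, rt_ms=rt,
            channel_hands=hands,
        )
        if start < 0 or start + n > recording.n_samples:
            epochs.append(TrialEpoch(signal=np.empty((0, 2)), excluded=True,
                                     exclusion_reason="epoch_out_of_bounds",
                                     **common))
        else:
            epochs.append(TrialEpoch(signal=recording.signal[start:start + n],
                                     **common))
    return epochs


def epoch_onset_locked(epoch: TrialEpoch, onset_ms: float,
                       pre_ms: float = 500.0, post_ms: float = 1000.0):
    """Re-lock an epoch to an EMG onset latency.

    Returns ``(segment, pad_mask)`` where `segment` has a fixed length of
    ``(pre_ms + post_ms) * rate / 1000 + 1`` samples (endpoints inclusive;
    1501 at 1 kHz) on the lag axis ``[-pre_ms, post_ms]`` relative to the
    onset, and `pad_mask` is True where the source epoch actually covers
    the lag.  Out-of-epoch lags are zero-filled.
    """
    if onset_ms is None:
        raise ValidationError("cannot onset-lock without an onset latency")
    rate = epoch.sampling_rate
    centre = epoch.index_of_ms(onset_ms)
    npre = int(round(pre_ms * rate / 1000.0))
    npost = int(round(post_ms * rate / 1000.0))
    length = npre + npost + 1
    segment = np.zeros((length, epoch.signal.shape[1]))
    mask = np.zeros(length, dtype=bool)
    lo = centre - npre
    hi = centre + npost + 1
    src_lo, src_hi = max(lo, 0), min(hi, epoch.n_samples)
    if src_lo < src_hi:
        segment[src_lo - lo:src_hi - lo] = epoch.signal[src_lo:src_hi]
        mask[src_lo - lo:src_hi - lo] = True
    return segment, mask
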