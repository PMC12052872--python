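"""Supra-threshold activity windows, onset validation, covert activations.

A window of EMG activity is a maximal run of samples whose rectified
amplitude exceeds a per-epoch threshold (baseline mean + 3.5 SD of the
rectified baseline).  Runs separated by gaps shorter than 25 ms are
merged, merged windows shorter than 50 ms are discarded, and windows
starting at or after the button-press are discarded — in that order.

The same machinery runs on the channel of the hand *not* involved in the
final press to find covert activations: partial errors (incorrect hand
active on a trial ending correctly) and partial corrects (correct hand
active on a trial ending in an overt error).  Onset validity is checked
automatically: the detected onset must fall inside the last activity
window preceding the press, which screens out false starts, drifts and
isolated noise bursts that the original protocol removed by visual
inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import RunConfig, ValidationError
from .onset_detection import DegenerateInputError, OnsetEstimate, integrated_profile_onset
from .preprocess import TrialEpoch


@dataclass
class ActivityWindow:
    """Half-open supra-threshold interval ``[start, end)`` on one channel."""

    start: int
    end: int
    channel: str
    duration_ms: float
    peak_abs_amplitude: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError("window start must precede end")


@dataclass
class PartialActivation:
    """Covert activation of the hand not delivering the final press."""

    window: ActivityWindow
    latency_ms: float
    kind: str  # "partial_error" | "partial_correct"


def baseline_threshold(epoch: TrialEpoch, hand: str,
                       multiplier: float = 3.5) -> float:
    """Detection threshold: mean + `multiplier`·SD of |x| over the baseline.

    The baseline is the pre-stimulus span ``[-pre_ms, 0)``; the SD uses
    denominator n−1.
    """
    n = epoch.pre_samples
    if n < 2:
        raise ValidationError("empty baseline span")
    base = np.abs(epoch.channel(hand)[:n])
    return float(base.mean() + multiplier * base.std(ddof=1))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask, as half-open (start, end)."""
    padded = np.diff(np.concatenate(([False], mask, [False])).astype(np.int8))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def windows_from_mask(mask: np.ndarray, merge_gap_samples: int,
                      min_samples: int, rt_limit: int | None
                      ) -> list[tuple[int, int]]:
    """Apply the four window rules to a supra-threshold mask.

    Order is fixed: (1) maximal runs; (2) merge runs separated by gaps
    strictly shorter than `merge_gap_samples`; (3) discard merged windows
    shorter than `min_samples`; (4) discard windows starting at or after
    `rt_limit` (None keeps everything, used when no press occurred).
    """
    runs = _runs(np.asarray(mask, dtype=bool))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    kept = [(s, e) for s, e in merged if e - s >= min_samples]
    if rt_limit is not None:
        kept = [(s, e) for s, e in kept if s < rt_limit]
    return kept


def detect_windows(signal: np.ndarray, threshold: float,
                   rt_sample: int | None, config: RunConfig,
                   sampling_rate: float, channel: str) -> list[ActivityWindow]:
    """Retained activity windows on a single-channel epoch segment.

    `rt_sample` is the epoch index of the button-press; when the trial has
    no press the epoch end acts as the limit (every window starts before
    it, so none is dropped by the post-RT rule).
    """
    absx = np.abs(np.asarray(signal, dtype=float))
    per_ms = sampling_rate / 1000.0
    spans = windows_from_mask(
        absx > threshold,
        merge_gap_samples=int(np.ceil(config.merge_gap_ms * per_ms)),
        min_samples=int(np.ceil(config.min_window_ms * per_ms)),
        rt_limit=rt_sample,
    )
    return [
        ActivityWindow(start=s, end=e, channel=channel,
                       duration_ms=(e - s) / per_ms,
                       peak_abs_amplitude=float(absx[s:e].max()))
        for s, e in spans
    ]


def validate_onset(onset: OnsetEstimate, windows: list[ActivityWindow],
                   rt_sample: int, tolerance_samples: int = 10
                   ) -> tuple[bool, str]:
    """Cross-check an onset against the activity windows of its channel.

    Valid iff (a) at least one retained window starts before the press and
    (b) the onset falls within ``[start - tolerance, end)`` of the *last*
    such window.  The tolerance absorbs the method's documented <=1-sample
    argmin bias and residual filter ringing.  Reason codes: ``ok``,
    ``no_window``, ``onset_outside_last_window``.
    """
    before = [w for w in windows if w.start < rt_sample]
    if not before:
        return False, "no_window"
    last = before[-1]
    if last.start - tolerance_samples <= onset.onset_sample < last.end:
        return True, "ok"
    return False, "onset_outside_last_window"


def detect_partial_activations(epoch: TrialEpoch,
                               windows: list[ActivityWindow],
                               config: RunConfig) -> list[PartialActivation]:
    """Covert activations from the non-responding channel's windows.

    Each retained window yields one activation.  Its latency is the
    integrated-profile onset of a local segment running from
    ``partial_lead_ms`` before the window start to the window end (the
    lead supplies quiescent context so the profile minimum is defined).
    Kind follows the trial outcome: a covert window on a correctly-ended
    trial is a partial error; on an overt-error trial it is a partial
    correct (the correct hand twitched but lost).
    """
    if epoch.responding_hand is None:
        return []
    hand = epoch.nonresponding_hand
    x = np.abs(epoch.channel(hand))
    lead = int(round(config.partial_lead_ms * epoch.sampling_rate / 1000.0))
    kind = ("partial_error" if epoch.responding_hand == epoch.correct_hand
            else "partial_correct")
    out = []
    for w in windows:
        lo = max(w.start - lead, 0)
        try:
            idx = lo + integrated_profile_onset(x[lo:w.end])
        except DegenerateInputError:
            idx = w.start
        out.append(PartialActivation(window=w,
                                     latency_ms=epoch.ms_of_index(idx),
                                     kind=kind))
    return out
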