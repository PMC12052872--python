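"""RT decomposition into premotor and motor time, and trial classing.

Premotor time (PMT) is the interval from stimulus onset to the EMG burst
onset of the responding hand; motor time (MT) runs from that onset to the
button press.  By construction ``PMT + MT = RT`` for every retained
trial.  Each trial lands in exactly one analysis class:

* ``pure_correct`` — correct press, no covert activity (the set used for
  chronometric means and EMG curves);
* ``partial_error_trial`` — correct press with a covert incorrect-hand
  activation;
* ``overt_error`` — wrong press, clean correct-hand channel;
* ``partial_correct_trial`` — wrong press with a covert correct-hand
  activation;
* ``no_response`` — no press within the deadline (treated as its own
  class, not as an error, since deadline misses may reflect a different
  generative process; a config switch re-counts them as errors);
* ``excluded`` — onset invalid or epoch unusable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity_detection import PartialActivation
from .io_formats import TRIAL_COLUMNS, format_latency_list
from .onset_detection import OnsetEstimate
from .preprocess import TrialEpoch

TRIAL_CLASSES = (
    "pure_correct",
    "overt_error",
    "partial_error_trial",
    "partial_correct_trial",
    "no_response",
    "excluded",
)


@dataclass
class TrialDecomposition:
    """Per-trial chronometric decomposition and classification."""

    participant: object
    trial: int
    sat: str
    lexicality: str
    correct_hand: str
    responding_hand: str | None
    rt_ms: float | None
    pmt_ms: float | None
    mt_ms: float | None
    trial_class: str
    partial_latencies: tuple[float, ...] = field(default_factory=tuple)
    onset_valid: bool | None = None
    exclusion_reason: str | None = None

    @property
    def correct(self) -> bool | None:
        if self.responding_hand is None:
            return None
        return self.responding_hand == self.correct_hand


def decompose_trial(epoch: TrialEpoch, onset: OnsetEstimate
                    ) -> tuple[float | None, float | None, str | None]:
    """Split the trial's RT at the EMG onset.

    Returns ``(pmt_ms, mt_ms, exclusion_reason)``.  Both components must
    be strictly positive for retention: an onset at or after the press
    yields reason ``onset_after_rt``, an onset at or before the stimulus
    yields ``onset_before_stimulus`` (chronometrically meaningless; such
    epochs are pathological and excluded).
    """
    pmt = onset.onset_ms
    mt = epoch.rt_ms - onset.onset_ms
    if mt <= 0:
        return None, None, "onset_after_rt"
    if pmt <= 0:
        return None, None, "onset_before_stimulus"
    return pmt, mt, None


def classify_trial(epoch: TrialEpoch, onset_valid: bool | None,
                   exclusion_reason: str | None,
                   partials: list[PartialActivation]) -> str:
    """Assign the trial to exactly one analysis class (see module doc)."""
    if epoch.rt_ms is None:
        return "no_response"
    if exclusion_reason is not None or not onset_valid:
        return "excluded"
    covert = bool(partials)
    if epoch.responding_hand != epoch.correct_hand:
        return "partial_correct_trial" if covert else "overt_error"
    return "partial_error_trial" if covert else "pure_correct"


def decompositions_to_frame(decomps: list[TrialDecomposition]) -> pd.DataFrame:
    """Long-format trial table (one row per trial, stable column order)."""
    rows = []
    for d in decomps:
        rows.append({
            "participant": d.participant,
            "trial": d.trial,
            "sat": d.sat,
            "lexicality": d.lexicality,
            "correct_hand": d.correct_hand,
            "responding_hand": d.responding_hand,
            "correct": d.correct,
            "rt_ms": np.nan if d.rt_ms is None else d.rt_ms,
            "pmt_ms": np.nan if d.pmt_ms is None else d.pmt_ms,
            "mt_ms": np.nan if d.mt_ms is None else d.mt_ms,
            "trial_class": d.trial_class,
            "partial_latencies": format_latency_list(d.partial_latencies),
            "onset_valid": d.onset_valid,
            "exclusion_reason": d.exclusion_reason,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
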