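"""Plain-text interchange formats and run configuration.

The pipeline reads and writes a BIDS-physio-style layout:

* a continuous recording as ``recording.tsv`` (optionally ``.tsv.gz``)
  with columns ``t_ms, emg_left, emg_right`` plus a JSON sidecar
  (``recording.json``) carrying ``sampling_rate_hz`` and ``channel_map``;
* a trial event table as ``events.tsv`` with one row per trial;
* trial-level and curve-level result tables (``trials.tsv``, ``caf.tsv``,
  ``ciaf.tsv``, ``summary.tsv``, ``curves.tsv``) written by the pipeline.

Missing values (no-response trials) are encoded as ``n/a``.  Times are
milliseconds stored as floats; samples are addressed 0-based; all windows
are half-open ``[start, end)``.  Amplitudes are assumed to be microvolts,
but only the reported amplitude metrics depend on the unit — the detection
chain is scale-invariant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

HANDS = ("left", "right")
SAT_CONDITIONS = ("neutral", "accuracy", "speed")
LEXICALITIES = ("word", "pseudoword")

#: Response deadline per speed–accuracy instruction condition (ms).
DEADLINE_MS = {"neutral": 1500.0, "speed": 800.0, "accuracy": 5000.0}

#: Stimulus-locked epoch length after stimulus onset: deadline + 1000 ms,
#: so the slowest admissible response's EMG burst is fully contained.
EPOCH_POST_MS = {c: DEADLINE_MS[c] + 1000.0 for c in SAT_CONDITIONS}

#: Pre-stimulus baseline span included in every epoch (ms).
EPOCH_PRE_MS = 500.0

NA = "n/a"

EVENT_COLUMNS = [
    "participant",
    "trial",
    "stimulus_onset_ms",
    "rt_ms",
    "responding_hand",
    "correct_hand",
    "sat",
    "lexicality",
]

TRIAL_COLUMNS = [
    "participant",
    "trial",
    "sat",
    "lexicality",
    "correct_hand",
    "responding_hand",
    "correct",
    "rt_ms",
    "pmt_ms",
    "mt_ms",
    "trial_class",
    "partial_latencies",
    "onset_valid",
    "exclusion_reason",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout or misses metadata."""


class ValidationError(ValueError):
    """Data violate a structural invariant (channel count, deadlines, ...)."""


def other_hand(hand: str) -> str:
    return "left" if hand == "right" else "right"


# ---------------------------------------------------------------------------
# Continuous recordings
# ---------------------------------------------------------------------------

@dataclass
class ContinuousRecording:
    """Two-channel surface EMG time series.

    Parameters
    ----------
    sampling_rate : float
        Samples per second; must be positive (1000 Hz in the reference
        acquisition).
    signal : ndarray of shape (n_samples, 2)
        Amplitudes in microvolts, one column per channel.
    channel_map : dict
        Channel label -> hand ("left"/"right"), e.g.
        ``{"emg_left": "left", "emg_right": "right"}``.
    channel_labels : tuple of str
        Column order of ``signal``.
    start_time_ms : float
        Absolute time of sample 0.
    """

    sampling_rate: float
    signal: np.ndarray
    channel_map: dict[str, str]
    channel_labels: tuple[str, str] = ("emg_left", "emg_right")
    start_time_ms: float = 0.0

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.signal.ndim != 2 or self.signal.shape[1] != len(self.channel_labels):
            raise ValidationError(
                "signal must be 2-D with one column per channel label"
            )
        mapped = [self.channel_map.get(lab) for lab in self.channel_labels]
        if sorted(h for h in mapped if h is not None) != sorted(HANDS):
            raise ValidationError(
                f"channel_map must resolve to exactly two EMG channels, one per "
                f"hand; got {mapped!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    def channel_index(self, hand: str) -> int:
        """Column index of the channel recorded from `hand`."""
        for i, lab in enumerate(self.channel_labels):
            if self.channel_map[lab] == hand:
                return i
        raise KeyError(hand)

    def replace_signal(self, signal: np.ndarray) -> "ContinuousRecording":
        return dataclasses.replace(self, signal=np.asarray(signal, float))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".tsv.gz", ".tsv"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_recording(path, layout: str = "tsv") -> ContinuousRecording:
    """Read a continuous recording from TSV (+ JSON sidecar).

    The sidecar must carry ``sampling_rate_hz`` and ``channel_map``;
    amplitude values pass through unchanged.
    """
    path = Path(path)
    if layout != "tsv":
        raise FormatError(f"unknown layout {layout!r}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "sampling_rate_hz" not in meta:
        raise FormatError("sidecar lacks sampling_rate_hz")
    if "channel_map" not in meta:
        raise FormatError("sidecar lacks channel_map")
    df = pd.read_csv(path, sep="\t")
    labels = [c for c in df.columns if c != "t_ms"]
    return ContinuousRecording(
        sampling_rate=float(meta["sampling_rate_hz"]),
        signal=df[labels].to_numpy(dtype=float),
        channel_map=dict(meta["channel_map"]),
        channel_labels=tuple(labels),
        start_time_ms=float(df["t_ms"].iloc[0]) if len(df) else 0.0,
    )


def write_recording(recording: ContinuousRecording, path) -> None:
    """Write a recording as TSV plus JSON sidecar (inverse of read_recording)."""
    path = Path(path)
    t = recording.start_time_ms + np.arange(recording.n_samples) * (
        1000.0 / recording.sampling_rate
    )
    df = pd.DataFrame({"t_ms": t})
    for i, lab in enumerate(recording.channel_labels):
        df[lab] = recording.signal[:, i]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate,
        "channel_map": recording.channel_map,
        "units": "microvolts",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type an event table; returns a typed copy.

    Enforces: required columns; known condition / hand labels; unique trial
    index per participant; ``rt_ms`` within ``[0, deadline]`` for its SAT
    condition; ``responding_hand`` missing iff ``rt_ms`` missing.
    """
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event table misses columns {missing}")
    df = df.copy()
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["stimulus_onset_ms"] = pd.to_numeric(df["stimulus_onset_ms"])
    for col, allowed in (("sat", SAT_CONDITIONS), ("lexicality", LEXICALITIES),
                         ("correct_hand", HANDS)):
        bad = set(df[col].astype(str)) - set(allowed)
        if bad:
            raise ValidationError(f"unknown {col} label(s): {sorted(bad)}")
    resp = df["responding_hand"].where(df["responding_hand"].notna(), None)
    bad_resp = {h for h in resp if h is not None} - set(HANDS)
    if bad_resp:
        raise ValidationError(f"unknown responding_hand label(s): {sorted(bad_resp)}")
    if df.duplicated(subset=["participant", "trial"]).any():
        raise ValidationError("trial index not unique per participant")
    has_rt = df["rt_ms"].notna()
    has_hand = df["responding_hand"].notna()
    if (has_rt != has_hand).any():
        idx = df.loc[has_rt != has_hand, "trial"].tolist()
        raise ValidationError(
            f"responding_hand must be present iff rt_ms is (trials {idx})"
        )
    deadlines = df["sat"].map(DEADLINE_MS)
    bad_rt = has_rt & ((df["rt_ms"] < 0) | (df["rt_ms"] > deadlines))
    if bad_rt.any():
        idx = df.loc[bad_rt, "trial"].tolist()
        raise ValidationError(
            f"rt_ms outside [0, deadline] for trial(s) {idx}"
        )
    return df


def read_events(path) -> pd.DataFrame:
    """Read and validate an ``events.tsv`` table ('n/a' marks no response)."""
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    return validate_events(df)


def write_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.4f")


# ---------------------------------------------------------------------------
# Trial-level output tables
# ---------------------------------------------------------------------------

def write_trial_table(trials: pd.DataFrame, path) -> None:
    """Write per-trial decompositions as TSV with a stable column order.

    One data row per trial: participant, conditions, RT, PMT, MT, trial
    class, partial-activation latencies (semicolon-joined ms), validity
    flags.  No-response trials carry ``n/a`` in the chronometric fields.
    """
    if len(trials) == 0:
        raise ValidationError("refusing to write an empty trial table")
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in cols]
    trials[cols + extra].to_csv(
        path, sep="\t", index=False, na_rep=NA, float_format="%.4f"
    )


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    for col in ("rt_ms", "pmt_ms", "mt_ms"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "partial_latencies" in df.columns:
        df["partial_latencies"] = df["partial_latencies"].where(
            df["partial_latencies"].notna(), ""
        )
    return df


def parse_latency_list(value) -> list[float]:
    """Decode a semicolon-joined latency field ('' or n/a -> [])."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    s = str(value).strip()
    if not s or s == NA:
        return []
    return [float(tok) for tok in s.split(";")]


def format_latency_list(latencies) -> str:
    return ";".join(f"{x:.4f}" for x in latencies)


def write_table(df: pd.DataFrame, path) -> None:
    """Generic TSV writer used for caf/ciaf/summary/curves outputs."""
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.6f")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable constants of the measurement chain.

    Defaults reproduce the reference protocol: 10-Hz order-2 Butterworth
    high-pass plus 50-Hz notch, epochs from 500 ms before stimulus onset
    to deadline + 1000 ms, activity threshold at baseline mean + 3.5 SD of
    the rectified signal, <25-ms gap merging, <50-ms window rejection,
    five RT quantiles, 30%-of-peak amplitude window and 0–30-ms slope
    window for the onset-locked EMG curves.
    """

    highpass_hz: float = 10.0
    highpass_order: int = 2
    notch_hz: float = 50.0
    notch_bandwidth_hz: float = 2.0
    zero_phase: bool = True
    # The narrow notch runs causally by default: run zero-phase, its
    # ~160-ms ringing smears burst energy backward and fabricates
    # supra-threshold activity before the true onset.  Its causal group
    # delay away from 50 Hz is sub-millisecond, so onsets are unaffected.
    notch_zero_phase: bool = False
    pre_ms: float = EPOCH_PRE_MS
    post_ms: dict = field(default_factory=lambda: dict(EPOCH_POST_MS))
    threshold_sd: float = 3.5
    merge_gap_ms: float = 25.0
    min_window_ms: float = 50.0
    onset_tolerance_ms: float = 10.0
    partial_lead_ms: float = 50.0
    n_quantiles: int = 5
    curve_pre_ms: float = 500.0
    curve_post_ms: float = 1000.0
    amplitude_return_fraction: float = 0.30
    slope_window_ms: tuple = (0.0, 30.0)
    rectify_curves: bool = True
    count_no_response_as_error: bool = False
    seed: int = 0

    def __post_init__(self):
        self.slope_window_ms = tuple(float(x) for x in self.slope_window_ms)
        self.validate()

    def validate(self) -> None:
        durations = [self.pre_ms, self.merge_gap_ms, self.min_window_ms,
                     self.curve_pre_ms, self.curve_post_ms,
                     *self.post_ms.values()]
        if any(d <= 0 for d in durations):
            raise ValidationError("all durations must be positive")
        if self.n_quantiles < 2:
            raise ValidationError("quantile count must be >= 2")
        if not (0.0 < self.amplitude_return_fraction < 1.0):
            raise ValidationError("amplitude return fraction must be in (0, 1)")
        if self.slope_window_ms[1] <= self.slope_window_ms[0]:
            raise ValidationError("slope window must have positive length")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["slope_window_ms"] = list(self.slope_window_ms)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))
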