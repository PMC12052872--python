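"""End-to-end orchestration: filter, epoch, detect, decompose, summarize.

``run_arrays`` chains the whole measurement pipeline on in-memory
recordings and returns every output table plus a run manifest;
``run_pipeline`` is the file-based wrapper used by the command line.
Outputs are deterministic given inputs and configuration.  The manifest
records per-class trial counts, the excluded-epoch proportion and
per-stage timings, and the trial table carries per-trial exclusion
reasons — the machine-checkable stand-in for the visual epoch review of
the original protocol (flagged epochs can be exported for human review).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity_detection import (
    baseline_threshold,
    detect_partial_activations,
    detect_windows,
    validate_onset,
)
from .chronometry import (
    TRIAL_CLASSES,
    TrialDecomposition,
    classify_trial,
    decompose_trial,
    decompositions_to_frame,
)
from .conditional_functions import caf, ciaf, model_ready_table, summarize
from .emg_curves import CurveAccumulator, curve_amplitude, curve_slope
from .io_formats import (
    ContinuousRecording,
    RunConfig,
    read_events,
    read_recording,
    write_table,
    write_trial_table,
)
from .onset_detection import DegenerateInputError, detect_trial_onset
from .preprocess import TrialEpoch, epoch_onset_locked, epoch_stimulus_locked, filter_recording


@dataclass
class RunManifest:
    """Summary of one pipeline run (config snapshot, counts, timings)."""

    config: dict
    n_trials: int
    class_counts: dict
    excluded_fraction: float
    timings_s: dict = field(default_factory=dict)
    version: str = __version__
    input_hashes: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def process_epoch(epoch: TrialEpoch, config: RunConfig):
    """Run detection and decomposition on one stimulus-locked epoch.

    Returns ``(TrialDecomposition, curve_input)`` where `curve_input` is
    an onset-locked (segment, mask) pair for pure-correct trials with a
    validated onset, else None.
    """
    base = dict(participant=epoch.participant, trial=epoch.trial,
                sat=epoch.sat, lexicality=epoch.lexicality,
                correct_hand=epoch.correct_hand,
                responding_hand=epoch.responding_hand, rt_ms=epoch.rt_ms)

    if epoch.excluded:
        return TrialDecomposition(**base, pmt_ms=None, mt_ms=None,
                                  trial_class="excluded",
                                  exclusion_reason=epoch.exclusion_reason), None
    if epoch.rt_ms is None:
        return TrialDecomposition(**base, pmt_ms=None, mt_ms=None,
                                  trial_class="no_response"), None

    resp = epoch.responding_hand
    nonresp = epoch.nonresponding_hand
    rt_sample = epoch.rt_sample
    tol = int(round(config.onset_tolerance_ms * epoch.sampling_rate / 1000.0))

    try:
        onset = detect_trial_onset(epoch)
    except DegenerateInputError:
        return TrialDecomposition(**base, pmt_ms=None, mt_ms=None,
                                  trial_class="excluded", onset_valid=False,
                                  exclusion_reason="degenerate_signal"), None

    thr_resp = baseline_threshold(epoch, resp, config.threshold_sd)
    windows_resp = detect_windows(epoch.channel(resp), thr_resp, rt_sample,
                                  config, epoch.sampling_rate, resp)
    valid, reason = validate_onset(onset, windows_resp, rt_sample, tol)
    onset.valid, onset.reason = valid, reason

    thr_non = baseline_threshold(epoch, nonresp, config.threshold_sd)
    windows_non = detect_windows(epoch.channel(nonresp), thr_non, rt_sample,
                                 config, epoch.sampling_rate, nonresp)
    partials = detect_partial_activations(epoch, windows_non, config)

    pmt = mt = None
    excl = None if valid else reason
    if valid:
        pmt, mt, excl = decompose_trial(epoch, onset)
        if excl is not None:
            valid = False
    trial_class = classify_trial(epoch, valid, excl, partials)

    decomp = TrialDecomposition(
        **base, pmt_ms=pmt, mt_ms=mt, trial_class=trial_class,
        partial_latencies=tuple(p.latency_ms for p in partials),
        onset_valid=valid, exclusion_reason=excl,
    )

    curve_input = None
    if trial_class == "pure_correct":
        segment, mask = epoch_onset_locked(epoch, onset.onset_ms,
                                           config.curve_pre_ms,
                                           config.curve_post_ms)
        curve_input = (segment[:, epoch.channel_index(resp)], mask)
    return decomp, curve_input


def _curve_rows(accumulators: dict, lags: np.ndarray,
                config: RunConfig) -> pd.DataFrame:
    rows = []
    for (participant, sat, lex), acc in sorted(accumulators.items()):
        curve = acc.mean()
        amp, end_ms, no_return = curve_amplitude(
            curve, lags, config.amplitude_return_fraction)
        slope = curve_slope(curve, lags, config.slope_window_ms)
        rows.append({
            "participant": participant, "sat": sat, "lexicality": lex,
            "n_epochs": acc.n_epochs, "amplitude_metric": amp,
            "amplitude_window_end_ms": end_ms, "no_return": no_return,
            "slope_metric": slope,
        })
    return pd.DataFrame(rows)


def run_arrays(recordings: dict[str, ContinuousRecording],
               events: pd.DataFrame, config: RunConfig | None = None):
    """Full pipeline on in-memory inputs.

    `recordings` maps participant id -> ContinuousRecording; `events`
    pools all participants.  Returns a dict with keys ``trials``,
    ``caf``, ``ciaf``, ``summary``, ``curves``, ``model_ready`` (pandas
    DataFrames) and ``manifest`` (RunManifest).
    """
    config = config or RunConfig()
    timings: dict[str, float] = {}
    decomps: list[TrialDecomposition] = []
    rate = None
    lags = None
    accumulators: dict[tuple, CurveAccumulator] = {}

    t0 = time.perf_counter()
    for participant, recording in recordings.items():
        rate = recording.sampling_rate
        if lags is None:
            npre = int(round(config.curve_pre_ms * rate / 1000.0))
            npost = int(round(config.curve_post_ms * rate / 1000.0))
            lags = np.arange(-npre, npost + 1) * 1000.0 / rate
        filtered = filter_recording(recording, config)
        ev = events[events["participant"] == participant]
        for epoch in epoch_stimulus_locked(filtered, ev, config):
            decomp, curve_input = process_epoch(epoch, config)
            decomps.append(decomp)
            if curve_input is not None:
                key = (decomp.participant, decomp.sat, decomp.lexicality)
                acc = accumulators.setdefault(
                    key, CurveAccumulator(lags.size, config.rectify_curves))
                acc.add(*curve_input)
    timings["detect_decompose"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    trials = decompositions_to_frame(decomps)
    caf_df = caf(trials, config.n_quantiles)
    ciaf_df = ciaf(trials, config.n_quantiles)
    summary = summarize(trials, config.count_no_response_as_error)
    curves = _curve_rows(accumulators, lags, config)
    model_ready = (model_ready_table(pd.concat([caf_df, ciaf_df],
                                               ignore_index=True))
                   if len(caf_df) or len(ciaf_df) else pd.DataFrame())
    timings["summarize"] = time.perf_counter() - t0

    counts = {c: int((trials["trial_class"] == c).sum()) for c in TRIAL_CLASSES}
    manifest = RunManifest(
        config=config.as_dict(),
        n_trials=len(trials),
        class_counts=counts,
        excluded_fraction=(counts["excluded"] / len(trials)) if len(trials) else 0.0,
        timings_s={k: round(v, 3) for k, v in timings.items()},
    )
    return {"trials": trials, "caf": caf_df, "ciaf": ciaf_df,
            "summary": summary, "curves": curves, "model_ready": model_ready,
            "manifest": manifest}


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(recording_paths, events_path, config: RunConfig,
                 out_dir) -> RunManifest:
    """File-based pipeline run; writes all output tables plus the manifest.

    `recording_paths` maps participant id -> recording TSV path (or is a
    single path for a one-participant run whose id is taken from the
    event table).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events = read_events(events_path)
    if isinstance(recording_paths, (str, Path)):
        pids = events["participant"].unique()
        if len(pids) != 1:
            raise ValueError("single recording path but several participants")
        recording_paths = {pids[0]: recording_paths}
    hashes = {"events": _hash_file(Path(events_path))}
    recordings = {}
    for pid, path in recording_paths.items():
        recordings[pid] = read_recording(path)
        hashes[str(pid)] = _hash_file(Path(path))

    results = run_arrays(recordings, events, config)
    manifest: RunManifest = results["manifest"]
    manifest.input_hashes = hashes

    write_trial_table(results["trials"], out / "trials.tsv")
    for name in ("caf", "ciaf", "summary", "curves", "model_ready"):
        write_table(results[name], out / f"{name}.tsv")
    review = results["trials"][results["trials"]["trial_class"] == "excluded"]
    if len(review):
        write_table(review, out / "review_excluded.tsv")
    manifest.to_json(out / "manifest.json")
    return manifest
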