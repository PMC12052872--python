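"""Onset-locked EMG curves and their amplitude / rising-flank metrics.

Epochs time-locked to the EMG onset (lags −500..+1000 ms) of pure-correct
trials with validated onsets are rectified and averaged per participant
and condition, ignoring pad-masked samples where a source epoch ended
before the lag window did.  Two scalar metrics summarize each curve:

* mean amplitude over the window from lag 0 up to the first sample of the
  decreasing flank at or below 30% of the curve's absolute peak (the
  whole span when the curve never returns, flagged ``no_return``);
* the rising-flank slope, i.e. the OLS regression coefficient of
  amplitude on lag over 0–30 ms (endpoints inclusive), in microvolts/ms.

Both metrics scale linearly with a global rescaling of the input signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ValidationError


@dataclass
class EmgCurve:
    """Mean rectified onset-locked curve for one participant × condition."""

    participant: object
    sat: str
    lexicality: str
    lags_ms: np.ndarray
    amplitude: np.ndarray
    n_epochs: int
    amplitude_metric: float | None = None
    amplitude_window_end_ms: float | None = None
    no_return: bool = False
    slope_metric: float | None = None


class CurveAccumulator:
    """Streaming masked mean over onset-locked segments.

    Keeps per-lag sums and valid-sample counts so large runs need not
    retain every segment.  Segments are rectified before accumulation
    (signed averaging would cancel across motor-unit phase); a config
    switch upstream may disable rectification for sensitivity checks.
    """

    def __init__(self, length: int, rectify: bool = True):
        self.sum = np.zeros(length)
        self.count = np.zeros(length, dtype=int)
        self.rectify = rectify
        self.n_epochs = 0

    def add(self, segment: np.ndarray, mask: np.ndarray) -> None:
        seg = np.abs(segment) if self.rectify else np.asarray(segment, float)
        self.sum[mask] += seg[mask]
        self.count[mask] += 1
        self.n_epochs += 1

    def mean(self) -> np.ndarray:
        if self.n_epochs == 0:
            raise ValidationError("no epochs accumulated")
        out = np.full_like(self.sum, np.nan)
        ok = self.count > 0
        out[ok] = self.sum[ok] / self.count[ok]
        return out


def average_curve(segments, masks, rectify: bool = True) -> tuple[np.ndarray, int]:
    """Per-lag mean of rectified segments, ignoring pad-masked samples.

    `segments` is an (m, L) stack of single-channel onset-locked traces
    and `masks` the matching (m, L) validity mask.  Lags with no valid
    contributor come back NaN.  Returns ``(curve, n_epochs)``.
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    masks = np.atleast_2d(np.asarray(masks, dtype=bool))
    if segments.shape[0] == 0:
        raise ValidationError("average_curve needs at least one segment")
    acc = CurveAccumulator(segments.shape[1], rectify=rectify)
    for seg, mask in zip(segments, masks):
        acc.add(seg, mask)
    return acc.mean(), acc.n_epochs


def curve_amplitude(curve: np.ndarray, lags_ms: np.ndarray,
                    return_fraction: float = 0.30
                    ) -> tuple[float, float, bool]:
    """Mean curve amplitude from lag 0 to the 30%-of-peak return point.

    The absolute peak is searched over lags >= 0 (pre-onset baseline
    excluded).  The window ends at the first post-peak sample whose value
    is <= ``return_fraction * peak``; the mean is taken over the half-open
    lag window ``[0, window_end)``.  If the curve never returns, the
    window runs to the curve end and ``no_return`` is True.

    Returns ``(metric, window_end_ms, no_return)``; the metric is NaN for
    an all-zero (or all-NaN) post-onset curve.
    """
    lags = np.asarray(lags_ms, dtype=float)
    y = np.asarray(curve, dtype=float)
    post = lags >= 0
    ypost = y[post]
    finite = np.isfinite(ypost)
    if not finite.any() or np.nanmax(np.abs(ypost)) == 0:
        return float("nan"), float("nan"), False
    peak_idx = int(np.nanargmax(np.abs(ypost)))
    peak = abs(ypost[peak_idx])
    after = ypost[peak_idx + 1:]
    below = np.flatnonzero(after <= return_fraction * peak)
    if below.size:
        end_idx = peak_idx + 1 + below[0]
        no_return = False
    else:
        end_idx = ypost.size
        no_return = True
    lags_post = lags[post]
    end_ms = (lags_post[end_idx] if end_idx < ypost.size
              else lags_post[-1] + (lags_post[-1] - lags_post[-2]))
    window = ypost[:end_idx]
    return float(np.nanmean(window)), float(end_ms), no_return


def curve_slope(curve: np.ndarray, lags_ms: np.ndarray,
                window_ms: tuple[float, float] = (0.0, 30.0)) -> float:
    """OLS slope of curve amplitude vs lag over `window_ms`, in µV/ms.

    Window endpoints are inclusive (31 samples at 1 kHz for 0–30 ms).
    """
    lags = np.asarray(lags_ms, dtype=float)
    y = np.asarray(curve, dtype=float)
    sel = (lags >= window_ms[0]) & (lags <= window_ms[1]) & np.isfinite(y)
    if sel.sum() < 2:
        raise ValidationError("slope window must contain at least two samples")
    t = lags[sel]
    v = y[sel]
    return float(np.polyfit(t, v, 1)[0])
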