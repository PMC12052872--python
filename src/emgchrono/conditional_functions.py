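"""Conditional accuracy / incorrect-activation functions and summaries.

CAFs track response accuracy across RT quantiles; CIAFs track the
proportion of incorrect EMG activations — overt errors *and* covert
partial errors — across quantiles of the pooled (partial) response
latency, so that corrected impulses are not hidden by their correct final
press.  Binning is rank-based equal-count (the standard CAF
construction): the trial of 0-based rank r among n goes to bin
``floor(r*K/n) + 1``, ties broken by stable input order, so bin sizes
differ by at most one and the functions are invariant to monotone
latency transforms.

Also here: per-cell descriptive rates (accuracy, partial-error rate,
correction likelihood), within-participant confidence-interval
half-widths (Cousineau normalization with Morey's J/(J−1) correction),
the BIC-based Bayes-factor approximation, and the model-ready long table
with centred-quantile and orthogonal-polynomial covariates for external
mixed-model fitting (the fits themselves are out of scope).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError, parse_latency_list

RESPONDED_CLASSES = ("pure_correct", "partial_error_trial", "overt_error",
                     "partial_correct_trial", "excluded")
OVERT_ERROR_CLASSES = ("overt_error", "partial_correct_trial")

CELL_KEYS = ["participant", "sat", "lexicality"]


def quantile_partition(latencies, k: int = 5) -> np.ndarray:
    """Equal-count quantile bin (1..k) per trial, in input order."""
    lat = np.asarray(latencies, dtype=float)
    n = lat.size
    if n < k:
        raise ValidationError(f"need at least {k} latencies, got {n}")
    order = np.argsort(lat, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return ranks * k // n + 1


def _responded(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials with a press inside the deadline (no-response dropped).

    Accuracy-type analyses keep onset-excluded epochs too: correctness
    needs no EMG, only the press.
    """
    return trials[trials["rt_ms"].notna() &
                  (trials["trial_class"] != "no_response")]


def _binned(cell: pd.DataFrame, latencies: np.ndarray, flags: np.ndarray,
            k: int, kind: str) -> list[dict]:
    bins = quantile_partition(latencies, k)
    rows = []
    for b in range(1, k + 1):
        sel = bins == b
        rows.append({
            **{key: cell[key].iloc[0] for key in CELL_KEYS},
            "quantile": b,
            "mean_latency_ms": float(latencies[sel].mean()),
            "proportion": float(flags[sel].mean()),
            "n_trials": int(sel.sum()),
            "kind": kind,
        })
    return rows


def caf(trials: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Conditional accuracy function rows per participant × SAT × lexicality.

    Uses every responded trial irrespective of covert activity; the
    proportion is the share of correct presses per RT bin, with the bin's
    mean RT as its latency coordinate.  Cells with fewer than `k` trials
    are skipped.
    """
    rows = []
    for _, cell in _responded(trials).groupby(CELL_KEYS, sort=True):
        if len(cell) < k:
            continue
        rows.extend(_binned(cell, cell["rt_ms"].to_numpy(float),
                            cell["correct"].to_numpy(bool).astype(float),
                            k, "caf"))
    return pd.DataFrame(rows)


def ciaf(trials: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Conditional incorrect-activation function rows.

    Event set per cell: every overt response (latency = RT, flagged when
    the press was an error) plus one event per detected partial error
    (latency = covert-activation onset, always flagged).  Bins partition
    the pooled latencies.
    """
    rows = []
    for _, cell in _responded(trials).groupby(CELL_KEYS, sort=True):
        latencies = cell["rt_ms"].to_numpy(float).tolist()
        flags = (~cell["correct"].to_numpy(bool)).astype(float).tolist()
        partial_rows = cell[cell["trial_class"] == "partial_error_trial"]
        for value in partial_rows["partial_latencies"]:
            for lat in parse_latency_list(value):
                latencies.append(lat)
                flags.append(1.0)
        if len(latencies) < k:
            continue
        rows.extend(_binned(cell, np.asarray(latencies), np.asarray(flags),
                            k, "ciaf"))
    return pd.DataFrame(rows)


def partial_error_rate(trials: pd.DataFrame) -> float:
    """Share of correct-response trials carrying a covert incorrect burst:

    ``partial_error_trials / (partial_error_trials + pure_correct)``.
    NaN when no correct-response trial exists.
    """
    n_pe = int((trials["trial_class"] == "partial_error_trial").sum())
    n_pc = int((trials["trial_class"] == "pure_correct").sum())
    if n_pe + n_pc == 0:
        return float("nan")
    return n_pe / (n_pe + n_pc)


def correction_likelihood(trials: pd.DataFrame) -> float:
    """Probability that an incorrect EMG activation ends in a correct press.

    Numerator: partial-error trials (incorrect impulse corrected online).
    Denominator: all trials featuring an incorrect activation, i.e.
    partial errors plus overt errors (with or without a covert correct
    twitch).  NaN when no incorrect activation exists.
    """
    n_pe = int((trials["trial_class"] == "partial_error_trial").sum())
    n_err = int(trials["trial_class"].isin(OVERT_ERROR_CLASSES).sum())
    if n_pe + n_err == 0:
        return float("nan")
    return n_pe / (n_pe + n_err)


def accuracy(trials: pd.DataFrame,
             count_no_response_as_error: bool = False) -> float:
    """Share of correct presses among responded trials."""
    resp = _responded(trials)
    n_correct = int((resp["correct"] == True).sum())  # noqa: E712 (object col)
    n = len(resp)
    if count_no_response_as_error:
        n += int((trials["trial_class"] == "no_response").sum())
    if n == 0:
        return float("nan")
    return n_correct / n


def summarize(trials: pd.DataFrame,
              count_no_response_as_error: bool = False) -> pd.DataFrame:
    """Descriptive summary per participant × SAT × lexicality cell."""
    rows = []
    for keys, cell in trials.groupby(CELL_KEYS, sort=True):
        rows.append({
            **dict(zip(CELL_KEYS, keys)),
            "n": len(cell),
            "accuracy": accuracy(cell, count_no_response_as_error),
            "partial_error_rate": partial_error_rate(cell),
            "correction_likelihood": correction_likelihood(cell),
        })
    return pd.DataFrame(rows)


def morey_ci(cell_means: pd.DataFrame, coverage: float = 0.95) -> pd.Series:
    """Within-participant CI half-widths per condition.

    `cell_means` is a complete wide table (rows = participants, columns =
    conditions).  Each participant's mean is subtracted and the grand
    mean added back (Cousineau normalization), the per-condition SE of
    the normalized values is multiplied by sqrt(J/(J−1)) (Morey's
    correction for the J repeated-measures conditions), and the
    half-width is the two-sided t quantile at `coverage` with n−1 df
    times that corrected SE.
    """
    X = np.asarray(cell_means, dtype=float)
    n, j = X.shape
    if j < 2:
        raise ValidationError("need at least two conditions")
    if np.isnan(X).any():
        raise ValidationError("cell-mean table must be complete")
    normalized = X - X.mean(axis=1, keepdims=True) + X.mean()
    se = normalized.std(axis=0, ddof=1) / np.sqrt(n) * np.sqrt(j / (j - 1))
    tcrit = stats.t.ppf(0.5 + coverage / 2.0, n - 1)
    return pd.Series(tcrit * se, index=cell_means.columns, name="ci_halfwidth")


def bic_bayes_factor(bic_model_a: float, bic_model_b: float) -> float:
    """Bayes factor for model a over model b, approximated from BICs:

    ``BF = exp((BIC_b − BIC_a) / 2)``.  Values below 1 favour model b
    (the model with the smaller BIC wins).
    """
    if not (np.isfinite(bic_model_a) and np.isfinite(bic_model_b)):
        raise ValidationError("BIC inputs must be finite")
    return float(np.exp((bic_model_b - bic_model_a) / 2.0))


def orthogonal_polynomials(x, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial contrast columns of 1..degree over `x`.

    Gram–Schmidt on the Vandermonde columns after removing the constant,
    matching the construction R's ``poly(x, degree)`` uses; returned as
    an (n, degree) array.
    """
    x = np.asarray(x, dtype=float)
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    out = Q[:, 1:degree + 1]
    # pin signs so the linear column increases with x
    for d in range(out.shape[1]):
        lead = out[np.argmax(x), d] - out[np.argmin(x), d]
        if (d == 0 and lead < 0) or (d > 0 and out[np.argmax(x), d] < 0):
            out[:, d] = -out[:, d]
    return out


def model_ready_table(function_rows: pd.DataFrame) -> pd.DataFrame:
    """CAF/CIAF rows augmented with centred and orthogonal quantile covariates.

    Adds ``quantile_c`` (quantile minus its mid-point) and
    ``quantile_poly1`` / ``quantile_poly2`` (orthonormal linear and
    quadratic contrasts over the distinct quantile values) for external
    (G)LMM fitting.  Values only; no model is fitted here.
    """
    out = function_rows.copy()
    q = out["quantile"].to_numpy(float)
    levels = np.unique(q)
    out["quantile_c"] = q - levels.mean()
    poly = orthogonal_polynomials(levels, degree=2)
    lookup = {lev: poly[i] for i, lev in enumerate(levels)}
    out["quantile_poly1"] = [lookup[v][0] for v in q]
    out["quantile_poly2"] = [lookup[v][1] for v in q]
    return out
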