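"""Sensory Index (SI) and the two-stage sensory-neuron selection.

A sensory neuron should respond to every repeat of its stimulus, so its
trace restricted to the trial windows is nearly periodic.  The SI
quantifies this as the fraction of the window-restricted variance
explained by the trial-averaged (periodic) component:

    SI = Var(Trace_avg) / Var(trace over windows),

where Trace_avg tiles the across-repeat average at each window
position.  SI is 1 exactly when the trace repeats identically across
windows, and for pure i.i.d. noise E[SI] ~ 1/n_repeats.  Because
periodicity alone also admits flat or slowly ramping traces, selection
is two-stage: top decile of correlation with the stimulus regressor,
then the top 15% by SI within that decile, with percentile thresholds
taken per fish over the active population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from visuomotor.data import concat_windows, window_slices


def _check_windows(starts: np.ndarray, window_frames: int, n_frames: int) -> np.ndarray:
    starts = np.asarray(starts, dtype=np.int64)
    if starts.size < 2:
        raise ValueError("need at least 2 trial windows")
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if np.any(starts < 0) or np.any(starts + window_frames > n_frames):
        raise ValueError("trial window extends beyond the recording")
    return starts


def trial_average(trace: np.ndarray, starts: np.ndarray, window_frames: int) -> np.ndarray:
    """Pointwise mean response across equal-length trial windows."""
    trace = np.asarray(trace, dtype=np.float64)
    starts = _check_windows(starts, window_frames, trace.size)
    segs = np.stack([trace[s] for s in window_slices(starts, window_frames)])
    return segs.mean(axis=0)


def concatenated_average(
    trace: np.ndarray, starts: np.ndarray, window_frames: int
) -> np.ndarray:
    """Trace_avg: the trial average tiled at each window position.

    Defined only over the concatenated windows; returned as a vector of
    length ``n_windows * window_frames`` aligned with
    :func:`visuomotor.data.concat_windows`.
    """
    avg = trial_average(trace, starts, window_frames)
    return np.tile(avg, len(starts))


def sensory_index(trace: np.ndarray, starts: np.ndarray, window_frames: int) -> float:
    """Variance-ratio Sensory Index over the stimulus's trial windows.

    Both variances are computed after subtracting the window-restricted
    mean, so the index is invariant to affine rescaling (gain and
    offset) of the trace.  Returns ``nan`` for a zero-variance
    (constant) trace, which callers must exclude from ranking.
    """
    trace = np.asarray(trace, dtype=np.float64)
    starts = _check_windows(starts, window_frames, trace.size)
    concat = concat_windows(trace, starts, window_frames)
    var_total = concat.var()
    if var_total == 0.0:
        return float("nan")
    avg = trial_average(trace, starts, window_frames)
    tiled = np.tile(avg, len(starts))
    return float(tiled.var() / var_total)


def _top_k(n: int, pct: float) -> int:
    """Number of items in the top ``pct`` percent of ``n``, at least 1."""
    return max(1, int(np.ceil(n * pct / 100.0)))


def select_sensory(
    scores: pd.DataFrame, pct_corr: float = 10.0, pct_si: float = 15.0
) -> pd.DataFrame:
    """Two-stage percentile selection of sensory neurons.

    ``scores`` has one row per (neuron, stimulus) with columns
    ``neuron_id``, ``fish``, ``stimulus``, ``corr``, ``si``; rows with
    undefined SI (``nan``) never pass the second stage.  Thresholds are
    percentiles of the scored (active) population, computed separately
    per fish and per stimulus.  Ties are broken by stable neuron-id
    order.  Returns the input with a boolean ``selected`` column added.

    An empty input yields an empty result (no active neurons to rank).
    """
    scores = scores.copy()
    scores["selected"] = False
    if len(scores) == 0:
        import warnings

        warnings.warn("empty active population; no sensory neurons selected")
        return scores
    for (_, _), grp in scores.groupby(["fish", "stimulus"], sort=False):
        k1 = _top_k(len(grp), pct_corr)
        stage1 = grp.sort_values(
            ["corr", "neuron_id"], ascending=[False, True], kind="stable"
        ).head(k1)
        ranked = stage1.dropna(subset=["si"])
        k2 = _top_k(len(stage1), pct_si)
        stage2 = ranked.sort_values(
            ["si", "neuron_id"], ascending=[False, True], kind="stable"
        ).head(k2)
        scores.loc[stage2.index, "selected"] = True
    return scores
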