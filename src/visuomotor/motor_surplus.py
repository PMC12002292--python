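"""Trace surplus, Motor Surplus Index (MSI), SM-neuron selection, and decoding.

A sensorimotor (SM) neuron responds in trials where the stimulus evoked
its paired behavior but not in other presentations of the same
stimulus.  Subtracting each neuron's trial-averaged stimulus response
(its typical sensory component) leaves the *trace surplus*, the
stimulus-independent part of its activity; the MSI is the Pearson
correlation between the surplus and a visuomotor regressor that marks
only the behavior trials.  Selection takes the top MSI percentile
within fish (97th by default, where motor enhancement shows an elbow),
followed by the cross-fish colocalization filter.  The selection is
validated by leave-one-trial-out decoding of the behavior annotation
against a permuted-annotation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from visuomotor._stats import pearson
from visuomotor.data import (
    STIMULUS_OF_BEHAVIOR,
    BehaviorTable,
    PopulationRecording,
    TrialSchedule,
    window_slices,
)
from visuomotor.population_filters import colocalization_filter, single_trial_regressor_segment
from visuomotor.regressors import Regressor
from visuomotor.sensory_index import trial_average


def trace_surplus(trace: np.ndarray, starts: np.ndarray, window_frames: int) -> np.ndarray:
    """Stimulus-independent residual of a trace.

    Within each trial window the across-repeat trial average is
    subtracted; outside the windows the mean of the non-window frames
    is subtracted, so the surplus is mean-centered everywhere.  Summing
    the surplus across windows at any within-trial time point gives
    exactly zero (mean-centering identity).
    """
    trace = np.asarray(trace, dtype=np.float64)
    avg = trial_average(trace, starts, window_frames)
    surplus = trace.copy()
    in_window = np.zeros(trace.size, dtype=bool)
    for s in window_slices(starts, window_frames):
        surplus[s] = trace[s] - avg
        in_window[s] = True
    if (~in_window).any():
        surplus[~in_window] = trace[~in_window] - trace[~in_window].mean()
    return surplus


def motor_surplus_index(surplus: np.ndarray, vm_regressor: Regressor | np.ndarray) -> float:
    """Pearson correlation between a trace surplus and the visuomotor regressor.

    Computed over the full trace length.  A zero-variance surplus has
    no behavior-locked structure and scores 0.
    """
    values = vm_regressor.values if isinstance(vm_regressor, Regressor) else vm_regressor
    if np.asarray(values).std() == 0:
        raise ValueError("visuomotor regressor is constant")
    r = pearson(surplus, values)
    if np.isnan(r):
        warnings.warn("zero-variance surplus; MSI set to 0")
        return 0.0
    return r


def select_sm(scores: pd.DataFrame, pct: float = 97.0, radius_um: float = 20.0,
              min_fish: int = 2) -> pd.DataFrame:
    """Select SM neurons at a within-fish MSI percentile threshold.

    ``scores`` has one row per (neuron, behavior) with columns
    ``neuron_id``, ``fish``, ``behavior``, ``msi`` and, optionally,
    coordinates ``x``, ``y``, ``z``.  Percentile ranks are computed
    within fish and behavior; neurons at or above the ``pct`` rank are
    pre-selected.  When coordinates are present and more than one fish
    contributed, pre-selections are passed through the cross-fish
    colocalization filter.  Returns the input with ``percentile_within_fish``
    and ``selected`` columns.
    """
    scores = scores.copy()
    scores["percentile_within_fish"] = np.nan
    scores["selected"] = False
    for (fish, behavior), grp in scores.groupby(["fish", "behavior"], sort=False):
        if grp["msi"].isna().all():
            warnings.warn(f"behavior {behavior!r} scoreless in fish {fish}; skipped")
            continue
        # Hazen percentile rank: the top 3% of n neurons at pct=97
        ranks = (grp["msi"].rank(method="average") - 0.5) / len(grp) * 100.0
        scores.loc[grp.index, "percentile_within_fish"] = ranks
        scores.loc[grp.index[ranks >= pct], "selected"] = True

    has_coords = {"x", "y", "z"}.issubset(scores.columns)
    if has_coords and scores["fish"].nunique() > 1:
        pre = scores[scores["selected"]]
        cand = pre.rename(columns={"behavior": "cls"})[
            ["neuron_id", "fish", "cls", "x", "y", "z"]
        ]
        filt = colocalization_filter(cand, radius_um=radius_um, min_fish=min_fish)
        scores.loc[pre.index, "selected"] = filt["kept"].to_numpy()
    return scores


@dataclass
class EnhancementCurve:
    """Motor enhancement per MSI-percentile bin, with an elbow estimate."""

    behavior: str
    percentiles: np.ndarray
    enhancement: np.ndarray
    elbow: float


def _peak_stat(dff: np.ndarray, starts: np.ndarray, window_frames: int) -> np.ndarray:
    """Per-neuron mean (over trials) of the peak response in each window."""
    peaks = np.stack(
        [dff[:, s : s + window_frames].max(axis=1) for s in starts]
    )
    return peaks.mean(axis=0)


def motor_enhancement(
    dff: np.ndarray,
    behavior_starts: np.ndarray,
    nr_starts: np.ndarray,
    window_frames: int,
    msi: np.ndarray,
    behavior: str = "",
    percentile_grid: np.ndarray | None = None,
) -> EnhancementCurve:
    """Mean behavior-trial minus no-response-trial peak response, by MSI bin.

    Neurons are binned by their MSI percentile rank within the scored
    population; bin p collects ranks in [p, p+1).  The elbow is the
    grid point of maximum discrete curvature (second difference),
    suggesting a selection threshold.
    """
    if len(behavior_starts) == 0 or len(nr_starts) == 0:
        raise ValueError("need at least one behavior trial and one no-response trial")
    if percentile_grid is None:
        percentile_grid = np.arange(90, 100)
    percentile_grid = np.asarray(percentile_grid)
    ranks = pd.Series(msi).rank(method="average", pct=True).to_numpy() * 100.0
    beh_peak = _peak_stat(dff, behavior_starts, window_frames)
    nr_peak = _peak_stat(dff, nr_starts, window_frames)
    per_neuron = beh_peak - nr_peak
    enh = np.full(len(percentile_grid), np.nan)
    for i, p in enumerate(percentile_grid):
        hi = p + np.diff(percentile_grid, append=100.0)[i]
        mask = (ranks >= p) & (ranks < hi)
        if mask.any():
            enh[i] = per_neuron[mask].mean()
    curv = np.diff(enh, 2) if len(percentile_grid) >= 3 else np.array([np.nan])
    if np.isnan(curv).all():
        # too few neurons per bin to locate a kink
        elbow = float(percentile_grid[-1])
    else:
        elbow = float(percentile_grid[1:-1][np.nanargmax(curv)])
    return EnhancementCurve(behavior, percentile_grid, enh, elbow)


@dataclass
class HoldoutResult:
    """Leave-one-trial-out decoding report."""

    behavior: str
    fold_trials: np.ndarray      # positions within the stimulus's trials
    truth: np.ndarray            # bool: held trial is a behavior trial
    predictions: np.ndarray      # bool
    accuracy: float
    null_accuracies: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "behavior": self.behavior,
            "folds": [
                {"trial": int(t), "truth": bool(y), "predicted": bool(p)}
                for t, y, p in zip(self.fold_trials, self.truth, self.predictions)
            ],
            "accuracy": self.accuracy,
            "null_accuracies": [float(a) for a in self.null_accuracies],
        }


def _loto_accuracy(
    dff: np.ndarray,
    starts: np.ndarray,
    window_frames: int,
    regseg: np.ndarray,
    is_behavior: np.ndarray,
    is_none: np.ndarray,
    pct: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One leave-one-trial-out pass for a given annotation.

    For each held-out fold, SM neurons are re-selected from the
    training trials alone: the trial average, surplus, and visuomotor
    regressor are all restricted to training windows, so no held-out
    activity informs the selection.
    """
    usable = np.flatnonzero(is_behavior | is_none)
    fold_truth = is_behavior[usable]
    preds = np.zeros(len(usable), dtype=bool)
    n_trials = len(starts)
    segs = np.stack([dff[:, s : s + window_frames] for s in starts])  # trial x neuron x t

    for k, held in enumerate(usable):
        train = np.array([t for t in range(n_trials) if t != held])
        train_beh = train[is_behavior[train]]
        train_none = train[is_none[train]]
        if len(train_beh) < 1 or len(train_none) < 1:
            raise ValueError(
                "insufficient training trials in class "
                + ("behavior" if len(train_beh) < 1 else "no-response")
            )
        train_segs = segs[train]                      # (T-1, N, W)
        avg = train_segs.mean(axis=0)                 # (N, W)
        surplus = (train_segs - avg).transpose(1, 0, 2).reshape(dff.shape[0], -1)
        vm = np.concatenate(
            [regseg if is_behavior[t] else np.zeros(window_frames) for t in train]
        )
        vmc = vm - vm.mean()
        sc = surplus - surplus.mean(axis=1, keepdims=True)
        denom = np.sqrt((sc**2).sum(axis=1) * (vmc @ vmc))
        with np.errstate(invalid="ignore", divide="ignore"):
            msi = np.where(denom > 0, (sc @ vmc) / denom, 0.0)
        thresh = np.percentile(msi, pct)
        sm = msi >= thresh
        pop = segs[:, sm, :].mean(axis=1)             # (T, W) mean ΔF/F of SM population
        stat = pop.max(axis=1)                        # max population activity per trial
        m_b = stat[train_beh].mean()
        m_n = stat[train_none].mean()
        midpoint = 0.5 * (m_b + m_n)
        preds[k] = stat[held] >= midpoint if m_b >= m_n else stat[held] < midpoint
    return usable, fold_truth, preds


def holdout_predict(
    recording: PopulationRecording,
    schedule: TrialSchedule,
    behavior_table: BehaviorTable,
    behavior: str,
    kernel: np.ndarray,
    window_frames: int,
    pct: float = 97.0,
    n_null: int = 100,
    seed: int = 0,
) -> HoldoutResult:
    """Leave-one-trial-out behavioral decoding with a permuted-annotation null.

    For each held-out trial of the behavior's primary stimulus, SM
    neurons are selected from the remaining trials, the SM population's
    maximum mean activity in the held-out window is computed, and the
    trial is classified as behavior vs no-response by the midpoint
    between the training classes' mean statistics.  The null repeats
    the whole procedure on annotations permuted within fish
    (``n_null`` draws), reporting the null accuracy distribution.
    """
    stimulus = STIMULUS_OF_BEHAVIOR[behavior]
    trials = schedule.trials_of(stimulus)
    dur = int(schedule.duration_frames[trials[0]])
    starts = schedule.onset_frame[trials]
    labels = behavior_table.labels_for(schedule, stimulus)
    is_behavior = labels == behavior
    is_none = labels == "none"
    if is_behavior.sum() < 2:
        raise ValueError(f"need >=2 trials with behavior {behavior!r}")
    if is_none.sum() < 2:
        raise ValueError("need >=2 no-response trials")

    regseg = single_trial_regressor_segment(dur, window_frames, kernel)
    folds, truth, preds = _loto_accuracy(
        recording.dff, starts, window_frames, regseg, is_behavior, is_none, pct
    )
    accuracy = float((truth == preds).mean())

    rng = np.random.default_rng(seed)
    null_acc = np.zeros(n_null)
    for i in range(n_null):
        perm = rng.permutation(len(labels))
        pb, pn = is_behavior[perm], is_none[perm]
        _, t0, p0 = _loto_accuracy(
            recording.dff, starts, window_frames, regseg, pb, pn, pct
        )
        null_acc[i] = (t0 == p0).mean()
    return HoldoutResult(
        behavior, trials[folds], truth, preds, accuracy, null_acc
    )
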