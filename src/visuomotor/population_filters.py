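"""Active-neuron definition and the cross-fish spatial colocalization filter.

Both sensory and sensorimotor selections operate on an *active*
subpopulation — neurons whose single-trial traces track the expected
calcium response in at least 30% of the relevant trials for some
stimulus or behavior — and are then filtered for candidates that
colocalize across animals in the shared coordinate frame, which removes
fish-idiosyncratic (likely spurious) selections.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from visuomotor.data import (
    BEHAVIOR_OF_STIMULUS,
    BehaviorTable,
    PopulationRecording,
    TrialSchedule,
)
from visuomotor.regressors import convolve_causal

#: A neuron is active if responsive in at least this fraction of the
#: relevant trials for some stimulus or behavior.
RESPONSIVE_FRACTION = 0.30


def single_trial_regressor_segment(
    duration_frames: int, window_frames: int, kernel: np.ndarray
) -> np.ndarray:
    """Expected calcium response within one trial window.

    A unit boxcar of the stimulus duration at the window start,
    convolved causally with the kernel and truncated to the window.
    Identical for every trial of a stimulus, so computed once.
    """
    box = np.zeros(window_frames)
    box[: min(duration_frames, window_frames)] = 1.0
    return convolve_causal(box, kernel)


def active_neurons(
    recording: PopulationRecording,
    schedule: TrialSchedule,
    behavior_table: BehaviorTable,
    kernel: np.ndarray,
    window_frames: int,
    r_thresh: float = 0.5,
) -> pd.DataFrame:
    """Flag active neurons by per-trial regressor correlation.

    For each neuron and each stimulus, a trial is *responsive* when the
    Pearson correlation between the single-trial trace segment and the
    kernel-convolved single-trial regressor segment is >= ``r_thresh``.
    For each behavior, only trials of the behavior's primary stimulus
    annotated with that behavior count as relevant.  A neuron is active
    when responsive in >= 30% of the relevant trials for any stimulus
    or behavior.

    Returns a DataFrame with one row per neuron: ``neuron_id``,
    ``active``, ``fraction_responsive`` (the best fraction over
    stimuli/behaviors) and per-condition ``frac_<condition>`` columns.
    """
    if window_frames < 2:
        raise ValueError("trial windows must span at least 2 frames")
    dff = recording.dff
    n_neurons = dff.shape[0]
    out: dict[str, np.ndarray] = {}
    stimuli = pd.unique(schedule.stimulus)
    for stim in stimuli:
        trials = schedule.trials_of(stim)
        dur = int(schedule.duration_frames[trials[0]])
        regseg = single_trial_regressor_segment(dur, window_frames, kernel)
        starts = schedule.onset_frame[trials]
        labels = behavior_table.labels_for(schedule, stim)
        behavior = BEHAVIOR_OF_STIMULUS.get(stim)

        resp = np.zeros((n_neurons, len(starts)), dtype=bool)
        for j, s in enumerate(starts):
            seg = dff[:, s : s + window_frames]
            segc = seg - seg.mean(axis=1, keepdims=True)
            regc = regseg - regseg.mean()
            denom = np.sqrt((segc**2).sum(axis=1) * (regc @ regc))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (segc @ regc) / denom
            resp[:, j] = r >= r_thresh
        out[f"frac_{stim}"] = resp.mean(axis=1)
        if behavior is not None:
            beh_mask = labels == behavior
            if beh_mask.any():
                out[f"frac_{behavior}"] = resp[:, beh_mask].mean(axis=1)

    frac_cols = np.column_stack(list(out.values()))
    best = frac_cols.max(axis=1)
    flags = pd.DataFrame({"neuron_id": np.arange(n_neurons), **out})
    flags["fraction_responsive"] = best
    flags["active"] = best >= RESPONSIVE_FRACTION
    return flags


def colocalization_filter(
    candidates: pd.DataFrame,
    radius_um: float = 20.0,
    min_fish: int = 2,
) -> pd.DataFrame:
    """Keep candidates with same-class support from enough other fish.

    ``candidates`` has columns ``neuron_id``, ``fish``, ``cls``, ``x``,
    ``y``, ``z`` (shared reference frame, micrometers).  A candidate is
    kept iff candidates of the same class from at least ``min_fish``
    *other* fish lie within ``radius_um``.  With a single fish the
    filter cannot apply and is skipped with a warning; ``min_fish=0``
    is the identity filter.

    Returns the input with ``n_neighbor_fish`` and ``kept`` columns.
    """
    candidates = candidates.reset_index(drop=True)
    fishes = candidates["fish"].unique()
    if min_fish == 0:
        candidates["n_neighbor_fish"] = 0
        candidates["kept"] = True
        return candidates
    if len(fishes) < 2:
        warnings.warn("colocalization filter skipped: fewer than 2 fish")
        candidates["n_neighbor_fish"] = 0
        candidates["kept"] = True
        return candidates

    n_support = np.zeros(len(candidates), dtype=int)
    for cls, grp in candidates.groupby("cls", sort=False):
        coords = grp[["x", "y", "z"]].to_numpy(dtype=np.float64)
        fish_of = grp["fish"].to_numpy()
        trees = {
            f: cKDTree(coords[fish_of == f]) for f in np.unique(fish_of)
        }
        for pos, (i, row) in enumerate(zip(grp.index, coords)):
            count = 0
            for f, tree in trees.items():
                if f == fish_of[pos]:
                    continue
                if tree.query_ball_point(row, r=radius_um, return_length=True) > 0:
                    count += 1
            n_support[candidates.index.get_loc(i)] = count
    candidates["n_neighbor_fish"] = n_support
    candidates["kept"] = n_support >= min_fish
    return candidates


def colocalization_permutation_p(
    candidates: pd.DataFrame,
    all_coords: pd.DataFrame,
    radius_um: float = 20.0,
    n_perm: int = 199,
    seed: int = 0,
) -> float:
    """Permutation p-value for the observed cross-fish neighbor support.

    The test statistic is the mean number of supporting fish per
    candidate; the null redraws, per fish, the same number of candidate
    positions uniformly from that fish's full coordinate table
    (``all_coords``: columns ``fish``, ``x``, ``y``, ``z``).
    """
    rng = np.random.default_rng(seed)

    def mean_support(df: pd.DataFrame) -> float:
        scored = colocalization_filter(df, radius_um=radius_um, min_fish=1)
        return float(scored["n_neighbor_fish"].mean())

    obs = mean_support(candidates)
    counts = candidates.groupby("fish").size()
    exceed = 0
    for _ in range(n_perm):
        rows = []
        for f, k in counts.items():
            pool = all_coords[all_coords["fish"] == f]
            pick = pool.sample(n=min(k, len(pool)), random_state=rng.integers(2**31))
            pick = pick.assign(cls="null", neuron_id=np.arange(len(pick)))
            rows.append(pick)
        null_df = pd.concat(rows, ignore_index=True)
        if mean_support(null_df) >= obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
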