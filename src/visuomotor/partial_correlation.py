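"""Behavior-conditioned partial correlation between sensory and SM neurons.

Two hypotheses can explain a correlation between a sensory (S) neuron
and a sensorimotor (SM) neuron: the SM neuron integrates the sensory
neuron's activity (H1, connected), or both merely covary with the
behavior through an unobserved common decision signal (H2).  Only
under H1 do the neurons remain correlated once the behavior-locked
component is removed.

The behavior-locked component is removed by template subtraction:
trials of the paired stimulus are split into behavior and nonbehavior
classes, each class's trial-averaged response is subtracted from that
class's windows, and the partial correlation given behavior
(rho_S,SM|B) is the Pearson correlation of the resulting residual
traces.  Each SM neuron is summarized by the 90th percentile of its
partial correlations with the whole sensory population (an SM neuron
likely receives input from only a sparse subset), tested against a
trial-shuffled null that reorders the SM residual's trial segments
within behavior class — preserving marginals, autocorrelation and the
behavior structure while destroying within-trial pairing.  Empirical
p-values are Benjamini–Hochberg adjusted within area x behavior x fish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from visuomotor._stats import pearson, percentile_linear
from visuomotor.data import window_slices

PC_PERCENTILE = 90.0


def behavior_templates(
    trace: np.ndarray,
    starts: np.ndarray,
    window_frames: int,
    is_behavior: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged responses of the behavior and nonbehavior trial classes."""
    trace = np.asarray(trace, dtype=np.float64)
    is_behavior = np.asarray(is_behavior, dtype=bool)
    if len(is_behavior) != len(starts):
        raise ValueError("one class flag per trial window required")
    if not is_behavior.any():
        raise ValueError("no behavior trials")
    if is_behavior.all():
        raise ValueError("no nonbehavior trials")
    segs = np.stack([trace[s] for s in window_slices(starts, window_frames)])
    return segs[is_behavior].mean(axis=0), segs[~is_behavior].mean(axis=0)


def residual(
    trace: np.ndarray,
    starts: np.ndarray,
    window_frames: int,
    is_behavior: np.ndarray,
    templates: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Residual trace over trial windows after class-template subtraction.

    Each trial window gets its own class's template subtracted, so the
    mean residual of each class is exactly zero at every within-trial
    time point.  Returned as an (n_trials, window_frames) array in
    trial order.
    """
    if templates is None:
        templates = behavior_templates(trace, starts, window_frames, is_behavior)
    beh_t, non_t = templates
    segs = np.stack([trace[s] for s in window_slices(starts, window_frames)])
    out = segs - np.where(np.asarray(is_behavior, bool)[:, None], beh_t, non_t)
    return out


def partial_corr(res_sm: np.ndarray, res_s: np.ndarray) -> float:
    """rho_S,SM|B: Pearson correlation of two residual traces.

    Residuals must cover identical windows; they are flattened and
    correlated.  A zero-variance residual yields 0 with a warning.
    """
    a = np.asarray(res_sm, dtype=np.float64).ravel()
    b = np.asarray(res_s, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("residuals must cover identical windows")
    r = pearson(a, b)
    if np.isnan(r):
        warnings.warn("zero-variance residual; partial correlation set to 0")
        return 0.0
    return r


def pc_statistic(res_sm: np.ndarray, sensory_residuals: np.ndarray,
                 q: float = PC_PERCENTILE) -> float:
    """q-th percentile (linear interpolation) of an SM neuron's partial correlations.

    ``sensory_residuals`` is (n_sensory, n_trials, window_frames); the
    statistic summarizes the SM neuron's strongest correlations with
    the sensory population.  Warns when fewer than 10 sensory neurons
    make the percentile degenerate.
    """
    sensory_residuals = np.asarray(sensory_residuals, dtype=np.float64)
    if sensory_residuals.ndim == 2:
        sensory_residuals = sensory_residuals[None, :, :]
    n_s = sensory_residuals.shape[0]
    if n_s == 0:
        raise ValueError("empty sensory population")
    if n_s < 10:
        warnings.warn(f"only {n_s} sensory neurons; percentile statistic degenerate")
    pcs = np.array([partial_corr(res_sm, sensory_residuals[i]) for i in range(n_s)])
    return percentile_linear(pcs, q)


def _normalized_rows(mat: np.ndarray) -> np.ndarray:
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    norms[norms == 0] = np.inf
    return centered / norms


def _class_permutation(rng: np.random.Generator, is_behavior: np.ndarray) -> np.ndarray:
    """Random trial permutation acting within each behavior class."""
    perm = np.arange(len(is_behavior))
    for mask in (is_behavior, ~is_behavior):
        idx = np.flatnonzero(mask)
        perm[idx] = rng.permutation(idx)
    return perm


def trial_shuffle_null(
    res_sm: np.ndarray,
    sensory_residuals: np.ndarray,
    is_behavior: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    q: float = PC_PERCENTILE,
) -> np.ndarray:
    """Trial-shuffled null distribution of the percentile statistic.

    Each permutation reorders the SM residual's trial segments by a
    random permutation *within* behavior class (preserving the class
    structure and each segment's waveform) and recomputes the
    percentile statistic against the fixed sensory residuals.
    """
    res_sm = np.asarray(res_sm, dtype=np.float64)
    sensory_residuals = np.asarray(sensory_residuals, dtype=np.float64)
    is_behavior = np.asarray(is_behavior, dtype=bool)
    n_trials = res_sm.shape[0]
    if n_trials < 3:
        raise ValueError("need >=3 trials for a meaningful trial shuffle")
    if max(is_behavior.sum(), (~is_behavior).sum()) < 2:
        raise ValueError("within-class permutation space is identity-only")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    S = _normalized_rows(sensory_residuals.reshape(sensory_residuals.shape[0], -1))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = _class_permutation(rng, is_behavior)
        x = res_sm[perm].ravel()
        xc = x - x.mean()
        nrm = np.linalg.norm(xc)
        pcs = S @ (xc / nrm) if nrm > 0 else np.zeros(S.shape[0])
        null[i] = percentile_linear(pcs, q)
    return null


def empirical_p(stat: float, null_stats: np.ndarray) -> float:
    """Permutation p-value: (1 + #{null >= stat}) / (1 + n_perm)."""
    null_stats = np.asarray(null_stats)
    if null_stats.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + (null_stats >= stat).sum()) / (1 + null_stats.size))


def pc_test_population(
    sm_residuals: np.ndarray,
    sensory_residuals: np.ndarray,
    is_behavior: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    q: float = PC_PERCENTILE,
) -> pd.DataFrame:
    """Percentile statistic and empirical p-value for every SM neuron.

    ``sm_residuals`` is (n_sm, n_trials, window_frames).  Returns a
    DataFrame with ``stat``, ``p_empirical`` and null summaries; each
    SM neuron gets an independent permutation stream derived from
    ``seed``.
    """
    sm_residuals = np.asarray(sm_residuals, dtype=np.float64)
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(sm_residuals.shape[0])
    for i in range(sm_residuals.shape[0]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = pc_statistic(sm_residuals[i], sensory_residuals, q=q)
        null = trial_shuffle_null(
            sm_residuals[i],
            sensory_residuals,
            is_behavior,
            n_perm=n_perm,
            seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
            q=q,
        )
        rows.append(
            {
                "sm_index": i,
                "stat": stat,
                "null_mean": float(null.mean()),
                "null_q95": percentile_linear(null, 95),
                "p_empirical": empirical_p(stat, null),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AreaFractionResult:
    """Fraction of SM neurons with significant sensory partial correlation."""

    area: str
    behavior: str
    fraction: float          # pooled over fish
    per_fish: dict[int, float]
    n_sm: int
    signed_rank_p: float | None


def area_fraction_significant(
    pc_results: pd.DataFrame,
    area: str,
    behavior: str,
    alpha: float = 0.05,
) -> AreaFractionResult:
    """BH-adjust within area x behavior x fish; report significant fractions.

    ``pc_results`` needs columns ``fish``, ``area``, ``behavior``,
    ``p_empirical``.  The pooled fraction is over all SM neurons of the
    behavior in the area; per-fish fractions feed a one-sided Wilcoxon
    signed-rank test against the chance level ``alpha`` (reported as
    ``signed_rank_p``, None when fewer than 3 fish contribute or all
    differences are zero).
    """
    sub = pc_results[(pc_results["area"] == area) & (pc_results["behavior"] == behavior)]
    if len(sub) == 0:
        raise ValueError(f"no SM neurons of behavior {behavior!r} in area {area!r}")
    sub = sub.copy()
    sub["p_adjusted"] = np.nan
    sub["significant"] = False
    for fish, grp in sub.groupby("fish", sort=False):
        rej, p_adj, _, _ = multipletests(grp["p_empirical"], alpha=alpha, method="fdr_bh")
        sub.loc[grp.index, "p_adjusted"] = p_adj
        sub.loc[grp.index, "significant"] = rej
    fraction = float(sub["significant"].mean())
    per_fish = {
        int(f): float(g["significant"].mean()) for f, g in sub.groupby("fish", sort=True)
    }
    signed_rank_p = None
    diffs = np.array(list(per_fish.values())) - alpha
    if len(diffs) >= 3 and np.any(diffs != 0):
        from scipy.stats import wilcoxon

        try:
            signed_rank_p = float(
                wilcoxon(diffs, alternative="greater", zero_method="wilcox").pvalue
            )
        except ValueError:
            signed_rank_p = None
    return AreaFractionResult(area, behavior, fraction, per_fish, len(sub), signed_rank_p)
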