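"""Planted-ground-truth validation harness.

Each function generates data under stated study conditions, runs the
corresponding analysis stage, and scores the result against the
generator's planted truth.  The functions back both the acceptance
test suite and ``scripts/acceptance.py``; they take an explicit seed so
every reported number is recomputed from scratch.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import kstest

from visuomotor.data import (
    BEHAVIORS,
    STIMULI,
    STIMULUS_OF_BEHAVIOR,
)
from visuomotor.motor_surplus import holdout_predict, select_sm, trace_surplus
from visuomotor.partial_correlation import (
    area_fraction_significant,
    partial_corr,
    pc_test_population,
    residual,
)
from visuomotor.physiology import (
    bradycardia,
    classify_trial,
    detect_beats,
    instantaneous_hr,
    rhythmic_pixels,
)
from visuomotor.population_filters import colocalization_filter
from visuomotor.regressors import (
    NoBehaviorTrialsError,
    make_kernel,
    stimulus_regressor,
    visuomotor_regressor,
)
from visuomotor.sensory_index import select_sensory, sensory_index
from visuomotor.synthetic_data import (
    SimConfig,
    bradycardia_rate_profile,
    generate_heart_video,
    generate_population,
)


def _spawn(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((seed, *key)).generate_state(1)[0] % (2**31))


# ----------------------------------------------------------------- SI --

def si_properties(seed: int, n_noise: int = 300) -> dict:
    """SI of noiseless periodic neurons (exactly 1) and pure-noise neurons (~1/8)."""
    clean = SimConfig(
        n_fish=1, n_sensory_per_stimulus=3, n_sm_per_behavior=0, n_mixed=0,
        n_background=0, noise_sd=0.0, amp_spread_sd=0.0, trial_jitter_sd=0.0,
        seed=_spawn(seed, 0),
    )
    recs, sched, _, _ = generate_population(clean)
    wf = clean.window_frames
    starts = sched.windows("sweep", wf)
    rec = recs[0]
    ids = rec.neurons.index[rec.neurons["true_class"] == "sensory:sweep"]
    si_clean = [sensory_index(rec.dff[n], starts, wf) for n in ids]

    rng = np.random.default_rng(_spawn(seed, 1))
    n_frames = rec.n_frames
    sis = [
        sensory_index(rng.normal(0, 1, n_frames), starts, wf) for _ in range(n_noise)
    ]
    sis = np.asarray(sis)
    return {
        "si_noiseless_min": float(np.min(si_clean)),
        "si_noise_mean": float(sis.mean()),
        "si_noise_se": float(sis.std() / np.sqrt(n_noise)),
        "n_repeats": len(starts),
    }


# --------------------------------------------------- sensory selection --

def _score_population(recs, sched, behs, cfg, truth):
    """Regressor correlation and SI for every neuron, every stimulus."""
    kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
    wf = cfg.window_frames
    rows = []
    for rec in recs:
        for stim in STIMULI:
            reg = stimulus_regressor(sched, stim, kernel, rec.n_frames)
            starts = sched.windows(stim, wf)
            segs = np.stack([rec.dff[:, s : s + wf] for s in starts])
            concat = segs.transpose(1, 0, 2).reshape(rec.n_neurons, -1)
            avg = segs.mean(axis=0)
            tiled = np.tile(avg, (1, len(starts)))
            with np.errstate(invalid="ignore", divide="ignore"):
                si = tiled.var(axis=1) / concat.var(axis=1)
            regc = reg.values - reg.values.mean()
            dffc = rec.dff - rec.dff.mean(axis=1, keepdims=True)
            denom = np.sqrt((dffc**2).sum(axis=1) * (regc @ regc))
            corr = np.where(denom > 0, (dffc @ regc) / denom, np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "neuron_id": np.arange(rec.n_neurons),
                        "fish": rec.fish_id,
                        "stimulus": stim,
                        "corr": corr,
                        "si": si,
                    }
                )
            )
    scores = pd.concat(rows, ignore_index=True)
    nt = truth.neurons.set_index(["fish", "neuron_id"])
    scores = scores.join(
        nt[["x", "y", "z", "region", "true_class"]], on=["fish", "neuron_id"]
    )
    return scores


def sensory_recovery(seed: int) -> dict:
    """Precision/recall of the two-stage cascade plus colocalization.

    Conditions: 3 fish, 1,000-neuron scored population per fish with
    2.5% planted sensory neurons per stimulus at amplitude SNR 3.
    """
    cfg = SimConfig(seed=_spawn(seed, 2))  # defaults encode the conditions
    recs, sched, behs, truth = generate_population(cfg)
    scores = _score_population(recs, sched, behs, cfg, truth)
    scores = select_sensory(scores)
    pre = scores[scores["selected"]]
    cand = pre.rename(columns={"stimulus": "cls"})[
        ["neuron_id", "fish", "cls", "x", "y", "z"]
    ]
    filt = colocalization_filter(cand, radius_um=20.0, min_fish=2)
    scores.loc[pre.index, "selected"] = filt["kept"].to_numpy()

    out = {"n_population": cfg.n_neurons}
    precisions, recalls = [], []
    for stim in STIMULI:
        sel = scores[(scores["stimulus"] == stim) & scores["selected"]]
        planted = scores[
            (scores["stimulus"] == stim) & (scores["true_class"] == f"sensory:{stim}")
        ]
        tp = (sel["true_class"] == f"sensory:{stim}").sum()
        precisions.append(tp / max(len(sel), 1))
        recalls.append(tp / len(planted))
    out["precision_min"] = float(min(precisions))
    out["recall_min"] = float(min(recalls))
    out["_scores"] = scores
    return out


# -------------------------------------------------------- SM selection --

def sm_recovery(seed: int, sensory_scores: pd.DataFrame | None = None) -> dict:
    """SM recall at the 97th percentile and the sensory/SM overlap count."""
    cfg = SimConfig(seed=_spawn(seed, 2))  # same dataset as sensory_recovery
    recs, sched, behs, truth = generate_population(cfg)
    kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
    wf = cfg.window_frames
    rows = []
    for rec, beh in zip(recs, behs):
        for behavior in BEHAVIORS:
            stim = STIMULUS_OF_BEHAVIOR[behavior]
            starts = sched.windows(stim, wf)
            try:
                vm = visuomotor_regressor(sched, beh, behavior, kernel, rec.n_frames)
            except NoBehaviorTrialsError:
                continue
            vmc = vm.values - vm.values.mean()
            surplus = np.stack(
                [trace_surplus(rec.dff[n], starts, wf) for n in range(rec.n_neurons)]
            )
            sc = surplus - surplus.mean(axis=1, keepdims=True)
            denom = np.sqrt((sc**2).sum(axis=1) * (vmc @ vmc))
            with np.errstate(invalid="ignore", divide="ignore"):
                msi = np.where(denom > 0, (sc @ vmc) / denom, 0.0)
            rows.append(
                pd.DataFrame(
                    {
                        "neuron_id": np.arange(rec.n_neurons),
                        "fish": rec.fish_id,
                        "behavior": behavior,
                        "msi": msi,
                    }
                )
            )
    scores = pd.concat(rows, ignore_index=True)
    nt = truth.neurons.set_index(["fish", "neuron_id"])
    scores = scores.join(
        nt[["x", "y", "z", "region", "true_class"]], on=["fish", "neuron_id"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = select_sm(scores, pct=97.0)

    recalls = {}
    for behavior in BEHAVIORS:
        sel = scores[(scores["behavior"] == behavior) & scores["selected"]]
        planted = scores[
            (scores["behavior"] == behavior)
            & (scores["true_class"] == f"sm:{behavior}")
        ]
        recalls[behavior] = float(
            (sel["true_class"] == f"sm:{behavior}").sum() / len(planted)
        )

    # sensory∩SM overlap for the paired (stimulus, behavior) classes
    if sensory_scores is None:
        sensory_scores = sensory_recovery(seed)["_scores"]
    overlap_obs = 0
    overlap_exp = 0.0
    for stim in STIMULI:
        behavior = {"sweep": "freezing", "looming": "escape", "prey": "hunting"}[stim]
        s_sel = sensory_scores[
            (sensory_scores["stimulus"] == stim) & sensory_scores["selected"]
        ]
        m_sel = scores[(scores["behavior"] == behavior) & scores["selected"]]
        s_set = set(map(tuple, s_sel[["fish", "neuron_id"]].to_numpy()))
        m_set = set(map(tuple, m_sel[["fish", "neuron_id"]].to_numpy()))
        overlap_obs += len(s_set & m_set)
        for fish in sensory_scores["fish"].unique():
            ns = (s_sel["fish"] == fish).sum()
            nm = (m_sel["fish"] == fish).sum()
            overlap_exp += ns * nm / cfg.n_neurons
    return {
        "recall_min": float(min(recalls.values())),
        "overlap_observed": int(overlap_obs),
        "overlap_expected": float(overlap_exp),
    }


# ------------------------------------------------- partial correlation --

def pc_oracle_equivalence(seed: int, n_trials: int = 50, frames_per_trial: int = 200) -> dict:
    """Residual-method vs closed-form partial correlation on a linear-Gaussian toy."""
    rng = np.random.default_rng(_spawn(seed, 3))
    z_trial = rng.random(n_trials) < 0.5
    n = n_trials * frames_per_trial
    z = np.repeat(z_trial, frames_per_trial).astype(float)
    u = rng.normal(0, 1, n)
    x = 1.5 * z + u + rng.normal(0, 0.5, n)
    y = -0.8 * z + 0.7 * u + rng.normal(0, 0.5, n)
    starts = np.arange(n_trials) * frames_per_trial
    rx = residual(x, starts, frames_per_trial, z_trial)
    ry = residual(y, starts, frames_per_trial, z_trial)
    r = np.corrcoef(np.stack([x, y, z]))
    closed = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
        (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)
    )
    return {
        "pc_residual": float(partial_corr(rx, ry)),
        "pc_closed_form": float(closed),
        "abs_difference": float(abs(partial_corr(rx, ry) - closed)),
        "n_frames": n,
    }


def _scenario_pc(scenario: str, seed: int, n_perm: int = 199) -> pd.DataFrame:
    cfg = SimConfig(scenario=scenario, seed=seed)
    recs, sched, behs, truth = generate_population(cfg)
    behavior = cfg.scenario_behavior
    stim = STIMULUS_OF_BEHAVIOR[behavior]
    wf = cfg.window_frames
    starts = sched.windows(stim, wf)
    frames = []
    for rec, beh in zip(recs, behs):
        labels = beh.labels_for(sched, stim)
        is_beh = labels == behavior
        if is_beh.sum() < 1 or (~is_beh).sum() < 2:
            continue
        nt = rec.neurons
        s_ids = nt.index[nt["true_class"] == f"sensory:{stim}"].to_numpy()
        s_res = np.stack([residual(rec.dff[n], starts, wf, is_beh) for n in s_ids])
        for area in ("tectum", "NI"):
            sm_ids = nt.index[
                (nt["true_class"] == f"sm:{behavior}") & (nt["region"] == area)
            ].to_numpy()
            if len(sm_ids) == 0:
                continue
            m_res = np.stack(
                [residual(rec.dff[n], starts, wf, is_beh) for n in sm_ids]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df = pc_test_population(
                    m_res, s_res, is_beh, n_perm=n_perm,
                    seed=_spawn(seed, 4, rec.fish_id, area == "NI"),
                )
            df["fish"] = rec.fish_id
            df["area"] = area
            df["behavior"] = behavior
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def pc_scenarios(seed: int) -> dict:
    """Calibration under H2 and power plus area specificity under H1."""
    h2 = _scenario_pc("H2", _spawn(seed, 5))
    h1 = _scenario_pc("H1", _spawn(seed, 6))
    h2_frac = area_fraction_significant(h2, "tectum", "freezing").fraction
    h1_frac = area_fraction_significant(h1, "tectum", "freezing").fraction
    out_frac = area_fraction_significant(h1, "NI", "freezing").fraction
    ks = kstest(h2["p_empirical"].to_numpy(), "uniform")
    return {
        "h2_ks_pvalue": float(ks.pvalue),
        "h2_significant_fraction": float(h2_frac),
        "h1_significant_fraction": float(h1_frac),
        "h1_out_of_area_fraction": float(out_frac),
        "n_sm_h1": int((h1["area"] == "tectum").sum()),
    }


# -------------------------------------------------------------- holdout --

def holdout_validation(seed: int, n_null: int = 100) -> dict:
    """Held-out decoding vs permuted-annotation null, noisy and noiseless."""

    def run(noise_sd, key):
        for attempt in range(30):
            cfg = SimConfig(
                n_fish=1, n_background=200, noise_sd=noise_sd,
                seed=_spawn(seed, key, attempt),
            )
            recs, sched, behs, _ = generate_population(cfg)
            labels = behs[0].labels_for(sched, "sweep")
            if (labels == "freezing").sum() >= 2 and (labels == "none").sum() >= 2:
                kernel = make_kernel(cfg.kernel_tau_s, cfg.frame_rate_hz)
                return holdout_predict(
                    recs[0], sched, behs[0], "freezing", kernel, cfg.window_frames,
                    n_null=n_null, seed=_spawn(seed, key, 99),
                )
        raise RuntimeError("no usable trial split found")

    noisy = run(0.2, 7)
    clean = run(0.0, 8)
    return {
        "accuracy": float(noisy.accuracy),
        "null_accuracy_q95": float(np.percentile(noisy.null_accuracies, 95)),
        "noiseless_accuracy": float(clean.accuracy),
    }


# ------------------------------------------------------------ physiology --

def physiology_validation(seed: int, n_beat_videos: int = 20, n_brady_trials: int = 200) -> dict:
    """Beat detection F1, rate accuracy, bradycardia ROC, classifier truth table."""
    fs = 100.0
    f1s, rate_errs = [], []
    for i in range(n_beat_videos):
        rate, _, _ = bradycardia_rate_profile(
            30.0, drop=False, seed=_spawn(seed, 9, i)
        )
        stack, true_beats, _ = generate_heart_video(
            rate, n_pixels=20, rhythmic_fraction=0.3, noise_sd=0.2,
            seed=_spawn(seed, 10, i),
        )
        _, intensity = rhythmic_pixels(stack, fs)
        beats = detect_beats(intensity, fs)
        tol = 2
        matched_det = sum(np.abs(true_beats - b).min() <= tol for b in beats)
        prec = matched_det / len(beats)
        rec = matched_det / len(true_beats)
        f1s.append(2 * prec * rec / (prec + rec))
        hr = instantaneous_hr(beats, fs, n_frames=len(rate))
        valid = ~np.isnan(hr)
        rate_errs.append(np.mean(np.abs(hr[valid] - rate[valid]) / rate[valid]))

    tp = fn = tn = fp = 0
    for i in range(n_brady_trials // 2):
        for drop in (True, False):
            rate, bw, sw = bradycardia_rate_profile(
                30.0, drop=drop, drop_n_sd=3.5, seed=_spawn(seed, 11, i, drop)
            )
            stack, _, _ = generate_heart_video(
                rate, n_pixels=20, rhythmic_fraction=0.3, noise_sd=0.1,
                seed=_spawn(seed, 12, i, drop),
            )
            _, intensity = rhythmic_pixels(stack, fs)
            hr = instantaneous_hr(detect_beats(intensity, fs), fs, n_frames=len(rate))
            flag, _ = bradycardia(hr, bw, sw, fs)
            if drop:
                tp += flag
                fn += not flag
            else:
                tn += not flag
                fp += flag

    # enumerated 16-case event-combination truth table
    window = (10, 30)
    n = 50

    def stream(flag):
        s = np.zeros(n, dtype=bool)
        if flag:
            s[15:20] = True
        return s

    agree = 0
    for movement, eye, fast, brady in itertools.product([False, True], repeat=4):
        label = classify_trial(
            stream(movement), stream(eye), stream(fast), brady, window
        ).label
        freezing = (not movement) and brady
        n_types = eye + fast + freezing
        expected = (
            "excluded" if n_types >= 2
            else "hunting" if eye
            else "escape" if fast
            else "freezing" if freezing
            else "none"
        )
        agree += label == expected
    return {
        "beat_f1_min": float(min(f1s)),
        "rate_mean_rel_error": float(np.mean(rate_errs)),
        "brady_sensitivity": tp / (tp + fn),
        "brady_specificity": tn / (tn + fp),
        "classifier_agreement": agree / 16,
    }


# ------------------------------------------------------------ determinism --

def determinism_check(seed: int, outdir) -> bool:
    """Two seeded end-to-end runs produce byte-identical directories."""
    import filecmp
    from pathlib import Path

    from visuomotor.pipeline import RunConfig, run_pipeline

    outdir = Path(outdir)
    sim = SimConfig(n_background=300, scenario="H1")
    dirs = []
    for name in ("a", "b"):
        cfg = RunConfig(
            outdir=str(outdir / name), seed=_spawn(seed, 13), sim=sim,
            n_perm=100, holdout_n_null=5,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dirs.append(run_pipeline(cfg))
    names = sorted(p.name for p in dirs[0].iterdir())
    if names != sorted(p.name for p in dirs[1].iterdir()):
        return False
    _, mismatch, errors = filecmp.cmpfiles(dirs[0], dirs[1], names, shallow=False)
    return not mismatch and not errors
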