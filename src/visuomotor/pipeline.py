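"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes simulate → physiology/classify → sensory
selection → SM selection → partial correlation → held-out decoding on
a synthetic dataset, writing CSV/JSON reports plus a run manifest into
an output directory.  Every stage derives its randomness from the
single run seed, so two runs with the same configuration produce
byte-identical output directories; re-running a stage recomputes the
same upstream state deterministically.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from visuomotor._stats import pearson
from visuomotor.data import (
    BEHAVIORS,
    STIMULI,
    STIMULUS_OF_BEHAVIOR,
    BehaviorTable,
    TrialSchedule,
)
from visuomotor.motor_surplus import (
    holdout_predict,
    motor_enhancement,
    select_sm,
    trace_surplus,
)
from visuomotor.partial_correlation import (
    area_fraction_significant,
    pc_test_population,
    residual,
)
from visuomotor.physiology import (
    bradycardia,
    classify_trial,
    detect_beats,
    heart_rate_change,
    instantaneous_hr,
    rhythmic_pixels,
)
from visuomotor.population_filters import active_neurons, colocalization_filter
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

ALL_STAGES = ("simulate", "heart", "sensory", "motor", "pc", "holdout")


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    ``seed`` governs every source of randomness, including the
    simulation (the nested ``sim.seed`` is overridden at run time).
    """

    outdir: str = "scratch/runs/default"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    r_thresh: float = 0.5
    pct_corr: float = 10.0
    pct_si: float = 15.0
    sm_pct: float = 97.0
    radius_um: float = 20.0
    min_fish: int = 2
    n_perm: int = 199
    alpha: float = 0.05
    holdout_n_null: int = 50
    stages: tuple = ALL_STAGES

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        if "sim" in d:
            d["sim"] = SimConfig(**d["sim"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, sort_keys=True, indent=2, default=float)
        f.write("\n")


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> None:
    sim = replace(cfg.sim, seed=cfg.seed)
    recs, schedule, behaviors, truth = generate_population(sim)
    state.update(sim=sim, recs=recs, schedule=schedule, behaviors=behaviors, truth=truth)
    schedule.to_csv(out / "schedule.csv")
    truth.neurons.to_csv(out / "neurons.csv", index=False)
    truth.behavior.to_csv(out / "behavior.csv", index=False)
    truth.connections.to_csv(out / "connections.csv", index=False)
    for rec in recs:
        rec.save_h5(out / f"dff_fish{rec.fish_id}.h5")


def _stage_heart(cfg: RunConfig, out: Path, state: dict) -> None:
    """Simulated side-camera physiology for fish 0's sweep trials.

    Freezing trials get a programmed heart-rate drop; the heart video →
    rhythmic pixels → beats → instantaneous rate → bradycardia chain
    then feeds the five-way trial classifier together with event
    streams consistent with the trial's annotation.
    """
    schedule: TrialSchedule = state["schedule"]
    behavior: BehaviorTable = state["behaviors"][0]
    fs = 100.0
    labels = behavior.labels_for(schedule, "sweep")
    rows = []
    ss = np.random.SeedSequence((cfg.seed, 911))
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(labels) * 2)]
    for i, label in enumerate(labels):
        drop = label == "freezing"
        rate, base_w, stim_w = bradycardia_rate_profile(
            duration_s=30.0, frame_rate_hz=fs, drop=drop, seed=seeds[2 * i]
        )
        stack, true_beats, _ = generate_heart_video(
            rate, n_pixels=20, rhythmic_fraction=0.3, noise_sd=0.1, seed=seeds[2 * i + 1],
            frame_rate_hz=fs,
        )
        _, intensity = rhythmic_pixels(stack, fs)
        beats = detect_beats(intensity, fs)
        hr = instantaneous_hr(beats, fs, n_frames=len(rate))
        flag, onset = bradycardia(hr, base_w, stim_w, fs)
        dhr = heart_rate_change(hr, stim_w[0], fs, baseline_window=base_w)
        n = len(rate)
        movement = np.zeros(n, dtype=bool)
        eye = np.zeros(n, dtype=bool)
        fast = np.zeros(n, dtype=bool)
        mid = (stim_w[0] + stim_w[1]) // 2
        if label == "escape":
            movement[mid : mid + 20] = True
            fast[mid : mid + 20] = True
        elif label == "hunting":
            movement[mid : mid + 20] = True
            eye[mid : mid + 20] = True
        tl = classify_trial(movement, eye, fast, flag, stim_w, trial_id=i, stimulus="sweep")
        rows.append(
            {
                "trial": i,
                "annotated": label,
                "bradycardia": flag,
                "onset_frame": -1 if onset is None else onset,
                "hr_change": round(dhr, 6),
                "classified": tl.label,
            }
        )
    pd.DataFrame(rows).to_csv(out / "heart_trials.csv", index=False)


def _score_sensory(cfg: RunConfig, state: dict) -> pd.DataFrame:
    """Per-fish regressor correlations and SIs for active neurons."""
    sim: SimConfig = state["sim"]
    schedule: TrialSchedule = state["schedule"]
    kernel = make_kernel(sim.kernel_tau_s, sim.frame_rate_hz)
    wf = sim.window_frames
    rows = []
    for rec, beh in zip(state["recs"], state["behaviors"]):
        flags = active_neurons(rec, schedule, beh, kernel, wf, r_thresh=cfg.r_thresh)
        active_ids = flags.loc[flags["active"], "neuron_id"].to_numpy()
        state.setdefault("active", {})[rec.fish_id] = active_ids
        for stim in STIMULI:
            reg = stimulus_regressor(schedule, stim, kernel, rec.n_frames)
            starts = schedule.windows(stim, wf)
            for nid in active_ids:
                trace = rec.dff[nid]
                rows.append(
                    {
                        "neuron_id": int(nid),
                        "fish": rec.fish_id,
                        "stimulus": stim,
                        "corr": pearson(trace, reg.values),
                        "si": sensory_index(trace, starts, wf),
                    }
                )
    return pd.DataFrame(rows)


def _stage_sensory(cfg: RunConfig, out: Path, state: dict) -> None:
    scores = _score_sensory(cfg, state)
    scores = select_sensory(scores, pct_corr=cfg.pct_corr, pct_si=cfg.pct_si)
    neurons = state["truth"].neurons.set_index(["fish", "neuron_id"])
    coords = neurons.loc[
        list(zip(scores["fish"], scores["neuron_id"])), ["x", "y", "z", "region", "true_class"]
    ].reset_index(drop=True)
    scores = pd.concat([scores.reset_index(drop=True), coords], axis=1)
    if state["sim"].n_fish > 1:
        pre = scores[scores["selected"]]
        cand = pre.rename(columns={"stimulus": "cls"})[
            ["neuron_id", "fish", "cls", "x", "y", "z"]
        ]
        filt = colocalization_filter(cand, radius_um=cfg.radius_um, min_fish=cfg.min_fish)
        scores.loc[pre.index, "selected"] = filt["kept"].to_numpy()
    state["sensory_scores"] = scores
    scores.round(6).to_csv(out / "index_table.csv", index=False)


def _stage_motor(cfg: RunConfig, out: Path, state: dict) -> None:
    sim: SimConfig = state["sim"]
    schedule: TrialSchedule = state["schedule"]
    kernel = make_kernel(sim.kernel_tau_s, sim.frame_rate_hz)
    wf = sim.window_frames
    rows = []
    enh_rows = []
    for rec, beh in zip(state["recs"], state["behaviors"]):
        active_ids = state["active"][rec.fish_id]
        for behavior in BEHAVIORS:
            stim = STIMULUS_OF_BEHAVIOR[behavior]
            starts = schedule.windows(stim, wf)
            try:
                vm = visuomotor_regressor(schedule, beh, behavior, kernel, rec.n_frames)
            except NoBehaviorTrialsError:
                warnings.warn(f"fish {rec.fish_id}: no {behavior} trials; skipped")
                continue
            msis = {}
            for nid in active_ids:
                surplus = trace_surplus(rec.dff[nid], starts, wf)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    msis[nid] = (
                        0.0 if np.std(surplus) == 0 else pearson(surplus, vm.values)
                    )
            for nid, m in msis.items():
                rows.append(
                    {"neuron_id": int(nid), "fish": rec.fish_id, "behavior": behavior, "msi": m}
                )
            labels = beh.labels_for(schedule, stim)
            beh_starts = starts[labels == behavior]
            nr_starts = starts[labels == "none"]
            if len(beh_starts) and len(nr_starts):
                sub = rec.dff[list(msis.keys())]
                curve = motor_enhancement(
                    sub, beh_starts, nr_starts, wf, np.array(list(msis.values())), behavior
                )
                for p, e in zip(curve.percentiles, curve.enhancement):
                    enh_rows.append(
                        {
                            "fish": rec.fish_id,
                            "behavior": behavior,
                            "percentile": int(p),
                            "enhancement": e,
                            "elbow": curve.elbow,
                        }
                    )
    scores = pd.DataFrame(rows)
    neurons = state["truth"].neurons.set_index(["fish", "neuron_id"])
    coords = neurons.loc[
        list(zip(scores["fish"], scores["neuron_id"])), ["x", "y", "z", "region", "true_class"]
    ].reset_index(drop=True)
    scores = pd.concat([scores.reset_index(drop=True), coords], axis=1)
    scores = select_sm(scores, pct=cfg.sm_pct, radius_um=cfg.radius_um, min_fish=cfg.min_fish)
    state["motor_scores"] = scores
    scores.round(6).to_csv(out / "motor_scores.csv", index=False)
    pd.DataFrame(enh_rows).round(6).to_csv(out / "motor_enhancement.csv", index=False)


def _stage_pc(cfg: RunConfig, out: Path, state: dict) -> None:
    """Behavior-conditioned partial-correlation test on the selected populations."""
    sim: SimConfig = state["sim"]
    schedule: TrialSchedule = state["schedule"]
    wf = sim.window_frames
    behavior = sim.scenario_behavior
    stim = STIMULUS_OF_BEHAVIOR[behavior]
    starts = schedule.windows(stim, wf)
    sens = state["sensory_scores"]
    mot = state["motor_scores"]
    results = []
    for rec, beh in zip(state["recs"], state["behaviors"]):
        labels = beh.labels_for(schedule, stim)
        is_beh = labels == behavior
        if is_beh.sum() < 1 or (~is_beh).sum() < 2:
            warnings.warn(f"fish {rec.fish_id}: unusable trial split for pc; skipped")
            continue
        s_sel = sens[
            (sens["fish"] == rec.fish_id)
            & (sens["stimulus"] == stim)
            & sens["selected"]
            & (sens["region"] == "tectum")
        ]["neuron_id"].to_numpy()
        if len(s_sel) == 0:
            warnings.warn(f"fish {rec.fish_id}: no selected sensory neurons; skipped")
            continue
        s_res = np.stack(
            [residual(rec.dff[n], starts, wf, is_beh) for n in s_sel]
        )
        for area_idx, area in enumerate(("tectum", "NI")):
            m_sel = mot[
                (mot["fish"] == rec.fish_id)
                & (mot["behavior"] == behavior)
                & mot["selected"]
                & (mot["region"] == area)
            ]["neuron_id"].to_numpy()
            if len(m_sel) == 0:
                continue
            m_res = np.stack(
                [residual(rec.dff[n], starts, wf, is_beh) for n in m_sel]
            )
            df = pc_test_population(
                m_res, s_res, is_beh, n_perm=cfg.n_perm,
                seed=int(np.random.SeedSequence((cfg.seed, rec.fish_id, area_idx)).generate_state(1)[0] % (2**31)),
            )
            df["sm_id"] = m_sel
            df["fish"] = rec.fish_id
            df["area"] = area
            df["behavior"] = behavior
            results.append(df)
    if not results:
        warnings.warn("pc stage produced no results")
        return
    pc_results = pd.concat(results, ignore_index=True)
    state["pc_results"] = pc_results
    pc_results.round(6).to_csv(out / "pc_results.csv", index=False)
    summary = {}
    for area in pc_results["area"].unique():
        res = area_fraction_significant(pc_results, area, behavior, alpha=cfg.alpha)
        summary[area] = {
            "fraction": res.fraction,
            "per_fish": res.per_fish,
            "n_sm": res.n_sm,
            "signed_rank_p": res.signed_rank_p,
        }
    _write_json(out / "pc_summary.json", summary)


def _stage_holdout(cfg: RunConfig, out: Path, state: dict) -> None:
    sim: SimConfig = state["sim"]
    schedule: TrialSchedule = state["schedule"]
    kernel = make_kernel(sim.kernel_tau_s, sim.frame_rate_hz)
    behavior = sim.scenario_behavior
    reports = {}
    for rec, beh in zip(state["recs"], state["behaviors"]):
        try:
            res = holdout_predict(
                rec, schedule, beh, behavior, kernel, sim.window_frames,
                pct=cfg.sm_pct, n_null=cfg.holdout_n_null,
                seed=int(np.random.SeedSequence((cfg.seed, 77, rec.fish_id)).generate_state(1)[0] % (2**31)),
            )
        except ValueError as e:
            reports[f"fish{rec.fish_id}"] = {"skipped": str(e)}
            continue
        reports[f"fish{rec.fish_id}"] = res.to_json_dict()
    _write_json(out / "holdout.json", reports)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "heart": _stage_heart,
    "sensory": _stage_sensory,
    "motor": _stage_motor,
    "pc": _stage_pc,
    "holdout": _stage_holdout,
}

_STAGE_DEPS = {
    "simulate": (),
    "heart": ("simulate",),
    "sensory": ("simulate",),
    "motor": ("simulate", "sensory"),
    "pc": ("simulate", "sensory", "motor"),
    "holdout": ("simulate",),
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Requested stages pull in their prerequisites automatically (the
    upstream state is recomputed deterministically from the run seed).
    A stage failure aborts with the stage name; outputs of completed
    stages are retained.
    """
    wanted: list[str] = []

    def require(stage: str) -> None:
        for dep in _STAGE_DEPS[stage]:
            require(dep)
        if stage not in wanted:
            wanted.append(stage)

    for s in config.stages:
        if s not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {s!r}")
        require(s)

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    cfg_dict = dataclasses.asdict(config)
    cfg_dict.pop("outdir")  # incidental to the results; keeps runs comparable
    manifest = {
        "config": {**cfg_dict, "stages": list(wanted)},
        "package_version": __import__("visuomotor").__version__,
    }
    for stage in wanted:
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as e:
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    _write_json(out / "manifest.json", manifest)
    return out
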