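"""Synthetic trial-structured populations with planted ground truth.

The generator mirrors the generative assumptions behind the analysis:
sensory neurons respond to every presentation of their stimulus
(amplitude drawn once per neuron, lognormal trial-to-trial jitter),
sensorimotor (SM) neurons respond only in trials of their paired
stimulus annotated with their behavior, mixed neurons carry both
components, background neurons are noise.  All responses are unit
boxcars scaled by amplitude, convolved with a single-exponential
calcium kernel (tau 3.5 s by default — nuclear GCaMP6s is slow), and
contaminated with i.i.d. Gaussian noise.  The interstimulus interval
is compressed from the experimental 2 min to 20 s by default; it only
pads the recording and is configurable back.

Connectivity scenarios plant the two hypotheses the
partial-correlation test discriminates:

* **H1** (connected): each SM neuron's within-trial activity adds a
  weighted sum of a sparse subset of sensory neurons' single-trial
  fluctuations, so S and SM residuals share variance beyond behavior.
* **H2** (behavior-only): SM neurons share a common per-trial
  "decision" gain but their within-trial fluctuations are independent
  of the sensory population.

A separate generator builds rhythmic heart-pixel videos with known
beat times and optional programmed bradycardia for the physiology
front-end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from visuomotor.data import (
    BEHAVIOR_OF_STIMULUS,
    BEHAVIORS,
    STIMULI,
    STIMULUS_OF_BEHAVIOR,
    BehaviorTable,
    PopulationRecording,
    TrialSchedule,
)
from visuomotor.regressors import convolve_causal, make_kernel


def _default_behavior_prob() -> dict[str, dict[str, float]]:
    # Qualitative behavior frequencies: sweep is freezing-dominant,
    # looming escape-dominant, prey hunting-dominant.
    return {
        "sweep": {"freezing": 0.5, "escape": 0.125},
        "looming": {"escape": 0.625, "freezing": 0.125},
        "prey": {"hunting": 0.5},
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic populations.

    Defaults reproduce the experimental trial structure (8 repeats of
    each of three stimuli, 4 s presentations, 2 Hz volumetric imaging)
    with a compressed 20 s ISI, a 1,000-neuron active-scale population
    per fish with 2.5% planted sensory neurons per stimulus, and
    response amplitude three times the noise SD.
    """

    n_fish: int = 3
    n_sensory_per_stimulus: int = 25
    n_sm_per_behavior: int = 25
    n_mixed: int = 5
    n_background: int = 770
    n_repeats: int = 8
    stim_duration_s: float = 4.0
    isi_s: float = 20.0
    frame_rate_hz: float = 2.0
    kernel_tau_s: float = 3.5
    tail_tau_mult: float = 2.0          # post-stimulus window tail = 2 * tau
    noise_sd: float = 0.2               # ΔF/F units
    sensory_amp: float = 0.6            # amplitude SNR 3 vs noise_sd
    sm_amp: float = 0.6
    amp_spread_sd: float = 0.2          # lognormal sigma, per-neuron amplitude
    trial_jitter_sd: float = 0.2        # lognormal sigma, per-trial gain
    behavior_prob: dict = field(default_factory=_default_behavior_prob)
    scenario: str = "none"              # none | H1 | H2
    scenario_behavior: str = "freezing"
    n_connections: int = 3
    connection_weight: float = 0.8
    fluct_sd: float = 0.3               # shared within-trial co-fluctuation SD (pre-kernel)
    private_fluct_ratio: float = 0.5    # private fluctuation SD as a fraction of fluct_sd
    sm_tectum_fraction: float = 0.6     # remaining SM neurons sit in the NI
    coord_jitter_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_fish,
            self.n_sensory_per_stimulus,
            self.n_sm_per_behavior,
            self.n_mixed,
            self.n_background,
            self.n_repeats,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.frame_rate_hz <= 0 or self.stim_duration_s <= 0:
            raise ValueError("frame_rate_hz and stim_duration_s must be positive")
        if self.scenario not in ("none", "H1", "H2"):
            raise ValueError("scenario must be one of none, H1, H2")
        for stim, probs in self.behavior_prob.items():
            if stim not in STIMULI:
                raise ValueError(f"unknown stimulus {stim!r} in behavior_prob")
            if any(p < 0 for p in probs.values()) or sum(probs.values()) > 1.0 + 1e-12:
                raise ValueError(f"behavior probabilities for {stim!r} must be in [0,1] and sum <= 1")

    # Derived geometry -------------------------------------------------
    @property
    def stim_frames(self) -> int:
        return int(round(self.stim_duration_s * self.frame_rate_hz))

    @property
    def window_frames(self) -> int:
        tail = self.tail_tau_mult * self.kernel_tau_s
        return self.stim_frames + int(round(tail * self.frame_rate_hz))

    @property
    def n_neurons(self) -> int:
        return (
            len(STIMULI) * self.n_sensory_per_stimulus
            + len(BEHAVIORS) * self.n_sm_per_behavior
            + self.n_mixed
            + self.n_background
        )


@dataclass
class GroundTruth:
    """Planted truth for a generated dataset.

    ``neurons``: per (fish, neuron) true class (``sensory:<stimulus>``,
    ``sm:<behavior>``, ``mixed:<stimulus>`` or ``background``) plus
    region and coordinates.  ``behavior``: per (fish, trial) label.
    ``connections``: planted S→SM edges under scenario H1.
    """

    neurons: pd.DataFrame
    behavior: pd.DataFrame
    connections: pd.DataFrame
    warnings: list = field(default_factory=list)


# Cluster centers (um, shared reference frame) for planted classes; the
# tectum occupies the central box, the NI a ventro-posterior one.
_CLASS_CENTERS = {
    "sensory:sweep": (80.0, 100.0, 50.0),
    "sensory:looming": (110.0, 100.0, 50.0),
    "sensory:prey": (140.0, 100.0, 50.0),
    "sm:freezing:tectum": (80.0, 150.0, 60.0),
    "sm:escape:tectum": (110.0, 150.0, 60.0),
    "sm:hunting:tectum": (140.0, 150.0, 60.0),
    "sm:freezing:NI": (50.0, 220.0, 40.0),
    "sm:escape:NI": (80.0, 220.0, 40.0),
    "sm:hunting:NI": (110.0, 220.0, 40.0),
    "mixed:sweep": (95.0, 120.0, 55.0),
    "mixed:looming": (110.0, 120.0, 55.0),
    "mixed:prey": (125.0, 120.0, 55.0),
}


def make_schedule(config: SimConfig) -> TrialSchedule:
    """Interleaved schedule: each repeat cycle presents all stimuli once."""
    fr = config.frame_rate_hz
    pre = int(round(10.0 * fr))
    gap = config.stim_frames + int(round(config.isi_s * fr))
    stimulus, onsets, durations = [], [], []
    onset = pre
    for _ in range(config.n_repeats):
        for s in STIMULI:
            stimulus.append(s)
            onsets.append(onset)
            durations.append(config.stim_frames)
            onset += gap
    return TrialSchedule(np.array(stimulus, dtype=object), np.array(onsets), np.array(durations))


def _draw_behavior_labels(
    config: SimConfig, schedule: TrialSchedule, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for t in range(schedule.n_trials):
        stim = schedule.stimulus[t]
        probs = config.behavior_prob.get(stim, {})
        u = rng.random()
        label = "none"
        acc = 0.0
        for beh, p in probs.items():
            acc += p
            if u < acc:
                label = beh
                break
        rows.append({"trial_id": t, "stimulus": stim, "label": label})
    return pd.DataFrame(rows)


def _neuron_table(config: SimConfig, rng: np.random.Generator, fish: int) -> pd.DataFrame:
    rows = []
    nid = 0

    def add(true_class: str, region: str, center_key: str | None, n: int):
        nonlocal nid
        for _ in range(n):
            if center_key is None:
                xyz = rng.uniform([0, 0, 0], [250, 250, 100])
            else:
                c = np.array(_CLASS_CENTERS[center_key])
                xyz = c + rng.normal(0, config.coord_jitter_um, 3)
            rows.append(
                {
                    "neuron_id": nid,
                    "fish": fish,
                    "x": xyz[0],
                    "y": xyz[1],
                    "z": xyz[2],
                    "region": region,
                    "true_class": true_class,
                }
            )
            nid += 1

    for s in STIMULI:
        add(f"sensory:{s}", "tectum", f"sensory:{s}", config.n_sensory_per_stimulus)
    n_tect = int(round(config.sm_tectum_fraction * config.n_sm_per_behavior))
    for b in BEHAVIORS:
        add(f"sm:{b}", "tectum", f"sm:{b}:tectum", n_tect)
        add(f"sm:{b}", "NI", f"sm:{b}:NI", config.n_sm_per_behavior - n_tect)
    mixed_stims = [STIMULI[i % len(STIMULI)] for i in range(config.n_mixed)]
    for s in mixed_stims:
        add(f"mixed:{s}", "tectum", f"mixed:{s}", 1)
    add("background", "other", None, config.n_background)
    return pd.DataFrame(rows)


def _fish_traces(
    config: SimConfig,
    schedule: TrialSchedule,
    behavior: pd.DataFrame,
    neurons: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Build one fish's ΔF/F matrix; returns (dff, connections)."""
    fr = config.frame_rate_hz
    n_frames = int(schedule.onset_frame[-1] + config.window_frames + round(config.isi_s * fr))
    kernel = make_kernel(config.kernel_tau_s, fr)
    labels = behavior.set_index("trial_id")["label"]

    stim_trials = {s: schedule.trials_of(s) for s in STIMULI}

    def windows_of(stim: str) -> np.ndarray:
        return schedule.onset_frame[stim_trials[stim]]

    n_neurons = len(neurons)
    drive = np.zeros((n_neurons, n_frames))
    # Per-sensory-neuron stochastic component (deviation from the mean
    # response), reused by scenario H1 to wire SM neurons.
    sensory_stoch: dict[int, np.ndarray] = {}

    # Under a connectivity scenario, sensory trial-to-trial variability
    # has a population-shared part (common response gain and common
    # within-trial co-fluctuation — attention/state-like signals that
    # move the whole population together) on top of private jitter.
    # Connectivity inference hinges on exactly these single-trial
    # fluctuations, so they are modeled explicitly here.
    shared: dict[str, dict] = {}
    if config.scenario != "none":
        for s in STIMULI:
            trials = stim_trials[s]
            # co-fluctuations span the full trial window: population
            # state keeps varying while the calcium response decays
            shared[s] = {
                "gain": {t: rng.lognormal(0.0, config.trial_jitter_sd) for t in trials},
                "fluct": {
                    t: rng.normal(0, config.fluct_sd, config.window_frames) for t in trials
                },
            }

    def sensory_component(nid: int, stim: str, amp_base: float) -> np.ndarray:
        amp = amp_base * rng.lognormal(0.0, config.amp_spread_sd)
        d = np.zeros(n_frames)
        mean_gain = np.exp(config.trial_jitter_sd**2 / 2.0)
        det = np.zeros(n_frames)
        for t in stim_trials[stim]:
            onset = schedule.onset_frame[t]
            sl = slice(onset, onset + config.stim_frames)
            g = rng.lognormal(0.0, config.trial_jitter_sd)
            if config.scenario != "none":
                g *= shared[stim]["gain"][t]
                wsl = slice(onset, onset + config.window_frames)
                d[wsl] += shared[stim]["fluct"][t] + rng.normal(
                    0,
                    config.private_fluct_ratio * config.fluct_sd,
                    config.window_frames,
                )
                mean_gain = np.exp(config.trial_jitter_sd**2)
            d[sl] += amp * g
            det[sl] += amp * mean_gain
        sensory_stoch[nid] = d - det
        return d

    def sm_component(stim: str, beh: str, amp_base: float) -> np.ndarray:
        amp = amp_base * rng.lognormal(0.0, config.amp_spread_sd)
        d = np.zeros(n_frames)
        for t in stim_trials[stim]:
            if labels.loc[t] == beh:
                g = rng.lognormal(0.0, config.trial_jitter_sd)
                onset = schedule.onset_frame[t]
                d[onset : onset + config.stim_frames] += amp * g
        return d

    sm_rows: list[tuple[int, str]] = []
    for _, row in neurons.iterrows():
        nid = int(row["neuron_id"])
        cls = row["true_class"]
        if cls.startswith("sensory:"):
            drive[nid] = sensory_component(nid, cls.split(":")[1], config.sensory_amp)
        elif cls.startswith("sm:"):
            beh = cls.split(":")[1]
            stim = STIMULUS_OF_BEHAVIOR[beh]
            drive[nid] = sm_component(stim, beh, config.sm_amp)
            sm_rows.append((nid, beh))
        elif cls.startswith("mixed:"):
            stim = cls.split(":")[1]
            beh = BEHAVIOR_OF_STIMULUS[stim]
            drive[nid] = sensory_component(nid, stim, config.sensory_amp) + sm_component(
                stim, beh, config.sm_amp
            )

    connections: list[dict] = []
    scen_beh = config.scenario_behavior
    scen_stim = STIMULUS_OF_BEHAVIOR[scen_beh]
    if config.scenario == "H1":
        sensory_pool = neurons.index[
            neurons["true_class"] == f"sensory:{scen_stim}"
        ].to_numpy()
        for nid, beh in sm_rows:
            if beh != scen_beh:
                continue
            if neurons.loc[nid, "region"] != "tectum":
                continue  # connections confined to the tectum
            k = min(config.n_connections, len(sensory_pool))
            src = rng.choice(sensory_pool, size=k, replace=False)
            w = config.connection_weight / k
            for j in src:
                drive[nid] += w * sensory_stoch[int(j)]
                connections.append({"src": int(j), "dst": nid, "weight": w})
    elif config.scenario == "H2":
        # Common per-trial decision gain shared by all SM neurons of the
        # scenario behavior, plus independent within-trial fluctuations
        # of the same scale H1 would inject.
        decision = {
            t: rng.lognormal(0.0, config.trial_jitter_sd) for t in stim_trials[scen_stim]
        }
        for nid, beh in sm_rows:
            if beh != scen_beh:
                continue
            for t in stim_trials[scen_stim]:
                onset = schedule.onset_frame[t]
                sl = slice(onset, onset + config.stim_frames)
                if labels.loc[t] == scen_beh:
                    drive[nid, sl] *= decision[t]
                wsl = slice(onset, onset + config.window_frames)
                drive[nid, wsl] += rng.normal(
                    0, config.connection_weight * config.fluct_sd, config.window_frames
                )

    dff = np.empty_like(drive)
    for i in range(n_neurons):
        dff[i] = convolve_causal(drive[i], kernel)
    if config.noise_sd > 0:
        dff += rng.normal(0, config.noise_sd, dff.shape)
    return dff, pd.DataFrame(connections, columns=["src", "dst", "weight"])


def generate_population(
    config: SimConfig,
) -> tuple[list[PopulationRecording], TrialSchedule, list[BehaviorTable], GroundTruth]:
    """Generate per-fish recordings, a shared schedule, behavior tables and truth.

    Deterministic given ``config.seed``: the same config yields
    bit-identical outputs.
    """
    ss = np.random.SeedSequence(config.seed)
    schedule = make_schedule(config)
    recordings, behavior_tables = [], []
    neuron_frames, behavior_frames, conn_frames = [], [], []
    warn_flags: list[str] = []
    for fish, child in enumerate(ss.spawn(config.n_fish)):
        rng = np.random.default_rng(child)
        behavior = _draw_behavior_labels(config, schedule, rng)
        neurons = _neuron_table(config, rng, fish)
        dff, conns = _fish_traces(config, schedule, behavior, neurons, rng)
        conns = conns.assign(fish=fish)
        recordings.append(
            PopulationRecording(dff, config.frame_rate_hz, fish, neurons)
        )
        behavior_tables.append(BehaviorTable(behavior))
        neuron_frames.append(neurons)
        behavior_frames.append(behavior.assign(fish=fish))
        conn_frames.append(conns)
        for beh in BEHAVIORS:
            stim = STIMULUS_OF_BEHAVIOR[beh]
            if not (behavior.query("stimulus == @stim")["label"] == beh).any():
                warn_flags.append(f"fish {fish}: behavior {beh!r} occurs in no trial")
    truth = GroundTruth(
        neurons=pd.concat(neuron_frames, ignore_index=True),
        behavior=pd.concat(behavior_frames, ignore_index=True),
        connections=pd.concat(conn_frames, ignore_index=True),
        warnings=warn_flags,
    )
    return recordings, schedule, behavior_tables, truth


def generate_connectivity_scenario(
    config: SimConfig,
) -> tuple[list[PopulationRecording], TrialSchedule, list[BehaviorTable], GroundTruth]:
    """Generate a population under an explicit connectivity hypothesis.

    Requires ``config.scenario`` to be ``"H1"`` or ``"H2"``; with
    ``"none"`` the traces are the plain population (no modification).
    """
    if config.scenario not in ("H1", "H2", "none"):
        raise ValueError("scenario must be H1, H2 or none")
    return generate_population(config)


def generate_heart_video(
    rate_profile: np.ndarray,
    n_pixels: int = 20,
    rhythmic_fraction: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
    frame_rate_hz: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rhythmic heart-pixel stack with known beat times.

    Rhythmic pixels oscillate with instantaneous frequency
    ``rate_profile`` (Hz per frame, shared phase, per-pixel amplitude);
    the rest are pure noise.  Returns ``(stack, beat_frames,
    rhythmic_mask)`` where beats are the frames at which the shared
    phase crosses multiples of 2*pi (the intensity peaks).

    Raises ``ValueError`` when the profile leaves (1, 6) Hz or
    violates Nyquist at the given frame rate.
    """
    rate_profile = np.asarray(rate_profile, dtype=np.float64)
    if np.any(rate_profile <= 1.0) or np.any(rate_profile >= 6.0):
        raise ValueError("rate profile must stay within (1, 6) Hz")
    if frame_rate_hz < 2.0 * rate_profile.max():
        raise ValueError("frame rate violates Nyquist for the rate profile")
    rng = np.random.default_rng(seed)
    phase = 2 * np.pi * np.cumsum(rate_profile) / frame_rate_hz
    phase -= phase[0]  # beat (peak) at frame 0
    n_frames = rate_profile.size
    n_rhythmic = int(round(rhythmic_fraction * n_pixels))
    mask = np.zeros(n_pixels, dtype=bool)
    mask[:n_rhythmic] = True
    signal = 0.5 + 0.5 * np.cos(phase)
    stack = np.full((n_pixels, n_frames), 0.5)
    if n_rhythmic:
        amps = rng.uniform(0.5, 1.5, n_rhythmic)
        stack[mask] = 0.5 + amps[:, None] * (signal - 0.5)
    if noise_sd > 0:
        stack += rng.normal(0, noise_sd, stack.shape)
    ks = np.arange(0, int(np.floor(phase[-1] / (2 * np.pi))) + 1)
    beat_frames = np.searchsorted(phase, 2 * np.pi * ks - 1e-9)
    return stack, beat_frames.astype(np.int64), mask


def bradycardia_rate_profile(
    duration_s: float,
    frame_rate_hz: float = 100.0,
    baseline_hz: float = 3.2,
    wander_sd_hz: float = 0.3,
    wander_smooth_s: float = 1.0,
    drop: bool = False,
    drop_n_sd: float = 3.5,
    stim_onset_s: float = 15.0,
    stim_duration_s: float = 4.0,
    recovery_s: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[int, int], tuple[int, int]]:
    """Heart-rate profile for one trial, optionally with a programmed drop.

    The baseline rate wanders smoothly (Gaussian noise low-pass
    filtered over ``wander_smooth_s``, rescaled to ``wander_sd_hz``).
    With ``drop=True`` the rate steps down by ``drop_n_sd`` baseline
    SDs at a point inside the stimulus window and recovers after
    ``recovery_s``.  Returns ``(rate_profile, baseline_window,
    stimulus_window)`` in frames.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate_hz))
    wander = gaussian_filter1d(rng.normal(0, 1, n), wander_smooth_s * frame_rate_hz)
    sd = wander.std()
    if sd > 0:
        wander *= wander_sd_hz / sd
    rate = baseline_hz + wander
    s0 = int(round(stim_onset_s * frame_rate_hz))
    s1 = s0 + int(round(stim_duration_s * frame_rate_hz))
    if drop:
        # The drop is programmed relative to this trial's own baseline
        # statistics (mean and SD of the pre-stimulus rate), matching how
        # bradycardia is defined: an excursion below the baseline mean
        # measured in baseline SDs.
        base_m, base_sd = rate[:s0].mean(), rate[:s0].std()
        onset = s0 + int(rng.integers(0, max(1, (s1 - s0) // 2)))
        end = min(n, onset + int(round(recovery_s * frame_rate_hz)))
        rate[onset:end] = base_m - drop_n_sd * max(base_sd, 1e-6)
    np.clip(rate, 1.05, 5.95, out=rate)
    baseline_window = (0, s0)
    return rate, baseline_window, (s0, s1)
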