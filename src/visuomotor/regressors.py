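"""Stimulus and visuomotor regressors.

A regressor is the expected calcium trace of a neuron that responds as a
unit boxcar during certain stimulus presentations: the boxcar indicator
is convolved causally with a peak-normalized exponential calcium kernel.
The *stimulus* regressor marks every presentation of one stimulus type;
the *visuomotor* regressor marks only those presentations that occurred
in trials annotated with a given behavior, so it is the template for a
neuron gated by behavior rather than by the stimulus alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from visuomotor.data import STIMULUS_OF_BEHAVIOR, BehaviorTable, TrialSchedule


class NoBehaviorTrialsError(ValueError):
    """Raised when a visuomotor regressor is requested for a behavior that never occurred."""


@dataclass
class Regressor:
    """Per-frame regressor values with provenance.

    ``kind`` is ``"stimulus"`` or ``"visuomotor"``; ``behavior`` is set
    for visuomotor regressors only.
    """

    values: np.ndarray
    kind: str
    stimulus_type: str
    behavior: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"frame": np.arange(len(self.values)), "value": self.values}).to_csv(
            path, index=False
        )


def make_kernel(tau_s: float, frame_rate_hz: float) -> np.ndarray:
    """Discretized exponential calcium kernel.

    The kernel is ``exp(-t / tau)`` sampled at the frame rate,
    peak-normalized (first sample 1.0) and truncated where the amplitude
    falls below 1% of the peak, i.e. at ``t = tau * ln(100)``.

    Parameters
    ----------
    tau_s
        Decay time constant in seconds.  Must span at least one frame;
        a tau shorter than one frame period cannot be represented at
        the sampling rate.
    frame_rate_hz
        Imaging frame rate in Hz.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    if tau_s * frame_rate_hz < 1.0:
        raise ValueError(
            f"tau ({tau_s} s) is shorter than one frame at {frame_rate_hz} Hz"
        )
    n = int(np.ceil(tau_s * np.log(100.0) * frame_rate_hz)) + 1
    t = np.arange(n) / frame_rate_hz
    return np.exp(-t / tau_s)


def convolve_causal(indicator: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal (left-aligned) convolution truncated to the indicator's length.

    The output at frame f depends only on indicator values at frames
    <= f, so the regressor is exactly zero strictly before the first
    event onset.
    """
    return np.convolve(indicator, kernel)[: len(indicator)]


def _boxcar(
    schedule: TrialSchedule, trial_idx: np.ndarray, n_frames: int
) -> np.ndarray:
    box = np.zeros(n_frames)
    for i in trial_idx:
        on = schedule.onset_frame[i]
        box[on : on + schedule.duration_frames[i]] = 1.0
    return box


def stimulus_regressor(
    schedule: TrialSchedule, stimulus_type: str, kernel: np.ndarray, n_frames: int
) -> Regressor:
    """Kernel-convolved indicator of every presentation of ``stimulus_type``.

    Raises ``KeyError`` if the schedule contains no presentation of the
    requested stimulus.
    """
    trials = schedule.trials_of(stimulus_type)
    values = convolve_causal(_boxcar(schedule, trials, n_frames), kernel)
    return Regressor(values, "stimulus", stimulus_type)


def visuomotor_regressor(
    schedule: TrialSchedule,
    behavior_table: BehaviorTable,
    behavior: str,
    kernel: np.ndarray,
    n_frames: int,
) -> Regressor:
    """Kernel-convolved indicator of the behavior's stimulus in behavior trials only.

    The behavior's primary stimulus is fixed by the sweep→freezing,
    looming→escape, prey→hunting pairing.  Only presentations of that
    stimulus whose trial is annotated with ``behavior`` contribute a
    boxcar.  By construction the result is pointwise <= the stimulus
    regressor for the same stimulus and kernel.

    Raises
    ------
    NoBehaviorTrialsError
        If the behavior occurs in no trial of its primary stimulus.
    """
    stimulus_type = STIMULUS_OF_BEHAVIOR[behavior]
    stim_trials = schedule.trials_of(stimulus_type)
    labels = behavior_table.labels_for(schedule, stimulus_type)
    beh_trials = stim_trials[labels == behavior]
    if beh_trials.size == 0:
        raise NoBehaviorTrialsError(
            f"behavior {behavior!r} occurs in no {stimulus_type!r} trial"
        )
    values = convolve_causal(_boxcar(schedule, beh_trials, n_frames), kernel)
    return Regressor(values, "visuomotor", stimulus_type, behavior)
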