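"""Core data containers shared by all analysis stages.

The containers are deliberately thin: a recording is a neurons x frames
ΔF/F matrix plus a neuron table, a schedule is an ordered list of
stimulus presentations, and a behavior table holds one label per trial.
All heavier structure (windows, regressors, indices) is derived on
demand by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Stimulus types used throughout, in canonical order.
STIMULI: tuple[str, ...] = ("sweep", "looming", "prey")

#: Each stimulus's primary evoked behavior (sweep drives freezing,
#: looming drives escape, prey drives hunting).
BEHAVIOR_OF_STIMULUS: dict[str, str] = {
    "sweep": "freezing",
    "looming": "escape",
    "prey": "hunting",
}

#: Inverse pairing: the stimulus whose presentations define a behavior's
#: visuomotor regressor.
STIMULUS_OF_BEHAVIOR: dict[str, str] = {b: s for s, b in BEHAVIOR_OF_STIMULUS.items()}

BEHAVIORS: tuple[str, ...] = tuple(BEHAVIOR_OF_STIMULUS[s] for s in STIMULI)

#: Valid per-trial behavior annotations.
TRIAL_LABELS: tuple[str, ...] = ("freezing", "escape", "hunting", "none", "excluded")


@dataclass
class TrialSchedule:
    """Ordered stimulus presentations.

    Parameters
    ----------
    stimulus
        Stimulus type of each presentation, in presentation order.
    onset_frame
        Frame index at which each presentation starts.
    duration_frames
        Length of each presentation in frames.
    """

    stimulus: np.ndarray
    onset_frame: np.ndarray
    duration_frames: np.ndarray

    def __post_init__(self) -> None:
        self.stimulus = np.asarray(self.stimulus, dtype=object)
        self.onset_frame = np.asarray(self.onset_frame, dtype=np.int64)
        self.duration_frames = np.asarray(self.duration_frames, dtype=np.int64)
        if not (len(self.stimulus) == len(self.onset_frame) == len(self.duration_frames)):
            raise ValueError("schedule columns must have equal length")
        if np.any(np.diff(self.onset_frame) < 0):
            raise ValueError("presentations must be ordered by onset")

    @property
    def n_trials(self) -> int:
        return len(self.stimulus)

    def trials_of(self, stimulus: str) -> np.ndarray:
        """Indices (into the schedule) of all presentations of ``stimulus``."""
        idx = np.flatnonzero(self.stimulus == stimulus)
        if idx.size == 0:
            raise KeyError(f"no presentations of stimulus {stimulus!r} in schedule")
        return idx

    def windows(self, stimulus: str, window_frames: int) -> np.ndarray:
        """Per-trial window start frames for ``stimulus``.

        A trial window starts at stimulus onset and spans
        ``window_frames`` frames (stimulus duration plus a post-stimulus
        tail chosen by the caller); all windows of one stimulus share a
        length so traces can be averaged across repeats.
        """
        return self.onset_frame[self.trials_of(stimulus)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus": self.stimulus,
                "onset_frame": self.onset_frame,
                "duration_frames": self.duration_frames,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSchedule":
        return cls(
            df["stimulus"].to_numpy(dtype=object),
            df["onset_frame"].to_numpy(),
            df["duration_frames"].to_numpy(),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialSchedule":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class BehaviorTable:
    """Per-trial behavior labels plus optional per-frame indicators.

    ``trials`` has one row per schedule entry with columns
    ``trial_id`` (schedule index), ``stimulus``, and ``label`` (one of
    :data:`TRIAL_LABELS`).  ``movement`` is an optional per-imaging-frame
    boolean movement indicator used by the active-neuron filter.
    """

    trials: pd.DataFrame
    movement: np.ndarray | None = None

    def __post_init__(self) -> None:
        required = {"trial_id", "stimulus", "label"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"behavior table missing columns: {sorted(missing)}")
        bad = set(self.trials["label"]) - set(TRIAL_LABELS)
        if bad:
            raise ValueError(f"unknown trial labels: {sorted(bad)}")

    def labels_for(self, schedule: TrialSchedule, stimulus: str) -> np.ndarray:
        """Behavior labels of all presentations of ``stimulus``, in order."""
        idx = schedule.trials_of(stimulus)
        by_id = self.trials.set_index("trial_id")["label"]
        return by_id.loc[idx].to_numpy(dtype=object)

    def trials_with(self, schedule: TrialSchedule, stimulus: str, behavior: str) -> np.ndarray:
        """Positions (within the stimulus's trials) annotated with ``behavior``."""
        return np.flatnonzero(self.labels_for(schedule, stimulus) == behavior)

    def to_csv(self, path: str | Path) -> None:
        self.trials.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BehaviorTable":
        return cls(pd.read_csv(path))


@dataclass
class PopulationRecording:
    """One fish's ΔF/F matrix with neuron metadata.

    ``dff`` is neurons x frames (float).  ``neurons`` has one row per
    neuron: ``neuron_id``, ``x``, ``y``, ``z`` (shared reference frame,
    micrometers) and ``region`` (brain-area label).  Synthetic
    recordings add a ``true_class`` column.
    """

    dff: np.ndarray
    frame_rate_hz: float
    fish_id: int
    neurons: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=np.float64))
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if len(self.neurons) and len(self.neurons) != self.dff.shape[0]:
            raise ValueError("neuron table length must match dff rows")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    def save_h5(self, path: str | Path) -> None:
        """Write traces to HDF5 (dataset ``dff``, float32) with a sidecar neuron CSV."""
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as f:
            # track_times=False keeps files byte-identical across runs
            f.create_dataset("dff", data=self.dff.astype(np.float32), track_times=False)
            f.attrs["frame_rate_hz"] = self.frame_rate_hz
            f.attrs["fish_id"] = self.fish_id
        if len(self.neurons):
            self.neurons.to_csv(path.with_suffix(".neurons.csv"), index=False)

    @classmethod
    def load_h5(cls, path: str | Path) -> "PopulationRecording":
        import h5py

        path = Path(path)
        with h5py.File(path, "r") as f:
            dff = f["dff"][:]
            fr = float(f.attrs["frame_rate_hz"])
            fish = int(f.attrs["fish_id"])
        neurons_csv = path.with_suffix(".neurons.csv")
        neurons = pd.read_csv(neurons_csv) if neurons_csv.exists() else pd.DataFrame()
        return cls(dff, fr, fish, neurons)


def window_slices(starts: np.ndarray, window_frames: int) -> list[slice]:
    """Equal-length trial-window slices from start frames."""
    return [slice(int(s), int(s) + int(window_frames)) for s in starts]


def concat_windows(trace: np.ndarray, starts: np.ndarray, window_frames: int) -> np.ndarray:
    """Trace values over the concatenated trial windows (n_windows * window_frames,)."""
    return np.concatenate([trace[s] for s in window_slices(starts, window_frames)])
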