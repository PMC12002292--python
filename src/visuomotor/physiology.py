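"""Optical heart-rate extraction, bradycardia detection, trial classification.

The heart of a head-fixed larva is visible to a side camera: pixels
over the beating heart oscillate at the cardiac rate (1.5–5 Hz in
larval zebrafish).  Heart rate per video frame is recovered by
(1) masking rhythmically active pixels by their spectral band-power
fraction, (2) detecting intensity peaks (beats), and (3) converting
inter-beat intervals to an instantaneous rate.  Bradycardia — a drop
of more than 3 baseline SDs with onset during stimulus presentation —
is the cardiac signature of freezing and, combined with movement,
eye-convergence and fast-swim event streams, drives the five-way
trial classification (freezing / escape / hunting / none / excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend, find_peaks, periodogram
from scipy.stats import median_abs_deviation

HEART_BAND_HZ = (1.5, 5.0)


def rhythmic_pixels(
    pixel_stack: np.ndarray,
    frame_rate_hz: float,
    band_hz: tuple[float, float] = HEART_BAND_HZ,
    min_fraction: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask pixels whose spectral power concentrates in the heart band.

    For each pixel the fraction of total (non-DC) periodogram power
    inside ``band_hz`` is computed; pixels in the top quartile of that
    fraction, and above the absolute floor ``min_fraction``, form the
    mask.  Returns ``(mask, intensity)`` where ``intensity`` is the
    mean trace over masked pixels.

    Raises ``ValueError`` when no pixel qualifies ("no rhythmic
    pixels") or when the frame rate undersamples the band.
    """
    pixel_stack = np.atleast_2d(np.asarray(pixel_stack, dtype=np.float64))
    if frame_rate_hz < 2 * band_hz[1]:
        raise ValueError("frame rate must be at least twice the band upper edge")
    freqs, power = periodogram(pixel_stack, fs=frame_rate_hz, axis=1)
    nondc = freqs > 0
    total = power[:, nondc].sum(axis=1)
    in_band = nondc & (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, power[:, in_band].sum(axis=1) / total, 0.0)
    # adaptive threshold: top quartile of the band-fraction distribution,
    # floored at the absolute minimum; the 'lower' quantile keeps the
    # threshold at the background level instead of interpolating into
    # the rhythmic cluster when rhythmic pixels exceed a quartile
    thresh = max(min_fraction, float(np.quantile(frac, 0.75, method="lower")))
    mask = frac >= thresh
    if not mask.any():
        raise ValueError("no rhythmic pixels")
    return mask, pixel_stack[mask].mean(axis=0)


def detect_beats(
    intensity: np.ndarray,
    frame_rate_hz: float,
    band_upper_hz: float = HEART_BAND_HZ[1],
    prominence_k: float = 2.0,
    smooth_s: float = 0.03,
) -> np.ndarray:
    """Heart-beat frames: prominent local maxima of the intensity trace.

    The trace is lightly low-pass filtered (Gaussian, ``smooth_s``
    seconds — well below one cardiac period, so peaks are preserved
    while frame noise that would mislocalize them is removed).  The
    minimum inter-peak distance is one period at the band's upper edge;
    the prominence floor is ``prominence_k`` times the MAD of the
    linearly detrended signal, which rejects noise ripples without a
    hand-set amplitude scale.
    """
    from scipy.ndimage import gaussian_filter1d

    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.size < 2 * frame_rate_hz:
        raise ValueError("signal shorter than 2 s")
    sigma = smooth_s * frame_rate_hz
    smoothed = gaussian_filter1d(intensity, sigma) if sigma >= 0.5 else intensity
    mad = median_abs_deviation(detrend(smoothed))
    if mad == 0:
        raise ValueError("flat signal: no beats detectable")
    peaks, _ = find_peaks(
        smoothed,
        distance=max(1, int(round(frame_rate_hz / band_upper_hz))),
        prominence=prominence_k * mad,
    )
    if peaks.size < 2:
        raise ValueError("fewer than 2 beats detected")
    return peaks


def instantaneous_hr(
    beat_frames: np.ndarray,
    frame_rate_hz: float,
    n_frames: int | None = None,
    interpolate: bool = False,
) -> np.ndarray:
    """Per-frame heart rate (Hz) from beat times.

    Each frame between two consecutive beats gets the reciprocal of
    that inter-beat interval; the series is defined between the first
    and last beat and ``nan`` elsewhere.  With ``interpolate=True``
    rates are interpolated linearly between interval midpoints instead
    of piecewise-constant steps.
    """
    beat_frames = np.asarray(beat_frames, dtype=np.int64)
    if beat_frames.size < 2:
        raise ValueError("need at least 2 beats")
    if np.any(np.diff(beat_frames) <= 0):
        raise ValueError("beat frames must be strictly increasing")
    if n_frames is None:
        n_frames = int(beat_frames[-1]) + 1
    hr = np.full(n_frames, np.nan)
    intervals_s = np.diff(beat_frames) / frame_rate_hz
    rates = 1.0 / intervals_s
    if interpolate:
        mids = (beat_frames[:-1] + beat_frames[1:]) / 2.0
        span = np.arange(int(beat_frames[0]), min(n_frames, int(beat_frames[-1]) + 1))
        hr[span] = np.interp(span, mids, rates)
    else:
        for (b0, b1), r in zip(zip(beat_frames[:-1], beat_frames[1:]), rates):
            hr[b0 : min(b1 + 1, n_frames)] = r
    return hr


def bradycardia(
    hr: np.ndarray,
    baseline_window: tuple[int, int],
    stimulus_window: tuple[int, int],
    frame_rate_hz: float,
    n_sd: float = 3.0,
    sd_floor_hz: float = 0.05,
) -> tuple[bool, int | None]:
    """Flag a heart-rate drop of more than ``n_sd`` baseline SDs starting in the stimulus window.

    The baseline mean and SD come from ``baseline_window`` (which must
    precede the stimulus and span at least 10 s).  The trace is scanned
    for contiguous runs below ``mean - n_sd * SD``; the flag is true
    iff some run's onset falls inside ``stimulus_window``.  Returns
    ``(flag, onset_frame)`` with ``onset_frame=None`` when no
    qualifying drop exists.  A zero-variance baseline falls back to a
    configurable SD floor with a warning.
    """
    hr = np.asarray(hr, dtype=np.float64)
    b0, b1 = baseline_window
    s0, s1 = stimulus_window
    if b1 > s0:
        raise ValueError("baseline window must precede the stimulus window")
    if (b1 - b0) / frame_rate_hz < 10.0:
        raise ValueError("baseline window must span at least 10 s")
    base = hr[b0:b1]
    base = base[~np.isnan(base)]
    if base.size == 0:
        raise ValueError("baseline heart rate undefined")
    mean, sd = base.mean(), base.std()
    if sd == 0.0:
        warnings.warn("zero-variance baseline; using SD floor")
        sd = sd_floor_hz
    thresh = mean - n_sd * sd
    below = hr < thresh  # nan compares False
    onsets = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    for onset in onsets:
        if s0 <= onset < s1:
            return True, int(onset)
    return False, None


def heart_rate_change(
    hr: np.ndarray,
    onset_frame: int,
    frame_rate_hz: float,
    baseline_window: tuple[int, int] | None = None,
    horizon_s: float = 3.0,
) -> float:
    """Relative heart-rate change in the ``horizon_s`` after stimulus onset.

    Mean rate in ``[onset, onset + horizon)`` minus the baseline mean,
    normalized by the baseline mean (so −0.30 is a 30% drop).  The
    baseline defaults to everything before the onset.  A horizon
    extending past the recording is truncated with a warning.
    """
    hr = np.asarray(hr, dtype=np.float64)
    end = onset_frame + int(round(horizon_s * frame_rate_hz))
    if end > hr.size:
        warnings.warn("horizon exceeds recording; truncated")
        end = hr.size
    b0, b1 = baseline_window if baseline_window is not None else (0, onset_frame)
    base = hr[b0:b1]
    base = base[~np.isnan(base)]
    seg = hr[onset_frame:end]
    seg = seg[~np.isnan(seg)]
    if base.size == 0 or seg.size == 0:
        raise ValueError("heart rate undefined over baseline or horizon")
    mean_base = base.mean()
    return float((seg.mean() - mean_base) / mean_base)


def swim_probability(bout_masks: np.ndarray) -> np.ndarray:
    """Fraction of trials with a swim bout active at each peri-stimulus frame.

    ``bout_masks`` is (n_trials, n_frames) boolean, trials aligned to
    stimulus onset.
    """
    bout_masks = np.atleast_2d(np.asarray(bout_masks, dtype=bool))
    if bout_masks.shape[0] == 0:
        return np.zeros(0)
    return bout_masks.mean(axis=0)


@dataclass
class TrialLabel:
    """Classification of one trial with the evidence that produced it."""

    trial_id: int
    stimulus: str
    label: str
    evidence: dict = field(default_factory=dict)


def classify_trial(
    movement: np.ndarray,
    eye_convergence: np.ndarray,
    fast_swim: np.ndarray,
    bradycardia_flag: bool,
    stimulus_window: tuple[int, int],
    trial_id: int = 0,
    stimulus: str = "",
) -> TrialLabel:
    """Five-way trial classification from aligned event streams.

    Within the stimulus window: eye convergence marks *hunting*; a
    fast, large-amplitude swim marks *escape*; no movement at all
    combined with bradycardia marks *freezing*.  A trial showing two or
    more behavior types is *excluded*; a trial showing none (including
    immobility without bradycardia) is *none*.
    """
    streams = {"movement": movement, "eye_convergence": eye_convergence,
               "fast_swim": fast_swim}
    for name, s in streams.items():
        if s is None:
            raise ValueError(f"missing event stream: {name}")
    s0, s1 = stimulus_window
    moved = bool(np.asarray(movement, dtype=bool)[s0:s1].any())
    hunting = bool(np.asarray(eye_convergence, dtype=bool)[s0:s1].any())
    escape = bool(np.asarray(fast_swim, dtype=bool)[s0:s1].any())
    freezing = (not moved) and bool(bradycardia_flag)
    evidence = {
        "movement": moved,
        "eye_convergence": hunting,
        "fast_swim": escape,
        "bradycardia": bool(bradycardia_flag),
    }
    n_types = int(hunting) + int(escape) + int(freezing)
    if n_types >= 2:
        label = "excluded"
    elif hunting:
        label = "hunting"
    elif escape:
        label = "escape"
    elif freezing:
        label = "freezing"
    else:
        label = "none"
    return TrialLabel(trial_id, stimulus, label, evidence)
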