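"""Small numerical helpers used across modules."""

from __future__ import annotations

import numpy as np


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; returns nan if either argument has zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def percentile_linear(values: np.ndarray, q: float) -> float:
    """q-th percentile with linear interpolation on sorted values."""
    return float(np.percentile(np.asarray(values, dtype=np.float64), q, method="linear"))
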