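"""Sensor-level features.

Two families: per-segment RMS vectors (one value per sensor over a labeled
segment) for isolated speech/silence classification, and four framewise
features computed across sensors at every time point for continuous
prediction:

* F1 — sum of absolute values across sensors,
* F2 — root mean square across sensors,
* F3 — standard deviation across sensors (population convention, so
  F2 >= F3 with equality iff the cross-sensor mean is zero),
* F4 — 1-based index of the sensor with the largest magnitude
  (ties break to the lowest index).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acoustic import POST, PRE, SPEECH
from .io_core import TrialEpoch

__all__ = [
    "segment_rms_features",
    "framewise_features",
    "feature_difference",
    "standardize_features",
    "features_to_frame",
]

_SEGMENT_NAMES = {"PRE": PRE, "SPEECH": SPEECH, "POST": POST}


def segment_rms_features(epoch: TrialEpoch, labels3: np.ndarray) -> dict[str, np.ndarray]:
    """Per-sensor RMS over each labeled segment of a production window.

    Returns a mapping with keys ``PRE``, ``SPEECH``, ``POST`` and
    ``NONSPEECH`` (RMS over the pooled PRE and POST samples); segments with
    no samples are omitted.
    """
    x = np.asarray(epoch.data, dtype=np.float64)
    labels3 = np.asarray(labels3)
    if labels3.shape[0] != x.shape[1]:
        raise ValueError("labels must cover the epoch's samples")
    out: dict[str, np.ndarray] = {}
    for name, code in _SEGMENT_NAMES.items():
        mask = labels3 == code
        if mask.any():
            out[name] = np.sqrt(np.mean(x[:, mask] ** 2, axis=1))
    mask_ns = labels3 != SPEECH
    if mask_ns.any():
        out["NONSPEECH"] = np.sqrt(np.mean(x[:, mask_ns] ** 2, axis=1))
    return out


def framewise_features(epoch: TrialEpoch | np.ndarray) -> np.ndarray:
    """T x 4 feature matrix (F1 sum-abs, F2 RMS, F3 std, F4 argmax index).

    Accepts an epoch or a raw sensors-by-time matrix; requires at least two
    sensors for the cross-sensor standard deviation.
    """
    x = np.asarray(epoch.data if isinstance(epoch, TrialEpoch) else epoch, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two sensors")
    a = np.abs(x)
    f1 = a.sum(axis=0)
    f2 = np.sqrt(np.mean(x**2, axis=0))
    f3 = x.std(axis=0)  # population std across sensors
    f4 = a.argmax(axis=0) + 1.0  # 1-based; argmax takes the lowest index on ties
    return np.column_stack([f1, f2, f3, f4])


def feature_difference(featseq: np.ndarray) -> np.ndarray:
    """Per-time-point difference of standardized F1 and F3.

    F1 and F3 live on different raw scales (a sum over sensors vs a spread),
    so each is z-scored over the trial before subtracting; constant features
    standardize to zero.
    """
    f = np.asarray(featseq, dtype=np.float64)
    z1 = _zscore(f[:, 0])
    z3 = _zscore(f[:, 2])
    return z1 - z3


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / s


def standardize_features(featseq: np.ndarray, n_sensors: int, scale_f4: bool = True) -> np.ndarray:
    """Model-input conditioning: per-trial z-score of F1-F3; F4 either kept
    as the raw index or scaled to [0, 1] by the sensor count."""
    f = np.asarray(featseq, dtype=np.float64).copy()
    for j in range(3):
        f[:, j] = _zscore(f[:, j])
    if scale_f4:
        f[:, 3] = f[:, 3] / n_sensors
    return f


def features_to_frame(featseq: np.ndarray, trial: int = 0, sfreq: float = 1000.0) -> pd.DataFrame:
    """Tidy export of one trial's feature sequence (trial, t_ms, f1..f4)."""
    T = featseq.shape[0]
    t_ms = (np.arange(1, T + 1)) * 1000.0 / sfreq
    return pd.DataFrame(
        {
            "trial": trial,
            "t_ms": t_ms,
            "f1": featseq[:, 0],
            "f2": featseq[:, 1],
            "f3": featseq[:, 2],
            "f4": featseq[:, 3].astype(int),
        }
    )
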