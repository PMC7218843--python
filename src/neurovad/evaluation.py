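"""Per-sample metrics, onset/offset timing errors, sensor-mode analysis and
the paired statistical comparisons.

Speech is the positive class throughout: accuracy = (TP+TN)/(TP+TN+FP+FN),
precision = TP/(TP+FP), recall = TP/(TP+FN).  Precision (recall) is
undefined — reported as NaN, never silently zero — when no positive
predictions (truths) exist.  Across trials, precision and recall are
micro-averaged: counts are pooled before the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "vad_metrics",
    "onset_offset_errors",
    "sensor_mode_analysis",
    "one_tailed_paired_ttest",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def confusion_counts(pred_labels2: np.ndarray, true_labels2: np.ndarray) -> ConfusionCounts:
    """Sample-wise confusion counts with Speech (1) as the positive class."""
    pred = np.asarray(pred_labels2).astype(bool)
    true = np.asarray(true_labels2).astype(bool)
    if pred.shape != true.shape:
        raise ValueError("label sequences must have equal length")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def vad_metrics(per_trial_counts: list[ConfusionCounts], subject_ids=None) -> dict:
    """Aggregate per-trial confusion counts.

    Returns per-trial accuracies, per-subject mean/std/median accuracy, and
    pooled (micro-averaged) accuracy/precision/recall.
    """
    if not per_trial_counts:
        raise ValueError("need at least one trial")
    accs = np.array([c.accuracy for c in per_trial_counts])
    if subject_ids is None:
        subject_ids = ["all"] * len(per_trial_counts)
    df = pd.DataFrame({"subject": list(subject_ids), "accuracy": accs})
    per_subject = df.groupby("subject")["accuracy"].agg(["mean", "std", "median", "count"])
    pooled = ConfusionCounts(0, 0, 0, 0)
    for c in per_trial_counts:
        pooled = pooled + c
    return {
        "per_trial_accuracy": accs,
        "per_subject": per_subject,
        "mean_accuracy": float(accs.mean()),
        "std_accuracy": float(accs.std()),
        "median_accuracy": float(np.median(accs)),
        "pooled_accuracy": pooled.accuracy,
        "pooled_precision": pooled.precision,
        "pooled_recall": pooled.recall,
        "pooled_counts": pooled,
        "per_trial_counts": list(per_trial_counts),
    }


def _speech_runs(labels2: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(np.asarray(labels2).astype(np.int8), prepend=0, append=0)
    return list(zip(np.flatnonzero(d == 1).tolist(), np.flatnonzero(d == -1).tolist()))


def onset_offset_errors(
    pred_labels2: np.ndarray,
    true_labels2: np.ndarray,
    sfreq: float = 1000.0,
    run_rule: str = "longest",
) -> tuple[float, float]:
    """Signed timing errors (ms) between predicted and true speech spans.

    The predicted span is the longest predicted Speech run (robust to
    isolated flipped samples; ``run_rule='first'`` selects the earliest run
    instead).  Negative onset error means the prediction started early.
    """
    true_runs = _speech_runs(true_labels2)
    pred_runs = _speech_runs(pred_labels2)
    if not true_runs:
        raise ValueError("no true speech run")
    if not pred_runs:
        raise ValueError("no predicted speech run")
    if run_rule == "longest":
        p = max(pred_runs, key=lambda r: r[1] - r[0])
    elif run_rule == "first":
        p = pred_runs[0]
    else:
        raise ValueError(f"unknown run rule {run_rule!r}")
    t = max(true_runs, key=lambda r: r[1] - r[0])
    scale = 1000.0 / sfreq
    return (p[0] - t[0]) * scale, (p[1] - t[1]) * scale


def sensor_mode_analysis(feature_sequences, speech_masks, subject_ids=None) -> pd.DataFrame:
    """Frequency table of the most-active-sensor index (F4) during speech.

    Counts how often each sensor is the maximum-magnitude sensor within
    speech-labeled samples, per subject and pooled.  Returns a tidy frame
    (subject, sensor, count) sorted by pooled count; empty masks yield an
    empty table.
    """
    if subject_ids is None:
        subject_ids = ["all"] * len(feature_sequences)
    rows = []
    for feats, mask, subj in zip(feature_sequences, speech_masks, subject_ids):
        feats = np.asarray(feats)
        mask = np.asarray(mask).astype(bool)
        f4 = feats[mask, 3].astype(int)
        if f4.size == 0:
            continue
        sensors, counts = np.unique(f4, return_counts=True)
        for s, c in zip(sensors, counts):
            rows.append({"subject": subj, "sensor": int(s), "count": int(c)})
    if not rows:
        return pd.DataFrame(columns=["subject", "sensor", "count"])
    df = pd.DataFrame(rows).groupby(["subject", "sensor"], as_index=False)["count"].sum()
    order = df.groupby("sensor")["count"].sum().sort_values(ascending=False)
    df["sensor_rank"] = df["sensor"].map({s: r for r, s in enumerate(order.index, 1)})
    return df.sort_values(["sensor_rank", "subject"]).reset_index(drop=True)


def top_sensors(mode_table: pd.DataFrame, k: int = 5) -> list[int]:
    """The k sensors with the largest pooled F4 counts."""
    if mode_table.empty:
        return []
    pooled = mode_table.groupby("sensor")["count"].sum().sort_values(ascending=False)
    return [int(s) for s in pooled.index[:k]]


def one_tailed_paired_ttest(sample_a, sample_b, direction: str = "greater") -> tuple[float, float]:
    """Paired t test with a one-sided alternative on mean(a - b).

    ``direction='greater'`` tests mean(a) > mean(b); ``'less'`` the reverse.
    Identical samples (zero statistic) give p = 0.5.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples, n >= 2")
    d = a - b
    if np.allclose(d, d[0]) and np.isclose(d[0], 0):
        return 0.0, 0.5
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(a, b, alternative=direction)
    return float(res.statistic), float(res.pvalue)
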