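"""End-to-end orchestration: simulate (or load) a session, preprocess,
label from the acoustic channel, extract features, train/evaluate models,
and write reports.

`run_subject_experiment` is the library-level composition used by the CLI
``run`` subcommand and by the reproduction script: one subject in, a
metrics dictionary out.  The train/test split follows the session protocol:
the first ``train_trials_per_stimulus`` labeled trials of each stimulus
train the network (with a seeded validation carve-out inside the trainer)
and the remainder are held out for testing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .acoustic import (
    NoVoiceDetectedError,
    VadDetectorConfig,
    detect_voice_activity_acoustic,
    label_segments,
)
from .evaluation import confusion_counts, onset_offset_errors, vad_metrics
from .features import framewise_features, segment_rms_features
from .io_core import epoch_trials
from .models import LstmConfig, SvmConfig, predict_sequence, svm_isolated_classify, train_lstm
from .preprocess import PreprocessConfig, preprocess_epochs
from .synthetic import SimulationConfig, simulate_session

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Nested stage configuration with one global seed."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    labeling: VadDetectorConfig = field(default_factory=VadDetectorConfig)
    lstm: LstmConfig = field(default_factory=LstmConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    train_trials_per_stimulus: int = 50
    run_svm: bool = True
    seed: int = 0

    def resolve_seed(self) -> None:
        """Propagate the global seed to every stage that randomizes."""
        self.sim.seed = self.seed
        self.lstm.seed = (self.seed + 1) % (2**31)
        self.svm.seed = (self.seed + 2) % (2**31)


def label_epochs(epochs, detector_config: VadDetectorConfig | None = None):
    """Acoustic labeling of production-window epochs.

    Returns ``(labeled_epochs, segment_labels)``; trials where no voice is
    detected are dropped with a log entry (untimely/missing articulation).
    """
    cfg = detector_config or VadDetectorConfig()
    kept, labels = [], []
    for e in epochs:
        if e.audio is None:
            raise ValueError("epoch has no audio channel")
        try:
            onset, offset = detect_voice_activity_acoustic(e.audio, e.sfreq, cfg)
        except NoVoiceDetectedError:
            logger.info("trial %d: no voice detected, dropped from analysis", e.trial_index)
            continue
        kept.append(e)
        labels.append(label_segments(onset, offset, e.n_samples))
    return kept, labels


def _train_test_split(epochs, labels, per_stimulus: int):
    """First ``per_stimulus`` labeled trials of each stimulus train; rest test."""
    seen: dict[int, int] = {}
    tr_idx, te_idx = [], []
    for i, e in enumerate(epochs):
        k = seen.get(e.stimulus_id, 0)
        (tr_idx if k < per_stimulus else te_idx).append(i)
        seen[e.stimulus_id] = k + 1
    if not te_idx:
        raise ValueError("no held-out trials; reduce train_trials_per_stimulus")
    return tr_idx, te_idx


def run_subject_experiment(config: PipelineConfig) -> dict:
    """Simulate and analyze one subject end to end.

    Returns a dictionary with preprocessing/labeling bookkeeping, the SVM
    accuracy table (optional), and held-out per-sample metrics of the
    sequence labeler.
    """
    cfg = config
    cfg.resolve_seed()
    t0 = time.time()
    recording, events, truth = simulate_session(cfg.sim)
    epochs = epoch_trials(recording, events)
    del recording
    epochs, prep_report = preprocess_epochs(epochs, cfg.preprocess)
    epochs, seglabels = label_epochs(epochs, cfg.labeling)

    feats = [framewise_features(e) for e in epochs]
    labels2 = [sl.labels2 for sl in seglabels]

    out: dict = {
        "subject": cfg.sim.subject_id,
        "n_trials_analyzed": len(epochs),
        "preprocess": prep_report,
    }

    if cfg.run_svm:
        X, y = [], []
        for e, sl in zip(epochs, seglabels):
            rms = segment_rms_features(e, sl.labels3)
            for name in ("PRE", "SPEECH", "POST"):
                if name in rms:
                    X.append(rms[name])
                    y.append(name)
        out["svm_table"] = svm_isolated_classify(np.array(X), np.array(y), cfg.svm)

    tr_idx, te_idx = _train_test_split(epochs, labels2, cfg.train_trials_per_stimulus)
    model = train_lstm([feats[i] for i in tr_idx], [labels2[i] for i in tr_idx], cfg.lstm)

    counts, onset_errs, offset_errs = [], [], []
    for i in te_idx:
        pred, _ = predict_sequence(model, feats[i])
        counts.append(confusion_counts(pred, labels2[i]))
        try:
            eon, eoff = onset_offset_errors(pred, labels2[i], epochs[i].sfreq)
            onset_errs.append(eon)
            offset_errs.append(eoff)
        except ValueError:
            pass
    metrics = vad_metrics(counts, [epochs[i].subject_id for i in te_idx])
    out["model"] = model
    out["metrics"] = metrics
    out["onset_bias_ms"] = float(np.mean(onset_errs)) if onset_errs else float("nan")
    out["offset_bias_ms"] = float(np.mean(offset_errs)) if offset_errs else float("nan")
    out["n_test_trials"] = len(te_idx)
    out["n_train_trials"] = len(tr_idx)
    out["runtime_s"] = time.time() - t0
    return out


def summarize(results: list[dict]) -> dict:
    """JSON-ready cross-subject summary of `run_subject_experiment` outputs."""
    rows = []
    for r in results:
        m = r["metrics"]
        rows.append(
            {
                "subject": r["subject"],
                "n_test_trials": r["n_test_trials"],
                "mean_accuracy": m["mean_accuracy"],
                "std_accuracy": m["std_accuracy"],
                "median_accuracy": m["median_accuracy"],
                "pooled_precision": m["pooled_precision"],
                "pooled_recall": m["pooled_recall"],
                "onset_bias_ms": r["onset_bias_ms"],
                "offset_bias_ms": r["offset_bias_ms"],
            }
        )
    grand = float(np.mean([x["mean_accuracy"] for x in rows])) if rows else float("nan")
    return {"per_subject": rows, "grand_mean_accuracy": grand}


def write_report(summary: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
        f.write("\n")
    return path
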