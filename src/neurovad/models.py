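"""Classifiers: isolated segment SVM and the continuous per-sample LSTM
voice-activity predictor.

The SVM sanity check asks whether per-sensor RMS vectors separate speech
from silence at the segment level (2nd-order polynomial kernel, stratified
6-fold cross-validation, one-vs-one voting for the 3-class case).  The LSTM
consumes the four framewise features and emits a Speech/Non-Speech
probability pair at every time step, so onset and offset can be read from a
causal stream of neural data alone.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import _lstm
from .features import standardize_features

__all__ = [
    "SvmConfig",
    "svm_isolated_classify",
    "LstmConfig",
    "VadModel",
    "train_lstm",
    "predict_sequence",
]

PAIRINGS = ("PRE-vs-POST", "PRE-vs-SPEECH", "POST-vs-SPEECH", "SPEECH-vs-NONSPEECH", "3-CLASS-OVO")


@dataclass
class SvmConfig:
    kernel: str = "poly"
    degree: int = 2
    n_folds: int = 6
    class_pairings: tuple[str, ...] = PAIRINGS
    C: float = 1.0
    coef0: float = 1.0  # inhomogeneous kernel (x.y + 1)^degree
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        unknown = set(self.class_pairings) - set(PAIRINGS)
        if unknown:
            raise ValueError(f"unknown pairings: {sorted(unknown)}")


def _pairing_data(X: np.ndarray, y: np.ndarray, pairing: str):
    if pairing == "3-CLASS-OVO":
        keep = np.isin(y, ["PRE", "SPEECH", "POST"])
        return X[keep], y[keep]
    if pairing == "SPEECH-vs-NONSPEECH":
        yy = np.where(y == "SPEECH", "SPEECH", "NONSPEECH")
        return X, yy
    a, b = pairing.split("-vs-")
    keep = np.isin(y, [a, b])
    return X[keep], y[keep]


def svm_isolated_classify(X, y, config: SvmConfig | None = None) -> pd.DataFrame:
    """Cross-validated segment classification accuracies.

    Parameters
    ----------
    X : array, shape (n_segments, n_sensors)
        Per-segment RMS feature vectors.
    y : array of str
        Segment classes (``PRE``, ``SPEECH``, ``POST``).
    config : SvmConfig

    Returns a table with one row per requested pairing (mean and standard
    deviation of fold accuracies).  Feature standardization is fit on the
    training folds only.
    """
    cfg = config or SvmConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=object).astype(str)
    rows = []
    for pairing in cfg.class_pairings:
        Xp, yp = _pairing_data(X, y, pairing)
        classes, counts = np.unique(yp, return_counts=True)
        if counts.min() < cfg.n_folds:
            raise ValueError(f"{pairing}: class with fewer examples ({counts.min()}) than folds")
        clf = make_pipeline(
            StandardScaler(),
            SVC(kernel=cfg.kernel, degree=cfg.degree, C=cfg.C, coef0=cfg.coef0, decision_function_shape="ovo"),
        )
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        accs = []
        for tr, te in skf.split(Xp, yp):
            clf.fit(Xp[tr], yp[tr])
            accs.append(float(np.mean(clf.predict(Xp[te]) == yp[te])))
        accs = np.asarray(accs)
        rows.append(
            {
                "pairing": pairing,
                "mean_accuracy": accs.mean(),
                "std_accuracy": accs.std(),
                "n_examples": len(yp),
                "n_folds": cfg.n_folds,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LstmConfig:
    """Training hyperparameters.

    Defaults follow the published recipe: two 256-unit layers, hard-sigmoid
    gate / tanh state activations, a 2-unit softmax head, Adam (beta1 0.9,
    beta2 0.998, epsilon 1e-8), learning rate in 0.004-0.006 (default the
    midpoint), L2 gradient-norm threshold 0.1 and at most 500 epochs with
    the stopping epoch chosen on validation accuracy.  ``time_stride``
    averages features over non-overlapping blocks before the recurrence
    (labels take the block majority); predictions are repeated back to full
    rate.  Stride 1 reproduces per-millisecond training.
    """

    n_layers: int = 2
    hidden_units: int = 256
    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.998
    epsilon: float = 1e-8
    gradient_clip: float = 0.1
    max_epochs: int = 500
    batch_size: int = 32
    validation_fraction: float = 0.2
    patience: int = 25
    time_stride: int = 1
    standardize: bool = True
    scale_f4: bool = True
    n_sensors: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_stride < 1:
            raise ValueError("time_stride must be >= 1")
        if self.learning_rate <= 0 or self.max_epochs < 1:
            raise ValueError("learning_rate and max_epochs must be positive")


@dataclass
class VadModel:
    """Trained sequence labeler: parameters + config + training history."""

    config: LstmConfig
    params: _lstm.LstmParams
    history: pd.DataFrame
    n_features: int = 4

    def save(self, path) -> None:
        arrays = {}
        for i, lay in enumerate(self.params.layers):
            for k, v in lay.items():
                arrays[f"layer{i}_{k}"] = v
        arrays["Wout"] = self.params.Wout
        arrays["bout"] = self.params.bout
        meta = {
            "config": asdict(self.config),
            "n_layers": len(self.params.layers),
            "n_features": self.n_features,
            "format_version": 1,
        }
        buf = io.BytesIO()
        self.history.to_csv(buf, index=False)
        arrays["_history_csv"] = np.frombuffer(buf.getvalue(), dtype=np.uint8)
        arrays["_meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "VadModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta_json"]))
            layers = [
                {k: z[f"layer{i}_{k}"] for k in ("W", "R", "b")}
                for i in range(meta["n_layers"])
            ]
            params = _lstm.LstmParams(layers, z["Wout"], z["bout"])
            history = pd.read_csv(io.BytesIO(bytes(z["_history_csv"])))
        cfg = LstmConfig(**meta["config"])
        return cls(config=cfg, params=params, history=history, n_features=meta["n_features"])


def _prepare(sequences, labels, cfg: LstmConfig):
    """Stack trials into a (B, T', D) batch, standardizing and striding."""
    xs, ys = [], []
    for seq, lab in zip(sequences, labels):
        seq = np.asarray(seq, dtype=np.float64)
        lab = np.asarray(lab)
        if seq.shape[0] != lab.shape[0]:
            raise ValueError("sequence and label lengths differ")
        if cfg.standardize:
            seq = standardize_features(seq, cfg.n_sensors, scale_f4=cfg.scale_f4)
        s = cfg.time_stride
        if s > 1:
            T = (seq.shape[0] // s) * s
            seq = seq[:T].reshape(-1, s, seq.shape[1]).mean(axis=1)
            lab = (lab[:T].reshape(-1, s).mean(axis=1) >= 0.5).astype(np.int64)
        xs.append(seq)
        ys.append(lab.astype(np.int64))
    return np.stack(xs), np.stack(ys)


def train_lstm(train_sequences, train_labels2, config: LstmConfig | None = None) -> VadModel:
    """Train the per-sample Speech/Non-Speech predictor.

    A seeded fraction of the training trials is carved out as the
    validation set; the returned parameters are those of the epoch with the
    best validation per-sample accuracy (the stopping-epoch rule).
    Deterministic given ``config.seed``.
    """
    cfg = config or LstmConfig()
    if len(train_sequences) < 2:
        raise ValueError("need at least 2 training trials")
    x, y = _prepare(train_sequences, train_labels2, cfg)
    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx = perm
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[tr_idx], y[tr_idx]

    params = _lstm.init_params(x.shape[2], cfg.hidden_units, cfg.n_layers, rng)
    opt = _lstm.AdamState(params)
    best = params.copy()
    best_acc = -1.0
    best_epoch = -1
    rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(xt))
        losses = []
        for start in range(0, len(xt), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = _lstm.loss_and_grads(params, xt[idx], yt[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or inspect the features"
                )
            _lstm.clip_global_norm(grads, cfg.gradient_clip)
            _lstm.adam_step(params, grads, opt, cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.epsilon)
            losses.append(loss)
        pv, _, _ = _lstm.forward(params, xv)
        val_acc = float((pv.argmax(-1) == yv).mean())
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best = params.copy()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    return VadModel(config=cfg, params=best, history=history, n_features=x.shape[2])


def predict_sequence(model: VadModel, feature_sequence: np.ndarray):
    """Per-sample labels (1 = Speech) and class probabilities for one trial.

    The recurrence is unidirectional, so each step's output depends only on
    past and current samples (causal streaming).  With a trained
    ``time_stride`` > 1, block predictions are repeated back to sample rate.
    """
    seq = np.asarray(feature_sequence, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[1] != model.n_features:
        raise ValueError(f"expected (T, {model.n_features}) features, got {seq.shape}")
    cfg = model.config
    T_full = seq.shape[0]
    x, _ = _prepare([seq], [np.zeros(T_full, dtype=np.int64)], cfg)
    probs, _, _ = _lstm.forward(model.params, x)
    probs = probs[0]
    s = cfg.time_stride
    if s > 1:
        probs = np.repeat(probs, s, axis=0)
        if probs.shape[0] < T_full:  # tail samples beyond the last full block
            pad = np.repeat(probs[-1:], T_full - probs.shape[0], axis=0)
            probs = np.vstack([probs, pad])
        probs = probs[:T_full]
    labels = probs.argmax(axis=-1).astype(np.int8)
    return labels, probs
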