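"""Preprocessing: channel selection, artifact rejection, wavelet band
restriction, and production-window extraction.

The analysis chain mirrors standard MEG practice for this task: keep planar
gradiometers only, drop unresponsive/noisy channels, reject trials with
high-amplitude transients, band-restrict each channel to below the
high-gamma ceiling (<125 Hz) with a 2-level Daubechies-4 decomposition, and
forward only the 2 s production window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .io_core import Recording, TrialEpoch, copy_epoch_with

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "resample_epoch",
    "select_gradiometers",
    "drop_bad_channels",
    "reject_artifact_trials",
    "wavelet_denoise",
    "extract_production_window",
    "preprocess_epochs",
]


@dataclass
class PreprocessConfig:
    """Wavelet and artifact-rejection parameters.

    A 2-level decomposition at 1 kHz leaves an approximation band of
    0-125 Hz, i.e. everything up to and including high gamma; analysis is
    therefore carried out at ``working_sfreq`` = 1000 (which also makes one
    sample = 1 ms, the labeling resolution).
    """

    wavelet_name: str = "db4"
    decomposition_level: int = 2
    target_band_hz: float = 125.0
    artifact_zscore_threshold: float = 10.0
    flat_threshold: float = 1e-12
    noise_threshold: float = 25.0
    working_sfreq: float = 1000.0
    soft_threshold: bool = False

    def __post_init__(self) -> None:
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")
        approx_band = self.working_sfreq / 2.0 ** (self.decomposition_level + 1)
        if approx_band > self.target_band_hz:
            raise ValueError(
                f"approximation band {approx_band:g} Hz exceeds target {self.target_band_hz:g} Hz"
            )


def resample_epoch(epoch: TrialEpoch, target_sfreq: float) -> TrialEpoch:
    """Polyphase (zero-phase) resampling of an epoch to ``target_sfreq``."""
    if epoch.sfreq == target_sfreq:
        return epoch
    from fractions import Fraction

    frac = Fraction(target_sfreq / epoch.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(epoch.data, up, down, axis=1)
    audio = None if epoch.audio is None else signal.resample_poly(epoch.audio, up, down)
    ratio = target_sfreq / epoch.sfreq
    marks = tuple(int(round(m * ratio)) for m in epoch.stage_marks)
    return copy_epoch_with(epoch, data=data, audio=audio, sfreq=target_sfreq, stage_marks=marks)


def select_gradiometers(obj: Recording | TrialEpoch):
    """Restrict a recording or epoch to its gradiometer channels.

    Auxiliary channels (the acoustic track in particular) live outside the
    sensor matrix of an epoch, so labeling workflows are unaffected.
    """
    if isinstance(obj, Recording):
        return obj.pick_kinds(("gradiometer",))
    idx = [i for i, k in enumerate(obj.channel_kinds) if k == "gradiometer"]
    if not idx:
        raise ValueError("no gradiometer channels present")
    if len(idx) == obj.n_channels:
        return obj
    return copy_epoch_with(
        obj,
        data=obj.data[idx],
        channel_names=[obj.channel_names[i] for i in idx],
        channel_kinds=[obj.channel_kinds[i] for i in idx],
    )


def _pooled_samples(epochs: list[TrialEpoch], budget: int = 500_000) -> np.ndarray:
    """Channels-by-samples pool across trials for session statistics.

    Deterministically strides time so at most ~``budget`` samples per
    channel are pooled; medians/MADs/variances are insensitive to this.
    """
    total = sum(e.n_samples for e in epochs)
    stride = max(1, total // budget)
    return np.concatenate([e.data[:, ::stride] for e in epochs], axis=1)


def drop_bad_channels(
    epochs: list[TrialEpoch],
    flat_threshold: float = 1e-12,
    noise_threshold: float = 25.0,
) -> tuple[list[TrialEpoch], list[str]]:
    """Remove unresponsive (flat) and noisy channels consistently across trials.

    A channel is unresponsive when its variance across all trials falls below
    ``flat_threshold``, and noisy when its robust variance (squared scaled
    MAD) exceeds ``noise_threshold`` times the median robust variance across
    channels.
    """
    if flat_threshold <= 0 or noise_threshold <= 0:
        raise ValueError("thresholds must be positive")
    stacked = _pooled_samples(epochs)
    var = stacked.var(axis=1)
    med = np.median(stacked, axis=1, keepdims=True)
    mad = np.median(np.abs(stacked - med), axis=1)
    robust_var = (1.4826 * mad) ** 2
    ref = np.median(robust_var)
    flat = var < flat_threshold
    noisy = robust_var > noise_threshold * ref
    bad = flat | noisy
    if bad.all():
        raise ValueError("channel rejection would remove every channel")
    if not bad.any():
        return list(epochs), []
    keep = np.flatnonzero(~bad)
    dropped = [epochs[0].channel_names[i] for i in np.flatnonzero(bad)]
    for name, is_flat in zip(dropped, flat[bad]):
        logger.info("dropping channel %s (%s)", name, "unresponsive" if is_flat else "noisy")
    out = [
        copy_epoch_with(
            e,
            data=e.data[keep],
            channel_names=[e.channel_names[i] for i in keep],
            channel_kinds=[e.channel_kinds[i] for i in keep],
        )
        for e in epochs
    ]
    return out, dropped


def reject_artifact_trials(
    epochs: list[TrialEpoch], zscore_threshold: float = 10.0, envelope_ms: float = 100.0
) -> tuple[list[TrialEpoch], list[int]]:
    """Reject trials containing high-amplitude transients.

    The statistic is the peak, over sensors and time, of a short moving-RMS
    amplitude envelope scaled by each sensor's session-wide robust spread
    (median/MAD over all trials pooled).  The envelope separates large
    artifact transients (jaw clenches and the like, tens of baseline
    standard deviations) from task-related amplitude elevation, which is
    sustained but only a few times baseline.  A deterministic stand-in for
    visual artifact inspection.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    if zscore_threshold <= 0:
        raise ValueError("zscore_threshold must be positive")
    stacked = _pooled_samples(epochs)
    med = np.median(stacked, axis=1)
    mad = 1.4826 * np.median(np.abs(stacked - med[:, None]), axis=1) + 1e-30
    del stacked
    win = max(2, int(round(envelope_ms * epochs[0].sfreq / 1000.0)))
    kept, rejected = [], []
    for i, e in enumerate(epochs):
        power = uniform_filter1d((e.data - med[:, None]) ** 2, size=win, axis=1, mode="nearest")
        z = np.sqrt(power) / mad[:, None]
        peak = float(z.max())
        if peak > zscore_threshold:
            ch = int(np.unravel_index(np.argmax(z), z.shape)[0])
            logger.info("rejecting trial %d: peak |z|=%.1f on channel %s", i, peak, e.channel_names[ch] if e.channel_names else ch)
            rejected.append(i)
        else:
            kept.append(e)
    if not kept:
        raise ValueError("all trials rejected; review artifact_zscore_threshold")
    return kept, rejected


def wavelet_denoise(epoch: TrialEpoch, config: PreprocessConfig | None = None) -> TrialEpoch:
    """Band-restrict every channel below the high-gamma ceiling.

    Decomposes each channel to ``decomposition_level`` with
    ``wavelet_name``, discards the detail coefficients (hard band
    restriction; optional soft-thresholding keeps shrunken details instead)
    and reconstructs from the approximation.  Periodized DWT boundary
    handling makes the operator an exact orthogonal projection, so applying
    it twice equals applying it once.
    """
    cfg = config or PreprocessConfig()
    x = np.asarray(epoch.data, dtype=np.float64)
    w = pywt.Wavelet(cfg.wavelet_name)
    if x.shape[1] < 2**cfg.decomposition_level * w.dec_len:
        raise ValueError("epoch shorter than wavelet support at this level")
    coeffs = pywt.wavedec(x, w, level=cfg.decomposition_level, mode="periodization", axis=1)
    if cfg.soft_threshold:
        details = [c for c in coeffs[1:]]
        sigma = np.median(np.abs(details[-1]), axis=1, keepdims=True) / 0.6745
        thr = sigma * np.sqrt(2 * np.log(x.shape[1]))
        new = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in details]
    else:
        new = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    y = pywt.waverec(new, w, mode="periodization", axis=1)[:, : x.shape[1]]
    return copy_epoch_with(epoch, data=y.astype(epoch.data.dtype, copy=False))


def extract_production_window(epoch: TrialEpoch) -> TrialEpoch:
    """The 2 s window starting at the production cue, audio cut identically."""
    if epoch.stage_marks is None or len(epoch.stage_marks) != 4:
        raise ValueError("epoch has no stage marks")
    cue = epoch.stage_marks[2]
    T = int(round(2.0 * epoch.sfreq))
    if cue < 0 or cue + T > epoch.n_samples:
        raise ValueError("production window out of epoch bounds")
    return copy_epoch_with(
        epoch,
        data=epoch.data[:, cue : cue + T],
        audio=None if epoch.audio is None else epoch.audio[cue : cue + T],
        t0_offset=epoch.t0_offset + cue / epoch.sfreq,
        stage_marks=(
            epoch.stage_marks[0] - cue,
            epoch.stage_marks[1] - cue,
            0,
            T,
        ),
    )


def preprocess_epochs(
    epochs: list[TrialEpoch], config: PreprocessConfig | None = None
) -> tuple[list[TrialEpoch], dict]:
    """Full chain: select -> drop bad channels -> reject trials -> denoise -> window.

    Returns the production-window epochs and a report dict with dropped
    channels and rejected trial indices (indices refer to the input list).
    """
    cfg = config or PreprocessConfig()
    epochs = [select_gradiometers(e) for e in epochs]
    if epochs[0].sfreq != cfg.working_sfreq:
        epochs = [resample_epoch(e, cfg.working_sfreq) for e in epochs]
    epochs, dropped = drop_bad_channels(epochs, cfg.flat_threshold, cfg.noise_threshold)
    epochs, rejected = reject_artifact_trials(epochs, cfg.artifact_zscore_threshold)
    out = [extract_production_window(wavelet_denoise(e, cfg)) for e in epochs]
    return out, {"dropped_channels": dropped, "rejected_trials": rejected}
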