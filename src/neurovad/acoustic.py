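"""Acoustic ground-truth labeling: audio denoising, voice onset/offset
detection, and per-sample segment labels.

Labels follow the 1-based millisecond convention of the production window:
``onset`` is the last sample labeled Pre-Speech and ``offset`` the last
sample labeled Speech.  With voicing detected from 401 ms to 931 ms in a
2000 ms window, samples 1-401 are Pre-Speech, 402-931 Speech and 932-2000
Post-Speech; the binary collapse maps Pre- and Post-Speech to Non-Speech.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

__all__ = [
    "PRE",
    "SPEECH",
    "POST",
    "NONSPEECH",
    "SegmentLabels",
    "VadDetectorConfig",
    "NoVoiceDetectedError",
    "wiener_denoise_audio",
    "detect_voice_activity_acoustic",
    "label_segments",
]

PRE, SPEECH, POST = 0, 1, 2
NONSPEECH = 0  # binary coding: SPEECH stays 1


class NoVoiceDetectedError(RuntimeError):
    """No supra-threshold acoustic activity in the trial (flag and skip)."""


@dataclass
class VadDetectorConfig:
    """Energy-threshold voice activity detector parameters.

    The short-time energy is compared against ``threshold_factor`` times the
    noise floor (median energy of the first ``noise_floor_ms``).  Silent
    gaps shorter than ``min_silence_gap_ms`` are bridged so that natural
    intra-phrase pauses do not split a phrase, and runs shorter than
    ``min_speech_ms`` are discarded as clicks.
    """

    frame_ms: float = 10.0
    hop_ms: float = 1.0
    threshold_factor: float = 3.0
    min_speech_ms: float = 100.0
    min_silence_gap_ms: float = 250.0
    noise_floor_ms: float = 200.0
    min_run_ms: float = 30.0  # supra-threshold blips shorter than this are noise
    refine_ms: float = 5.0  # boundary-refinement energy window

    def __post_init__(self) -> None:
        if self.frame_ms < self.hop_ms:
            raise ValueError("frame_ms must be >= hop_ms")
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")


def wiener_denoise_audio(
    audio: np.ndarray,
    noise_profile_window: tuple[int, int] = (0, 200),
    sfreq: float = 1000.0,
    nperseg: int = 64,
    gain_floor: float = 0.05,
) -> np.ndarray:
    """Spectral Wiener suppression with the noise spectrum estimated from a
    known-silent stretch (``noise_profile_window``, samples).

    The per-bin gain is ``max(1 - N(f)/|X(f,t)|^2, gain_floor)`` with light
    temporal smoothing; output has the input's length.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if audio.size == 0:
        raise ValueError("audio is empty")
    a, b = noise_profile_window
    if b - a > audio.size or b > audio.size:
        raise ValueError("noise window longer than audio")
    if not audio.any():
        return np.zeros_like(audio)

    nperseg = min(nperseg, audio.size)
    f, t, Z = signal.stft(audio, fs=sfreq, nperseg=nperseg)
    power = np.abs(Z) ** 2
    # frames whose centers fall inside the noise-profile window
    centers = t * sfreq
    in_noise = (centers >= a) & (centers < b)
    if not in_noise.any():
        in_noise[: max(1, len(t) // 10)] = True
    noise_psd = power[:, in_noise].mean(axis=1, keepdims=True)
    gain = np.clip(1.0 - noise_psd / np.maximum(power, 1e-300), gain_floor, 1.0)
    # exponential smoothing along time stabilizes the gain between frames
    alpha = 0.6
    for k in range(1, gain.shape[1]):
        gain[:, k] = alpha * gain[:, k] + (1 - alpha) * gain[:, k - 1]
    _, y = signal.istft(Z * gain, fs=sfreq, nperseg=nperseg)
    if y.size < audio.size:
        y = np.pad(y, (0, audio.size - y.size))
    return y[: audio.size]


def _short_time_energy(audio: np.ndarray, frame_samples: int) -> np.ndarray:
    """Centered moving-average power, same length as the input."""
    return uniform_filter1d(audio.astype(np.float64) ** 2, size=frame_samples, mode="nearest")


def detect_voice_activity_acoustic(
    audio: np.ndarray,
    sfreq: float = 1000.0,
    config: VadDetectorConfig | None = None,
) -> tuple[int, int]:
    """Locate the voiced span of a production-window audio trace.

    Returns ``(onset, offset)`` in the 1-based convention (onset = last
    sample before voicing, offset = last voiced sample).  Detection is
    two-stage: coarse supra-threshold runs from frame energy, then boundary
    refinement at the half-rise level between noise floor and speech energy
    — the mid-level crossing of a centered energy window is unbiased with
    respect to the true edge regardless of signal-to-noise ratio.

    Raises :class:`NoVoiceDetectedError` when no sufficiently long
    supra-threshold run exists (e.g. an untimely or missing articulation).
    """
    cfg = config or VadDetectorConfig()
    audio = np.asarray(audio, dtype=np.float64)
    ms = sfreq / 1000.0
    L = max(2, int(round(cfg.frame_ms * ms)))
    e = _short_time_energy(audio, L)

    n_floor = max(L, int(round(cfg.noise_floor_ms * ms)))
    floor = float(np.median(e[:n_floor])) + 1e-300
    active = e > cfg.threshold_factor * floor

    runs = _runs(active)
    # discard click-length blips before bridging, else isolated noise
    # excursions get absorbed into the voiced span
    runs = [(s, t) for s, t in runs if t - s >= int(round(cfg.min_run_ms * ms))]
    gap = int(round(cfg.min_silence_gap_ms * ms))
    runs = _bridge(runs, gap)
    min_len = int(round(cfg.min_speech_ms * ms))
    runs = [(s, t) for s, t in runs if t - s >= min_len]
    if not runs:
        raise NoVoiceDetectedError("no voice detected")

    s0, s1 = runs[0][0], runs[-1][1]  # 0-based, half-open coarse span

    # refine each boundary as the crossing of the half-rise level between
    # noise floor and speech energy: a centered energy window crosses the
    # mid-level when it is half inside the voiced span, so the estimate is
    # unbiased in the window length and the signal-to-noise ratio
    level = float(np.median(e[s0:s1]))
    mid = 0.5 * (floor + level)
    Lr = max(2, int(round(cfg.refine_ms * ms)))
    er = _short_time_energy(audio, Lr)
    lo, hi = max(0, s0 - 2 * L), min(len(er), s0 + 2 * L)
    above = np.flatnonzero(er[lo:hi] >= mid)
    first_speech = lo + int(above[0]) if above.size else s0
    lo2, hi2 = max(0, s1 - 2 * L), min(len(er), s1 + 2 * L)
    above2 = np.flatnonzero(er[lo2:hi2] >= mid)
    last_speech = lo2 + int(above2[-1]) if above2.size else s1 - 1

    onset = first_speech  # 1-based index of the sample preceding voicing
    offset = last_speech + 1  # 1-based index of the last voiced sample
    if onset < 1:
        onset = 1
    if offset <= onset:
        raise NoVoiceDetectedError("degenerate voiced span")
    return onset, offset


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) runs of True."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _bridge(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs:
        return runs
    merged = [runs[0]]
    for s, t in runs[1:]:
        ps, pt = merged[-1]
        if s - pt < max_gap:
            merged[-1] = (ps, t)
        else:
            merged.append((s, t))
    return merged


@dataclass
class SegmentLabels:
    """Per-sample three-way and binary labels for one production window."""

    labels3: np.ndarray
    onset_sample: int
    offset_sample: int

    @property
    def labels2(self) -> np.ndarray:
        """Binary collapse: Pre- and Post-Speech become Non-Speech (0)."""
        return (self.labels3 == SPEECH).astype(np.int8)

    def __len__(self) -> int:
        return len(self.labels3)


def label_segments(onset_sample: int, offset_sample: int, T: int) -> SegmentLabels:
    """Partition samples 1..T into Pre-Speech / Speech / Post-Speech.

    ``onset_sample`` is the last Pre-Speech sample and ``offset_sample`` the
    last Speech sample (1-based inclusive).  ``offset_sample == T`` yields an
    empty Post-Speech segment, a documented edge case.
    """
    if not (1 <= onset_sample < offset_sample <= T):
        raise ValueError(
            f"require 1 <= onset ({onset_sample}) < offset ({offset_sample}) <= T ({T})"
        )
    labels3 = np.full(T, POST, dtype=np.int8)
    labels3[:onset_sample] = PRE  # 1-based samples 1..onset
    labels3[onset_sample:offset_sample] = SPEECH  # onset+1..offset
    return SegmentLabels(labels3=labels3, onset_sample=int(onset_sample), offset_sample=int(offset_sample))
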