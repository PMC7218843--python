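"""Synthetic speech-task sessions with known ground truth.

Emulates a time-locked delayed overt-reading MEG session: each trial has a
0.5 s baseline, 1 s stimulus display, 1 s preparation period and a 2 s overt
production stage.  During production, a designated subset of
"speech-related" sensors shows elevated amplitude time-locked to a burst on
the acoustic channel, with the neural elevation leading the acoustic onset
by a small configurable amount (speech-motor activity precedes voicing).

The signal model is amplitude-modulated band-limited noise, not a biophysical
forward model: downstream stages only consume sensor amplitude statistics,
so sensor-level realism (1/f-ish spectrum, shared background, artifact
transients) is what matters for testing the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_core import EventTable, Recording, TrialEpoch

__all__ = ["SimulationConfig", "GroundTruth", "simulate_session", "make_worked_example"]


@dataclass
class SimulationConfig:
    """Parameters of the simulated session.

    ``snr_db`` sets the amplitude elevation of speech sensors during speech
    (factor ``10**(snr_db/20)``) and, unless ``audio_snr_db`` overrides it,
    the acoustic burst-to-background power ratio.  Onset jitter and speech
    duration are uniform in milliseconds after the production cue; defaults
    keep every burst inside the 2 s production stage.
    """

    n_sensors: int = 200
    sfreq: float = 1000.0
    n_trials_per_stimulus: int = 100
    n_stimuli: int = 5
    speech_sensor_fraction: float = 0.15
    snr_db: float = 10.0
    audio_snr_db: float | None = None
    onset_jitter_ms: tuple[float, float] = (300.0, 600.0)
    speech_duration_ms: tuple[float, float] = (400.0, 900.0)
    neural_lead_ms: float = 10.0
    artifact_trial_rate: float = 0.25
    inter_trial_gap_s: float = 0.5
    noise_lowpass_hz: float = 100.0
    shared_background_weight: float = 0.3
    subject_id: str = "S01"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.speech_sensor_fraction <= 1:
            raise ValueError("speech_sensor_fraction must be in (0, 1]")
        if self.neural_lead_ms < 0:
            raise ValueError("neural_lead_ms must be >= 0")
        production_ms = 2000.0
        if self.onset_jitter_ms[1] + self.speech_duration_ms[1] > production_ms:
            raise ValueError("onset jitter + speech duration must fit the 2 s production stage")

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_stimulus * self.n_stimuli


@dataclass
class GroundTruth:
    """Per-trial truth for a simulated session.

    Onset/offset use the labeling convention: 1-based milliseconds after the
    production cue, onset = last pre-speech sample, offset = last speech
    sample.
    """

    onset_ms: np.ndarray
    offset_ms: np.ndarray
    speech_sensors: np.ndarray
    artifact_flags: np.ndarray
    stimulus_order: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _bandlimited_noise(rng: np.random.Generator, shape, sfreq: float, lowpass_hz: float) -> np.ndarray:
    """White noise low-passed to ``lowpass_hz`` and rescaled to unit std."""
    x = rng.standard_normal(shape).astype(np.float32)
    sos = signal.butter(4, lowpass_hz / (sfreq / 2.0), btype="low", output="sos")
    x = signal.sosfilt(sos, x, axis=-1).astype(np.float32)
    x /= x.std(axis=-1, keepdims=True) + 1e-12
    return x


def _voiced_carrier(rng: np.random.Generator, n: int, sfreq: float, f0: float = 150.0, phase_jitter: float = 0.6) -> np.ndarray:
    """Unit-RMS quasi-periodic carrier for the acoustic burst.

    A harmonic complex (1/k amplitude roll-off, lightly jittered phases
    aligned so a glottal-pulse-like maximum falls at the burst start) plus a
    weak noise floor — the quasi-periodic structure of voiced speech, whose
    short-time power is far steadier than white noise and so carries a
    well-defined acoustic edge.
    """
    t = np.arange(n) / sfreq
    x = np.zeros(n)
    k = 1
    while k * f0 < sfreq / 2:
        x += (1.0 / k) * np.cos(2 * np.pi * k * f0 * t + phase_jitter * rng.uniform(-0.5, 0.5))
        k += 1
    x /= np.sqrt(np.mean(x**2)) + 1e-30
    x += 0.3 * rng.standard_normal(n)
    x /= np.sqrt(np.mean(x**2)) + 1e-30
    return x.astype(np.float32)


def _burst_envelope(n: int, ramp: int) -> np.ndarray:
    """Unit envelope with raised-cosine ramps contained inside the burst."""
    env = np.ones(n, dtype=np.float32)
    ramp = min(ramp, n // 2)
    if ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(1, ramp + 1) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    return env


def simulate_session(config: SimulationConfig) -> tuple[Recording, EventTable, GroundTruth]:
    """Generate one subject's session.

    Returns the continuous recording (sensors + one acoustic channel), the
    stimulus event table, and the per-trial ground truth used as the oracle
    in downstream tests.  Deterministic under ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sfreq = cfg.sfreq
    ms = sfreq / 1000.0  # samples per millisecond

    epoch_len = int(round(5.0 * sfreq))
    gap = int(round(cfg.inter_trial_gap_s * sfreq))
    lead_in = int(round(0.5 * sfreq))
    stride = epoch_len + gap
    n_trials = cfg.n_trials
    n_samples = lead_in + n_trials * stride + lead_in

    # preallocate the full channel matrix (sensors + trailing audio row) and
    # fill sensor noise in channel blocks to keep the peak footprint low
    data = np.empty((cfg.n_sensors + 1, n_samples), dtype=np.float32)
    sensors = data[: cfg.n_sensors]
    bg = None
    if cfg.shared_background_weight > 0:
        bg = _bandlimited_noise(rng, (3, n_samples), sfreq, cfg.noise_lowpass_hz)
    block = 32
    for c0 in range(0, cfg.n_sensors, block):
        c1 = min(c0 + block, cfg.n_sensors)
        chunk = _bandlimited_noise(rng, (c1 - c0, n_samples), sfreq, cfg.noise_lowpass_hz)
        if bg is not None:
            mix = rng.standard_normal((c1 - c0, 3)).astype(np.float32) / np.sqrt(3)
            chunk += cfg.shared_background_weight * (mix @ bg)
            chunk /= chunk.std(axis=1, keepdims=True) + 1e-12
        sensors[c0:c1] = chunk
    del bg

    audio = data[cfg.n_sensors]
    audio[:] = rng.standard_normal(n_samples).astype(np.float32)

    n_speech = max(1, int(round(cfg.speech_sensor_fraction * cfg.n_sensors)))
    speech_sensors = rng.choice(cfg.n_sensors, size=n_speech, replace=False)
    speech_sensors.sort()

    # pseudo-randomized stimulus order: shuffled blocks of all stimuli
    order = np.concatenate(
        [rng.permutation(cfg.n_stimuli) + 1 for _ in range(cfg.n_trials_per_stimulus)]
    )

    onset_ms = rng.uniform(*cfg.onset_jitter_ms, size=n_trials)
    duration_ms = rng.uniform(*cfg.speech_duration_ms, size=n_trials)
    onset_ms = np.round(onset_ms).astype(np.int64)
    offset_ms = onset_ms + np.round(duration_ms).astype(np.int64)
    artifact_flags = rng.random(n_trials) < cfg.artifact_trial_rate

    g_neural = 10.0 ** (cfg.snr_db / 20.0)
    audio_snr = cfg.snr_db if cfg.audio_snr_db is None else cfg.audio_snr_db
    g_audio = 10.0 ** (audio_snr / 20.0)
    lead = int(round(cfg.neural_lead_ms * ms))

    onsets = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        ev = lead_in + t * stride  # stimulus-onset sample
        onsets[t] = ev
        cue = ev + int(round(2.0 * sfreq))  # production cue
        a = cue + int(round(onset_ms[t] * ms))  # first speech sample (0-based)
        b = cue + int(round(offset_ms[t] * ms))  # one past last speech sample

        # neural amplitude elevation on speech sensors, leading the acoustics
        env = _burst_envelope(b - (a - lead), ramp=int(round(10 * ms)))
        sensors[np.ix_(speech_sensors, range(a - lead, b))] *= 1.0 + (g_neural - 1.0) * env

        # acoustic burst: amplitude-modulated noise exactly over [a, b)
        env_a = _burst_envelope(b - a, ramp=int(round(1 * ms)))
        audio[a:b] += g_audio * env_a * _voiced_carrier(rng, b - a, sfreq)

        if artifact_flags[t]:
            # high-amplitude transient somewhere in the epoch, subset of sensors
            w = int(round(0.1 * sfreq))
            start = ev - lead_in + int(rng.integers(0, epoch_len - w))
            chans = rng.choice(cfg.n_sensors, size=max(1, cfg.n_sensors // 4), replace=False)
            art = 25.0 * np.hanning(w).astype(np.float32)
            sensors[chans, start : start + w] += art * rng.choice([-1.0, 1.0], size=(len(chans), 1)).astype(np.float32)

    names = [f"GRAD{i:03d}" for i in range(cfg.n_sensors)] + ["AUDIO"]
    kinds = ["gradiometer"] * cfg.n_sensors + ["acoustic"]
    recording = Recording(data, sfreq, names, kinds)
    events = EventTable(onsets, order, np.array([cfg.subject_id] * n_trials, dtype=object))
    truth = GroundTruth(onset_ms, offset_ms, speech_sensors, artifact_flags, order)
    return recording, events, truth


def make_worked_example(
    sfreq: float = 1000.0, n_sensors: int = 60, snr_db: float = 20.0, seed: int = 12345
) -> tuple[TrialEpoch, GroundTruth]:
    """One 2 s production-window trial with voicing from 402 to 931 ms.

    The acoustic burst occupies exactly the 1-based millisecond range
    402-931, so the labeling convention gives onset 401 (last pre-speech
    sample) and offset 931 (last speech sample).
    """
    rng = np.random.default_rng(seed)
    ms = sfreq / 1000.0
    T = int(round(2.0 * sfreq))
    onset, offset = 401, 931
    a, b = int(round(onset * ms)), int(round(offset * ms))  # 0-based slice [a, b)

    sensors = _bandlimited_noise(rng, (n_sensors, T), sfreq, 100.0)
    speech_sensors = np.arange(max(1, n_sensors // 6))
    g = 10.0 ** (snr_db / 20.0)
    lead = int(round(10 * ms))
    env = _burst_envelope(b - (a - lead), ramp=int(round(10 * ms)))
    sensors[np.ix_(speech_sensors, range(a - lead, b))] *= 1.0 + (g - 1.0) * env

    audio = rng.standard_normal(T).astype(np.float32)
    env_a = _burst_envelope(b - a, ramp=int(round(1 * ms)))
    audio[a:b] += g * env_a * _voiced_carrier(rng, b - a, sfreq)

    epoch = TrialEpoch(
        data=sensors,
        sfreq=sfreq,
        t0_offset=2.0,
        stage_marks=(-int(2.0 * sfreq), -int(1.0 * sfreq), 0, T),
        stimulus_id=2,
        audio=audio,
        subject_id="worked-example",
        trial_index=0,
        channel_names=[f"GRAD{i:03d}" for i in range(n_sensors)],
        channel_kinds=["gradiometer"] * n_sensors,
    )
    truth = GroundTruth(
        onset_ms=np.array([onset]),
        offset_ms=np.array([offset]),
        speech_sensors=speech_sensors,
        artifact_flags=np.array([False]),
        stimulus_order=np.array([2]),
    )
    return epoch, truth
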