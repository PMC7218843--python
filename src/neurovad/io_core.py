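"""Core data containers and I/O for multichannel speech-task recordings.

A session is a continuous sensor-by-time matrix (``Recording``) plus an
``EventTable`` of stimulus onsets.  Trials follow a time-locked delayed
overt-reading protocol: 0.5 s baseline, 1 s stimulus display, 1 s
preparation, then a 2 s overt production stage.  ``epoch_trials`` cuts the
recording into ``TrialEpoch`` objects spanning -0.5 s to 4.5 s around each
stimulus onset, with the protocol's stage boundaries precomputed.

The native on-disk container is a single HDF5 file
(``/data``, ``/sfreq``, ``/channel_names``, ``/channel_kinds``, ``/events``).
FIF files from MEG acquisition systems can be imported when ``mne`` is
installed; export is native-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized per-channel kind tags.
CHANNEL_KINDS = ("gradiometer", "magnetometer", "acoustic", "jaw", "eog", "ecg", "other")

# Protocol stage durations, seconds.
BASELINE_S = 0.5
STIMULUS_S = 1.0
PREPARATION_S = 1.0
PRODUCTION_S = 2.0
#: Epoch window relative to stimulus onset, seconds.
EPOCH_WINDOW_S = (-BASELINE_S, STIMULUS_S + PREPARATION_S + PRODUCTION_S + BASELINE_S)


@dataclass
class Recording:
    """Continuous multichannel session.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sensor signals in field units (arbitrary scale).
    sfreq : float
        Sampling frequency, samples/second.
    channel_names : list of str
    channel_kinds : list of str
        One tag from :data:`CHANNEL_KINDS` per channel.
    """

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    channel_kinds: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        n = self.data.shape[0]
        if len(self.channel_names) != n or len(self.channel_kinds) != n:
            raise ValueError("channel metadata length must match data row count")
        bad = set(self.channel_kinds) - set(CHANNEL_KINDS)
        if bad:
            raise ValueError(f"unknown channel kinds: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick_kinds(self, kinds) -> "Recording":
        """Return a copy restricted to channels of the given kinds."""
        idx = [i for i, k in enumerate(self.channel_kinds) if k in kinds]
        if not idx:
            raise ValueError(f"no channels of kind {kinds}")
        return Recording(
            self.data[idx],
            self.sfreq,
            [self.channel_names[i] for i in idx],
            [self.channel_kinds[i] for i in idx],
        )

    def acoustic_channel(self) -> np.ndarray:
        """The first acoustic channel's signal (1-D)."""
        for i, k in enumerate(self.channel_kinds):
            if k == "acoustic":
                return self.data[i]
        raise ValueError("recording has no acoustic channel")


@dataclass
class EventTable:
    """Stimulus events: onset sample (0-based), stimulus id, subject id."""

    onset_sample: np.ndarray
    stimulus_id: np.ndarray
    subject_id: np.ndarray

    def __post_init__(self) -> None:
        self.onset_sample = np.asarray(self.onset_sample, dtype=np.int64)
        self.stimulus_id = np.asarray(self.stimulus_id, dtype=np.int64)
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        if not (len(self.onset_sample) == len(self.stimulus_id) == len(self.subject_id)):
            raise ValueError("event columns must have equal length")
        if len(self.onset_sample) > 1 and np.any(np.diff(self.onset_sample) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onset_sample)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_sample": self.onset_sample,
                "stimulus_id": self.stimulus_id,
                "subject_id": self.subject_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        return cls(
            df["onset_sample"].to_numpy(),
            df["stimulus_id"].to_numpy(),
            df["subject_id"].to_numpy(),
        )

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        return cls.from_frame(pd.read_csv(Path(path), dtype={"subject_id": str}))


@dataclass
class TrialEpoch:
    """One trial cut around stimulus onset.

    ``stage_marks`` are epoch-relative sample indices (0-based) of
    stimulus-on, preparation-cue, production-cue and trial-end.  For the
    full -0.5 to 4.5 s epoch at 1 kHz these are (500, 1500, 2500, 4500).
    """

    data: np.ndarray
    sfreq: float
    t0_offset: float
    stage_marks: tuple[int, int, int, int]
    stimulus_id: int
    audio: np.ndarray | None = None
    subject_id: str = ""
    trial_index: int = -1
    channel_names: list[str] = field(default_factory=list)
    channel_kinds: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def stage_marks_for(sfreq: float) -> tuple[int, int, int, int]:
    """Epoch-relative stage boundaries for the delayed-reading protocol."""
    base = BASELINE_S
    marks = (
        base,
        base + STIMULUS_S,
        base + STIMULUS_S + PREPARATION_S,
        base + STIMULUS_S + PREPARATION_S + PRODUCTION_S,
    )
    return tuple(int(round(m * sfreq)) for m in marks)


def write_recording(recording: Recording, path, events: EventTable | None = None) -> Path:
    """Write a recording (and optionally its events) to the native HDF5 container."""
    if not np.isfinite(recording.data).all():
        raise ValueError("non-finite data")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("sfreq", data=float(recording.sfreq))
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("channel_names", data=np.array(recording.channel_names, dtype=object), dtype=str_dt)
        f.create_dataset("channel_kinds", data=np.array(recording.channel_kinds, dtype=object), dtype=str_dt)
        if events is not None:
            g = f.create_group("events")
            g.create_dataset("onset_sample", data=events.onset_sample)
            g.create_dataset("stimulus_id", data=events.stimulus_id)
            g.create_dataset("subject_id", data=np.array(events.subject_id, dtype=object), dtype=str_dt)
    return path


def read_recording(path, format: str = "native-container") -> tuple[Recording, EventTable | None]:
    """Read a recording from the native container or import from FIF.

    Returns ``(recording, events)``; events is None when the file stores none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native-container":
        return _read_native(path)
    if format == "fif-import":
        return _read_fif(path), None
    raise ValueError(f"unknown format: {format!r}")


def _read_native(path: Path) -> tuple[Recording, EventTable | None]:
    with h5py.File(path, "r") as f:
        if "sfreq" not in f:
            raise ValueError("missing sampling rate")
        data = f["data"][()]
        if data.shape[0] == 0:
            raise ValueError("empty channel set")
        rec = Recording(
            data,
            float(f["sfreq"][()]),
            [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_names"][()]],
            [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_kinds"][()]],
        )
        events = None
        if "events" in f:
            g = f["events"]
            events = EventTable(
                g["onset_sample"][()],
                g["stimulus_id"][()],
                np.array([s.decode() if isinstance(s, bytes) else str(s) for s in g["subject_id"][()]], dtype=object),
            )
    return rec, events


#: FIF channel-type tag -> native channel kind.
_FIF_KIND_MAP = {
    "grad": "gradiometer",
    "mag": "magnetometer",
    "misc": "acoustic",  # ADC/audio channels are typed 'misc' in FIF
    "eog": "eog",
    "ecg": "ecg",
}


def _read_fif(path: Path) -> Recording:
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("FIF import requires the optional 'mne' dependency") from e
    raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    if len(raw.ch_names) == 0:
        raise ValueError("empty channel set")
    kinds = [_FIF_KIND_MAP.get(t, "other") for t in raw.get_channel_types()]
    return Recording(raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names), kinds)


def epoch_trials(
    recording: Recording,
    events: EventTable,
    window: tuple[float, float] = EPOCH_WINDOW_S,
) -> list[TrialEpoch]:
    """Cut one :class:`TrialEpoch` per in-bounds event.

    Events whose window would run past either edge of the recording are
    skipped with a log entry rather than raising, mirroring how truncated
    trials are discarded during acquisition review.
    """
    sfreq = recording.sfreq
    pre = int(round(-window[0] * sfreq))
    post = int(round(window[1] * sfreq))
    marks = stage_marks_for(sfreq)
    sensor_idx = [i for i, k in enumerate(recording.channel_kinds) if k not in ("acoustic",)]
    # contiguous sensor block -> slice (view), avoids copying the session
    if sensor_idx and sensor_idx == list(range(sensor_idx[0], sensor_idx[-1] + 1)):
        sensor_sel: slice | list[int] = slice(sensor_idx[0], sensor_idx[-1] + 1)
    else:
        sensor_sel = sensor_idx
    try:
        audio_full = recording.acoustic_channel()
    except ValueError:
        audio_full = None
    epochs: list[TrialEpoch] = []
    for j in range(len(events)):
        onset = int(events.onset_sample[j])
        start, stop = onset - pre, onset + post
        if start < 0 or stop > recording.n_samples:
            logger.warning("trial %d at sample %d skipped: window [%d, %d) out of bounds", j, onset, start, stop)
            continue
        epochs.append(
            TrialEpoch(
                data=recording.data[sensor_sel, start:stop],
                sfreq=sfreq,
                t0_offset=window[0],
                stage_marks=marks,
                stimulus_id=int(events.stimulus_id[j]),
                audio=None if audio_full is None else audio_full[start:stop].copy(),
                subject_id=str(events.subject_id[j]),
                trial_index=j,
                channel_names=[recording.channel_names[i] for i in sensor_idx],
                channel_kinds=[recording.channel_kinds[i] for i in sensor_idx],
            )
        )
    return epochs


def copy_epoch_with(epoch: TrialEpoch, **kwargs) -> TrialEpoch:
    """Shallow copy of an epoch with selected fields replaced."""
    return replace(epoch, **kwargs)
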