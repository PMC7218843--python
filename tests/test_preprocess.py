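import numpy as np
import pytest

from neurovad.io_core import Recording, TrialEpoch, epoch_trials
from neurovad.preprocess import (
    PreprocessConfig,
    drop_bad_channels,
    extract_production_window,
    preprocess_epochs,
    reject_artifact_trials,
    resample_epoch,
    select_gradiometers,
    wavelet_denoise,
)
from neurovad.synthetic import SimulationConfig, simulate_session


def _epoch(data, sfreq=1000.0, marks=None):
    n = data.shape[0]
    return TrialEpoch(
        data=data,
        sfreq=sfreq,
        t0_offset=-0.5,
        stage_marks=marks or (int(0.5 * sfreq), int(1.5 * sfreq), int(2.5 * sfreq), int(4.5 * sfreq)),
        stimulus_id=1,
        audio=np.zeros(data.shape[1]),
        channel_names=[f"GRAD{i:03d}" for i in range(n)],
        channel_kinds=["gradiometer"] * n,
    )


class TestSelectGradiometers:
    def test_mixed_recording_keeps_gradiometers_only(self):
        rec = Recording(
            np.zeros((4, 10)),
            1000.0,
            ["g1", "m1", "g2", "a1"],
            ["gradiometer", "magnetometer", "gradiometer", "acoustic"],
        )
        out = select_gradiometers(rec)
        assert out.channel_names == ["g1", "g2"]
        assert out.channel_kinds == ["gradiometer", "gradiometer"]

    def test_all_gradiometer_input_is_identity(self, small_production_epochs):
        epochs, _ = small_production_epochs
        out = select_gradiometers(epochs[0])
        np.testing.assert_array_equal(out.data, epochs[0].data)

    def test_no_gradiometers_raises(self):
        rec = Recording(np.zeros((1, 10)), 1000.0, ["m"], ["magnetometer"])
        with pytest.raises(ValueError):
            select_gradiometers(rec)


class TestDropBadChannels:
    def test_constant_channel_dropped_as_unresponsive(self):
        rng = np.random.default_rng(0)
        epochs = [_epoch(rng.standard_normal((4, 500))) for _ in range(3)]
        for e in epochs:
            e.data[2] = 0.0
        out, dropped = drop_bad_channels(epochs)
        assert dropped == ["GRAD002"]
        assert all(e.n_channels == 3 for e in out)

    def test_high_variance_channel_dropped_as_noisy(self):
        rng = np.random.default_rng(1)
        epochs = [_epoch(rng.standard_normal((6, 500))) for _ in range(3)]
        for e in epochs:
            e.data[4] *= 10.0  # 100x variance
        _, dropped = drop_bad_channels(epochs)
        assert dropped == ["GRAD004"]

    def test_clean_session_has_zero_drops(self, small_production_epochs):
        epochs, _ = small_production_epochs
        out, dropped = drop_bad_channels(list(epochs))
        assert dropped == []
        assert len(out) == len(epochs)

    def test_channel_order_preserved(self):
        rng = np.random.default_rng(2)
        epochs = [_epoch(rng.standard_normal((5, 300))) for _ in range(2)]
        for e in epochs:
            e.data[0] = 0.0
        out, _ = drop_bad_channels(epochs)
        assert out[0].channel_names == ["GRAD001", "GRAD002", "GRAD003", "GRAD004"]


class TestRejectArtifactTrials:
    def test_rejected_fraction_tracks_artifact_rate(self):
        cfg = SimulationConfig(
            n_sensors=30, n_trials_per_stimulus=80, artifact_trial_rate=0.25, seed=6
        )
        rec, ev, truth = simulate_session(cfg)
        epochs = [select_gradiometers(e) for e in epoch_trials(rec, ev)]
        _, rejected = reject_artifact_trials(epochs)
        frac = len(rejected) / len(epochs)
        assert abs(frac - 0.25) < 0.05  # 400 trials
        # rejections should be the flagged trials
        assert set(rejected) <= set(np.flatnonzero(truth.artifact_flags))

    def test_artifact_free_session_keeps_everything(self, small_production_epochs):
        epochs, _ = small_production_epochs
        kept, rejected = reject_artifact_trials(list(epochs))
        assert rejected == []
        assert len(kept) == len(epochs)

    def test_nonpositive_threshold_rejected(self, small_production_epochs):
        epochs, _ = small_production_epochs
        with pytest.raises(ValueError):
            reject_artifact_trials(list(epochs), zscore_threshold=0.0)

    def test_trial_order_preserved(self):
        cfg = SimulationConfig(n_sensors=10, n_trials_per_stimulus=6, artifact_trial_rate=0.3, seed=9)
        rec, ev, _ = simulate_session(cfg)
        epochs = [select_gradiometers(e) for e in epoch_trials(rec, ev)]
        kept, _ = reject_artifact_trials(epochs)
        kept_idx = [e.trial_index for e in kept]
        assert kept_idx == sorted(kept_idx)


class TestWaveletDenoise:
    def test_retains_low_frequency_tone(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 50 * t)
        e = _epoch(np.vstack([x, x]))
        y = wavelet_denoise(e).data[0]
        r = np.corrcoef(x, y)[0, 1]
        assert r >= 0.99

    def test_attenuates_high_frequency_tone(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 400 * t)
        e = _epoch(np.vstack([x, x]))
        y = wavelet_denoise(e).data[0]
        assert np.mean(y**2) <= 0.05 * np.mean(x**2)

    def test_zero_signal_maps_to_zero(self):
        e = _epoch(np.zeros((2, 1024)))
        assert np.allclose(wavelet_denoise(e).data, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        e = _epoch(rng.standard_normal((3, 2000)))
        once = wavelet_denoise(e)
        twice = wavelet_denoise(once)
        dev = np.abs(twice.data - once.data).max() / e.data.std()
        assert dev < 1e-8

    def test_output_length_preserved_for_odd_length(self):
        rng = np.random.default_rng(4)
        e = _epoch(rng.standard_normal((2, 1999)))
        assert wavelet_denoise(e).data.shape == (2, 1999)

    def test_too_short_epoch_raises(self):
        e = _epoch(np.zeros((2, 8)))
        with pytest.raises(ValueError, match="shorter"):
            wavelet_denoise(e)

    def test_config_level_band_consistency_enforced(self):
        with pytest.raises(ValueError, match="exceeds target"):
            PreprocessConfig(decomposition_level=1)


class TestProductionWindow:
    def test_window_starts_at_cue_with_2s_length(self, small_session):
        _, recording, events, _ = small_session
        epochs = epoch_trials(recording, events)
        w = extract_production_window(epochs[0])
        assert w.n_samples == 2000
        assert w.stage_marks[2] == 0
        np.testing.assert_array_equal(w.data, epochs[0].data[:, 2500:4500])

    @pytest.mark.parametrize("sfreq,expected", [(1000.0, 2000), (4000.0, 8000)])
    def test_window_length_scales_with_sfreq(self, sfreq, expected):
        rng = np.random.default_rng(5)
        e = _epoch(rng.standard_normal((2, int(5 * sfreq))), sfreq=sfreq)
        assert extract_production_window(e).n_samples == expected

    def test_worked_example_burst_inside_window(self, worked_example):
        epoch, truth = worked_example
        # already a production window; burst energy at 1-based ms 402-931
        seg = epoch.audio[truth.onset_ms[0] : truth.offset_ms[0]]
        assert np.mean(seg**2) > 10 * np.mean(epoch.audio[:400] ** 2)


class TestResample:
    def test_4khz_to_1khz_preserves_duration_and_marks(self):
        rng = np.random.default_rng(6)
        sfreq = 4000.0
        e = _epoch(rng.standard_normal((2, int(5 * sfreq))), sfreq=sfreq)
        out = resample_epoch(e, 1000.0)
        assert out.n_samples == 5000
        assert out.stage_marks == (500, 1500, 2500, 4500)

    def test_identity_when_already_at_target(self, small_production_epochs):
        epochs, _ = small_production_epochs
        assert resample_epoch(epochs[0], 1000.0) is epochs[0]


def test_full_chain_preserves_ground_truth_alignment():
    cfg = SimulationConfig(n_sensors=20, n_trials_per_stimulus=8, artifact_trial_rate=0.3, seed=8)
    rec, ev, truth = simulate_session(cfg)
    out, report = preprocess_epochs(epoch_trials(rec, ev))
    kept_idx = [e.trial_index for e in out]
    # rejected trials are exactly the generator's artifact trials here
    assert set(report["rejected_trials"]).isdisjoint(kept_idx)
    for e in out:
        on, off = truth.onset_ms[e.trial_index], truth.offset_ms[e.trial_index]
        burst = np.mean(e.audio[on:off] ** 2)
        quiet = np.mean(e.audio[: on - 5] ** 2)
        assert burst > 3 * quiet
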