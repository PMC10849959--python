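"""Sleep scoring: spectra, features, classification, episodes, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliasleep import sleep, synth
from gliasleep.sleep import Episode, Hypnogram, Recording


def _sine_recording(freq_hz, duration_s=60.0, fs=200.0):
    t = np.arange(int(duration_s * fs)) / fs
    eeg = np.sin(2 * np.pi * freq_hz * t)
    return Recording(eeg=eeg, emg=np.zeros_like(eeg), fs=fs)


class TestEpochSpectrogram:
    def test_pure_delta_tone_concentrates_in_delta_band(self):
        rec = _sine_recording(2.0)
        freqs, psd = sleep.epoch_spectrogram(rec, epoch_s=5.0)
        delta = sleep.band_power(freqs, psd, 0.5, 4.0)
        total = sleep.band_power(freqs, psd, 0.0, freqs[-1])
        assert np.all(delta / total > 0.95)

    def test_parseval_white_noise(self, rng):
        eeg = rng.standard_normal(5 * 1500)
        rec = Recording(eeg=eeg, emg=np.zeros_like(eeg), fs=1500.0)
        freqs, psd = sleep.epoch_spectrogram(rec, epoch_s=5.0)
        df = freqs[1] - freqs[0]
        # time-domain variance oracle (periodogram removes the epoch mean)
        assert np.sum(psd[0]) * df == pytest.approx(np.var(eeg), rel=0.01)

    def test_epoch_count_and_partial_epoch_dropped(self):
        rec = _sine_recording(2.0, duration_s=62.0, fs=200.0)
        _, psd = sleep.epoch_spectrogram(rec, epoch_s=5.0)
        assert psd.shape[0] == 12

    def test_short_recording_rejected(self):
        rec = _sine_recording(2.0, duration_s=2.0, fs=200.0)
        with pytest.raises(ValueError, match="shorter than one"):
            sleep.epoch_spectrogram(rec, epoch_s=5.0)

    def test_frequency_resolution_at_default_settings(self):
        rec = _sine_recording(2.0, duration_s=5.0, fs=1500.0)
        freqs, _ = sleep.epoch_spectrogram(rec, epoch_s=5.0)
        assert freqs[1] - freqs[0] == pytest.approx(0.2)


class TestExtractFeatures:
    def test_flat_psd_band_powers(self):
        freqs = np.arange(0, 100.2, 0.2)
        h = 2.0
        psd = np.full((4, freqs.size), h)
        emg = np.zeros(4 * 1000)
        feats = sleep.extract_features(freqs, psd, emg, fs=200.0, epoch_s=5.0)
        assert feats["power_delta"].to_numpy() == pytest.approx([3.5 * h] * 4)
        assert feats["power_theta"].to_numpy() == pytest.approx([3.0 * h] * 4)
        assert feats["power_total_0_25"].to_numpy() == pytest.approx([25.0 * h] * 4)

    def test_zero_emg_gives_zero_rms(self):
        freqs = np.arange(0, 50.2, 0.2)
        psd = np.ones((3, freqs.size))
        feats = sleep.extract_features(
            freqs, psd, np.zeros(3 * 1000), fs=200.0, epoch_s=5.0
        )
        assert np.all(feats["emg_rms"] == 0)

    def test_span_mismatch_rejected(self):
        freqs = np.arange(0, 50.2, 0.2)
        psd = np.ones((3, freqs.size))
        with pytest.raises(ValueError, match="epochs"):
            sleep.extract_features(freqs, psd, np.zeros(1000), fs=200.0, epoch_s=5.0)

    def test_nrem_session_theta_delta_ratio_below_one(self):
        cfg = synth.SleepSynthConfig(
            duration_s=300.0,
            transition_matrix=np.eye(3),
            initial_state="N",
            seed=5,
        )
        rec, _ = synth.gen_sleep_session(cfg)
        freqs, psd = sleep.epoch_spectrogram(rec)
        feats = sleep.extract_features(freqs, psd, rec.emg, rec.fs)
        assert feats["theta_delta_ratio"].median() < 1


class TestClassifyEpochs:
    def test_high_emg_everywhere_scores_all_wake(self):
        import pandas as pd

        feats = pd.DataFrame(
            {
                "epoch_index": range(5),
                "power_delta": [1.0] * 5,
                "power_theta": [0.5] * 5,
                "power_total_0_25": [2.0] * 5,
                "theta_delta_ratio": [0.5] * 5,
                "emg_rms": [10.0] * 5,
            }
        )
        h = sleep.classify_epochs(feats, emg_threshold=1.0)
        assert np.all(h.states == "W")

    def test_single_epoch_input(self):
        import pandas as pd

        feats = pd.DataFrame(
            {
                "epoch_index": [0],
                "power_delta": [1.0],
                "power_theta": [0.2],
                "power_total_0_25": [2.0],
                "theta_delta_ratio": [0.2],
                "emg_rms": [0.1],
            }
        )
        h = sleep.classify_epochs(feats, emg_threshold=1.0)
        assert h.n_epochs == 1 and h.states[0] == "N"

    def test_synthetic_session_recovered(self, short_sleep_session):
        _, rec, truth = short_sleep_session
        freqs, psd = sleep.epoch_spectrogram(rec)
        feats = sleep.extract_features(freqs, psd, rec.emg, rec.fs)
        h = sleep.classify_epochs(feats)
        accuracy = np.mean(h.states == truth.hypnogram_true.states)
        assert accuracy >= 0.9

    def test_smoothing_removes_isolated_singletons(self):
        states = np.array(list("NNNWNNN"))
        assert "".join(sleep.smooth_singletons(states)) == "NNNNNNN"


class TestEpisodes:
    def test_run_length_merge_example(self):
        h = Hypnogram(states=np.array(list("NNNWWR")), epoch_s=5.0)
        episodes = sleep.merge_episodes(h)
        assert episodes == [
            Episode("N", 0.0, 15.0),
            Episode("W", 15.0, 10.0),
            Episode("R", 25.0, 5.0),
        ]

    def test_single_state_one_episode(self):
        h = Hypnogram(states=np.array(["W"] * 10), epoch_s=5.0)
        episodes = sleep.merge_episodes(h)
        assert len(episodes) == 1
        assert episodes[0].duration_s == 50.0

    @settings(deadline=None)
    @given(
        st.lists(st.sampled_from("WNR"), min_size=1, max_size=200),
        st.sampled_from([2.0, 5.0, 10.0]),
    )
    def test_merge_expand_round_trip(self, labels, epoch_s):
        h = Hypnogram(states=np.array(labels), epoch_s=epoch_s)
        episodes = sleep.merge_episodes(h)
        # episodes tile the session exactly and adjacent states differ
        assert sum(ep.duration_s for ep in episodes) == pytest.approx(h.duration_s)
        assert all(a.state != b.state for a, b in zip(episodes, episodes[1:]))
        back = sleep.expand_episodes(episodes, epoch_s)
        assert np.array_equal(back.states, h.states)


class TestStateMetrics:
    def test_all_nrem(self):
        h = Hypnogram(states=np.array(["N"] * 12), epoch_s=5.0)
        m = sleep.state_metrics(h, bin_s=30.0)
        assert np.all(m.percent_time["N"] == 100.0)
        assert np.all(m.percent_time[["W", "R"]] == 0.0)
        assert np.isnan(m.mean_episode_duration_s["W"])
        assert m.episodes_per_hour["W"] == 0.0

    def test_mixed_episode_arithmetic(self):
        h = Hypnogram(states=np.array(list("NNNWWR")), epoch_s=5.0)
        m = sleep.state_metrics(h, bin_s=30.0)
        row = m.percent_time.iloc[0]
        assert row["N"] == pytest.approx(50.0)
        assert row["W"] == pytest.approx(100 / 3)
        assert row["R"] == pytest.approx(100 / 6)
        assert m.mean_episode_duration_s["N"] == 15.0
        assert m.episodes_per_hour["R"] == pytest.approx(1 / (30 / 3600))

    def test_rows_sum_to_100(self, short_sleep_session):
        _, _, truth = short_sleep_session
        m = sleep.state_metrics(truth.hypnogram_true, bin_s=60.0)
        sums = m.percent_time[["W", "N", "R"]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-6)

    def test_non_multiple_bin_rejected(self):
        h = Hypnogram(states=np.array(["N"] * 12), epoch_s=5.0)
        with pytest.raises(ValueError, match="multiple"):
            sleep.state_metrics(h, bin_s=7.0)


class TestNormalizedSpectrum:
    def test_unit_integral(self, short_sleep_session):
        _, rec, truth = short_sleep_session
        freqs, dens = sleep.normalized_spectrum(rec, truth.hypnogram_true, "N")
        assert np.trapezoid(dens, freqs) == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_spectrum_is_flat(self, rng):
        eeg = rng.standard_normal(200 * 5 * 400)
        rec = Recording(eeg=eeg, emg=np.zeros_like(eeg), fs=400.0)
        h = Hypnogram(states=np.array(["N"] * 200), epoch_s=5.0)
        freqs, dens = sleep.normalized_spectrum(rec, h, "N")
        # flat-line oracle: density should hover around 1/25 per Hz
        assert np.mean(dens[freqs > 0]) * 25.0 == pytest.approx(1.0, rel=0.05)
        # the DC bin is removed by detrending; check flatness above it
        assert np.max(np.abs(dens[freqs > 0] * 25.0 - 1.0)) < 0.5

    def test_absent_state_error_names_state(self, short_sleep_session):
        _, rec, _ = short_sleep_session
        h = Hypnogram(states=np.array(["N"] * 120), epoch_s=5.0)
        with pytest.raises(ValueError, match="'R'"):
            sleep.normalized_spectrum(rec, h, "R")
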