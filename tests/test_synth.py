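"""Generator contracts: determinism, ground-truth consistency, signal regimes."""

import numpy as np
import pytest
from scipy import stats as sps

from gliasleep import sleep, synth


class TestSleepGenerator:
    def test_absorbing_chain_stays_in_initial_state(self):
        cfg = synth.SleepSynthConfig(
            duration_s=300.0,
            transition_matrix=np.eye(3),
            initial_state="N",
            seed=0,
        )
        _, truth = synth.gen_sleep_session(cfg)
        assert np.all(truth.hypnogram_true.states == "N")

    def test_same_seed_bit_identical(self):
        cfg = synth.SleepSynthConfig(duration_s=120.0, seed=1)
        rec_a, truth_a = synth.gen_sleep_session(cfg)
        rec_b, truth_b = synth.gen_sleep_session(cfg)
        assert np.array_equal(rec_a.eeg, rec_b.eeg)
        assert np.array_equal(rec_a.emg, rec_b.emg)
        assert np.array_equal(
            truth_a.hypnogram_true.states, truth_b.hypnogram_true.states
        )

    def test_invalid_transition_matrix_rejected(self):
        bad = np.full((3, 3), 0.5)
        with pytest.raises(ValueError, match="stochastic"):
            synth.SleepSynthConfig(duration_s=60.0, transition_matrix=bad)

    def test_nrem_delta_power_dominates_wake(self):
        """With 10x NREM/wake delta separation, per-epoch FFT delta power
        ranks NREM above wake in >95% of epoch pairs."""
        band_power = {
            "W": {"delta": 1.0, "theta": 1.0, "broad": 1.0},
            "N": {"delta": 10.0, "theta": 0.5, "broad": 1.0},
            "R": {"delta": 0.5, "theta": 5.0, "broad": 1.0},
        }
        cfg = synth.SleepSynthConfig(
            duration_s=1200.0, band_power=band_power, seed=3
        )
        rec, truth = synth.gen_sleep_session(cfg)
        freqs, psd = sleep.epoch_spectrogram(rec)  # independent periodogram oracle
        delta = sleep.band_power(freqs, psd, 0.5, 4.0)
        states = truth.hypnogram_true.states
        d_n, d_w = delta[states == "N"], delta[states == "W"]
        assert d_n.size > 5 and d_w.size > 5
        frac = np.mean(d_n[:, None] > d_w[None, :])
        assert frac > 0.95

    def test_occupancy_matches_stationary_distribution(self):
        """Marginal occupancy of a long chain converges to the stationary
        distribution.  The chain is thinned to ~independent draws before
        the chi-square test (consecutive epochs are strongly correlated,
        which would invalidate the test's sampling assumption)."""
        tm = synth.default_transition_matrix()
        states = synth.sample_markov_states(
            tm, 10_000, np.random.default_rng(0)
        )
        pi = synth.stationary_distribution(tm)
        thinned = states[::100]
        observed = np.array([(thinned == s).sum() for s in sleep.STATES])
        chi2 = sps.chisquare(observed, f_exp=pi * thinned.size)
        assert chi2.pvalue > 0.01

    def test_band_power_ordering_by_state(self, short_sleep_session):
        _, rec, truth = short_sleep_session
        freqs, psd = sleep.epoch_spectrogram(rec)
        delta = sleep.band_power(freqs, psd, 0.5, 4.0)
        theta = sleep.band_power(freqs, psd, 6.0, 9.0)
        states = truth.hypnogram_true.states
        assert delta[states == "N"].mean() > delta[states == "W"].mean()
        if np.any(states == "R"):
            ratio = theta / delta
            assert ratio[states == "R"].mean() > ratio[states == "N"].mean()


class TestCalciumGenerator:
    def test_zero_rate_yields_no_events(self):
        cfg = synth.CalciumSynthConfig(
            n_rois=3, duration_s=300.0, event_rate_per_min=0.0, seed=0
        )
        traces, truth = synth.gen_calcium(cfg)
        assert all(len(roi) == 0 for roi in truth.events_true)
        for trace in traces.traces:
            assert abs(trace.values.mean() - cfg.baseline_level) < 3 * cfg.noise_sd

    def test_noiseless_event_peak_matches_amplitude(self):
        cfg = synth.CalciumSynthConfig(
            n_rois=5,
            duration_s=600.0,
            event_rate_per_min=0.2,
            noise_sd=0.0,
            drift_amplitude=0.0,
            seed=4,
        )
        traces, truth = synth.gen_calcium(cfg)
        frame_gap = 1.0 / cfg.frame_rate
        for trace, events in zip(traces.traces, truth.events_true):
            if len(events) != 1:
                continue
            peak_dff = trace.values.max() / cfg.baseline_level - 1.0
            amp = events[0][1]
            # sampled peak lags the true onset by < one frame of decay
            assert amp * np.exp(-frame_gap / cfg.decay_tau_s) <= peak_dff <= amp + 1e-12

    def test_total_event_count_in_poisson_interval(self):
        """2/min x 40 min x 10 ROIs: count within the Poisson 99% interval
        around 800 (interval from the analytic tail computation)."""
        cfg = synth.CalciumSynthConfig(
            n_rois=10, duration_s=2400.0, event_rate_per_min=2.0, seed=0
        )
        _, truth = synth.gen_calcium(cfg)
        total = sum(len(roi) for roi in truth.events_true)
        lo, hi = sps.poisson.ppf([0.005, 0.995], 800)
        assert lo <= total <= hi

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            synth.CalciumSynthConfig(duration_s=0.5)


class TestSensorGenerator:
    def test_null_effect_pre_post_consistent_with_zero(self):
        cfg = synth.SensorSynthConfig(
            duration_s=4800.0, treatment_time_s=1800.0, effect_size_z=0.0, seed=2
        )
        traces, truth = synth.gen_sensor(cfg)
        assert np.all(truth.effect_true == 0.0)
        t_cut = int(cfg.treatment_time_s * cfg.frame_rate)
        diffs = [
            t.values[t_cut:].mean() - t.values[:t_cut].mean() for t in traces.traces
        ]
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 4 * se + 1e-12

    def test_seeds_change_noise_not_truth(self):
        base = dict(duration_s=1200.0, treatment_time_s=600.0, effect_size_z=-2.0)
        tr_a, truth_a = synth.gen_sensor(synth.SensorSynthConfig(seed=0, **base))
        tr_b, truth_b = synth.gen_sensor(synth.SensorSynthConfig(seed=1, **base))
        assert np.array_equal(truth_a.effect_true, truth_b.effect_true)
        assert not np.array_equal(tr_a.traces[0].values, tr_b.traces[0].values)

    def test_state_coupling_requires_valid_states(self):
        with pytest.raises(ValueError, match="unknown states"):
            synth.SensorSynthConfig(
                duration_s=600.0, treatment_time_s=300.0, state_coupling={"X": 1.0}
            )


class TestVolumeGenerator:
    def test_sphere_distance_formula(self):
        centers = np.array([[0.0, 0.0, 0.0]])
        radii = np.array([5.0])
        points = np.array([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        d = synth.sphere_min_distances(points, centers, radii)
        assert d == pytest.approx([0.0, 7.0, 0.0])

    def test_ground_truth_matches_direct_formula(self):
        cfg = synth.VolumeSynthConfig(n_spheres=5, n_boutons=50, seed=1)
        scene, truth = synth.gen_volume(cfg)
        assert truth.distances_true.shape == (50,)
        assert np.all(truth.distances_true >= 0)
        assert scene.mask.any()

    def test_boutons_without_spheres_rejected(self):
        with pytest.raises(ValueError, match="sphere"):
            synth.VolumeSynthConfig(n_spheres=0, n_boutons=10)
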