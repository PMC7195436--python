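import numpy as np
import pytest
from scipy import stats

from czdown import features as ft
from czdown import model, synchrony, synthetic
from czdown.segments import SegmentStream, SeizureCatalog


class TestConfig:
    def test_validation(self):
        with pytest.raises(synthetic.ConfigError):
            synthetic.SimulatorConfig(r=-1.0).validate()
        with pytest.raises(synthetic.ConfigError):
            synthetic.SimulatorConfig(noise_sd=-0.1).validate()
        with pytest.raises(synthetic.ConfigError):
            synthetic.SimulatorConfig(cadence_min=0.01).validate()
        synthetic.SimulatorConfig().validate()

    def test_segment_grid(self):
        cfg = synthetic.SimulatorConfig(duration_days=1.0)
        assert cfg.n_segments == 720
        ts = cfg.segment_times_s()
        assert ts[1] - ts[0] == 120.0


class TestSimulateState:
    def test_deterministic_relaxation(self):
        cfg = synthetic.SimulatorConfig(noise_sd=0.0, duration_days=0.5,
                                        n_channels=1)
        traj = synthetic.simulate_state(cfg, z0=0.7)
        assert traj.z[-1] == pytest.approx(np.sqrt(0.5), abs=1e-4)
        assert np.all(np.abs(traj.z[-100:] - np.sqrt(0.5)) < 1e-3)

    def test_single_transition_after_fold(self):
        cfg = synthetic.SimulatorConfig(noise_sd=0.0, duration_days=2.0,
                                        n_channels=1)
        n = int(cfg.duration_h / cfg.dt)
        k = np.linspace(0.0, 200.0, n)
        traj = synthetic.simulate_state(cfg, k_override=k, z0=-0.7)
        assert traj.onsets_h.size == 1
        (_, _), (_, k_fold) = model.critical_point(cfg.r)
        k_at_onset = np.interp(traj.onsets_h[0], traj.t_h, traj.k)
        assert k_at_onset > k_fold    # crossing happens after the fold

    def test_no_transitions_far_from_fold(self):
        total = 0
        for seed in range(10):
            cfg = synthetic.SimulatorConfig(noise_sd=0.1, duration_days=10.0,
                                            n_channels=1, seed=seed)
            total += synthetic.simulate_state(cfg).onsets_h.size
        assert total == 0

    def test_seeded_reproducibility(self):
        cfg = synthetic.SimulatorConfig(duration_days=1.0, seed=3)
        t1 = synthetic.simulate_state(cfg)
        t2 = synthetic.simulate_state(cfg)
        np.testing.assert_array_equal(t1.z, t2.z)

    def test_divergence_guard(self):
        cfg = synthetic.SimulatorConfig(noise_sd=0.0, duration_days=0.1,
                                        dt=10.0)   # absurd step
        with pytest.raises((synthetic.StepSizeError, synthetic.ConfigError)):
            synthetic.simulate_state(cfg, z0=5.0)

    def test_dt_convergence_of_crossing_time(self):
        onsets = []
        for dt in (0.01, 0.005):
            cfg = synthetic.SimulatorConfig(noise_sd=0.0, duration_days=2.0,
                                            n_channels=1, dt=dt)
            n = int(cfg.duration_h / cfg.dt)
            k = np.linspace(0.0, 200.0, n)
            traj = synthetic.simulate_state(cfg, k_override=k, z0=-0.7)
            onsets.append(traj.onsets_h[0])
        # halving dt moves the crossing by less than one reporting sample
        assert abs(onsets[0] - onsets[1]) * 60.0 < 2.0   # minutes


class TestLabelSeizures:
    def test_monostable_empty(self):
        cfg = synthetic.SimulatorConfig(noise_sd=0.05, duration_days=2.0,
                                        n_channels=1, seed=1)
        traj = synthetic.simulate_state(cfg)
        assert len(synthetic.label_seizures(traj, cfg)) == 0

    def test_forced_single_crossing(self):
        cfg = synthetic.SimulatorConfig(noise_sd=0.0, duration_days=2.0,
                                        n_channels=1)
        n = int(cfg.duration_h / cfg.dt)
        traj = synthetic.simulate_state(
            cfg, k_override=np.linspace(0, 200, n), z0=-0.7)
        catalog = synthetic.label_seizures(traj, cfg)
        assert len(catalog) == 1
        assert catalog.onsets_s[0] == pytest.approx(traj.onsets_h[0] * 3600.0)

    def test_refractory_separation(self):
        cfg = synthetic.SimulatorConfig(noise_sd=0.6, duration_days=3.0,
                                        n_channels=1, k_baseline=120.0, seed=2)
        traj = synthetic.simulate_state(cfg)
        catalog = synthetic.label_seizures(traj, cfg)
        if len(catalog) >= 2:
            gaps = np.diff(catalog.onsets_s) - catalog.durations_s[:-1]
            assert np.all(gaps >= cfg.refractory_min * 60.0 - 1.0)

    def test_onsets_strictly_increasing(self):
        cfg = synthetic.SimulatorConfig(noise_sd=0.5, duration_days=5.0,
                                        n_channels=1, k_baseline=110.0, seed=3)
        traj = synthetic.simulate_state(cfg)
        catalog = synthetic.label_seizures(traj, cfg)
        if len(catalog) > 1:
            assert np.all(np.diff(catalog.onsets_s) > 0)
        assert np.all(catalog.onsets_s <= cfg.duration_h * 3600.0)


class TestSynthesizeSegments:
    def test_stationary_far_from_fold(self):
        cfg = synthetic.SimulatorConfig(noise_sd=0.0, duration_days=2.0,
                                        n_channels=1, seed=0)
        traj = synthetic.simulate_state(cfg)
        stream = synthetic.synthesize_segments(traj, cfg)
        feats = ft.compute_features(stream)
        y = feats.acfw[0]
        res = stats.linregress(np.arange(y.size), y)
        # slope CI contains 0 (99.7% band)
        assert abs(res.slope) < 3 * res.stderr

    def test_acfw_grows_toward_fold(self):
        pairs = []
        for seed in range(5):
            cfg = synthetic.SimulatorConfig(noise_sd=0.0, duration_days=2.0,
                                            n_channels=1, seed=seed)
            n = int(cfg.duration_h / cfg.dt)
            k = np.linspace(0.0, 130.0, n)
            traj = synthetic.simulate_state(cfg, k_override=k, z0=-0.7)
            stream = synthetic.synthesize_segments(traj, cfg)
            feats = ft.compute_features(stream)
            q = feats.n_segments // 5
            pairs.append((np.nanmean(feats.acfw[0, :q]),
                          np.nanmean(feats.acfw[0, -q:])))
        far, near = zip(*pairs)
        assert all(n > f for f, n in zip(far, near))

    def test_cross_channel_acfw_correlation(self):
        cfg = synthetic.SimulatorConfig(noise_sd=0.05, duration_days=3.0,
                                        n_channels=2, k_multidien_amp=80.0,
                                        multidien_period_h=36.0, seed=1)
        traj = synthetic.simulate_state(cfg)
        stream = synthetic.synthesize_segments(traj, cfg)
        feats = ft.compute_features(stream)
        r = np.corrcoef(feats.acfw[0], feats.acfw[1])[0, 1]
        assert r > 0.5

    def test_ar_oracle_far_from_fold(self):
        # measured lag-wise ACF matches a^lag for the configured coefficient
        cfg = synthetic.SimulatorConfig(noise_sd=0.0, duration_days=1.0,
                                        n_channels=1, measurement_noise_sd=0.0,
                                        seed=2)
        traj = synthetic.simulate_state(cfg)
        stream = synthetic.synthesize_segments(traj, cfg)
        k_seg = np.interp(stream.timestamps / 3600.0, traj.t_h, traj.k)
        a_cfg, _ = synthetic._ar_coefficients(cfg, k_seg)
        a = float(np.median(a_cfg))
        acfs = [ft.autocorrelation_function(stream.data[0, i], 10)
                for i in range(stream.n_segments)]
        mean_acf = np.mean(acfs, axis=0)
        np.testing.assert_allclose(mean_acf, a ** np.arange(11), atol=0.05)

    def test_variance_and_acfw_monotone_in_tau(self, rng):
        cfg = synthetic.SimulatorConfig(n_channels=1, measurement_noise_sd=0.0)
        var_means, acfw_means = [], []
        for lag in (2.0, 4.0, 8.0, 16.0):
            a = np.exp(-1.0 / lag)
            n_seg = 300
            e = rng.standard_normal((n_seg, 400))
            x = np.empty((n_seg, 400))
            x[:, 0] = e[:, 0] / np.sqrt(1 - a ** 2)
            for s in range(1, 400):
                x[:, s] = a * x[:, s - 1] + e[:, s]
            stream = SegmentStream(np.arange(n_seg) * 120.0, x[None],
                                   np.zeros(n_seg, bool))
            feats = ft.compute_features(stream)
            var_means.append(np.nanmean(feats.variance))
            acfw_means.append(np.nanmean(feats.acfw))
        assert all(b > a for a, b in zip(var_means, var_means[1:]))
        assert all(b > a for a, b in zip(acfw_means, acfw_means[1:]))


class TestInjectSpikes:
    def _quiet_stream(self, cfg):
        traj = synthetic.simulate_state(cfg)
        return traj, synthetic.synthesize_segments(traj, cfg)

    def test_zero_rate_identity(self):
        cfg = synthetic.SimulatorConfig(duration_days=0.2, n_channels=1,
                                        spike_rate_base=0.0, seed=0)
        _, stream = self._quiet_stream(cfg)
        out, truth = synthetic.inject_spikes(stream, cfg)
        np.testing.assert_array_equal(out.data, stream.data)
        assert all(t.size == 0 for t in truth)

    def test_poisson_thinning_expectation(self):
        cfg = synthetic.SimulatorConfig(duration_days=10.0, n_channels=1,
                                        noise_sd=0.0, spike_rate_base=10.0,
                                        seed=1)
        traj = synthetic.simulate_state(cfg)
        stream = synthetic.synthesize_segments(traj, cfg)
        _, truth = synthetic.inject_spikes(stream, cfg,
                                           channel_factors=np.ones(1))
        # 10/h * 240 h * (1 s / 120 s duty)
        expected = 10.0 * 240.0 / 120.0
        assert abs(truth[0].size - expected) <= 3 * np.sqrt(expected)

    def test_modulated_rate_raises_si(self):
        cfg = synthetic.SimulatorConfig(duration_days=10.0, n_channels=1,
                                        noise_sd=0.0, spike_rate_base=120.0,
                                        spike_rate_mod=0.95,
                                        multidien_period_h=48.0, seed=2)
        traj = synthetic.simulate_state(cfg)
        stream = synthetic.synthesize_segments(traj, cfg)
        phase = synthetic.drive_phase(stream.timestamps / 3600.0, 48.0)
        _, truth_mod = synthetic.inject_spikes(stream, cfg,
                                               modulation_phase=phase)
        cfg0 = synthetic.SimulatorConfig(**{**cfg.__dict__, "spike_rate_mod": 0.0})
        _, truth_flat = synthetic.inject_spikes(stream, cfg0,
                                                modulation_phase=phase)
        si_mod, _ = synchrony.synchronization_index(
            synthetic.drive_phase(truth_mod[0] / 3600.0, 48.0))
        si_flat, _ = synchrony.synchronization_index(
            synthetic.drive_phase(truth_flat[0] / 3600.0, 48.0))
        assert si_mod > si_flat

    def test_truth_only_in_unmasked_segments(self):
        cfg = synthetic.SimulatorConfig(duration_days=1.0, n_channels=1,
                                        spike_rate_base=240.0, seed=3)
        traj = synthetic.simulate_state(cfg)
        stream = synthetic.synthesize_segments(traj, cfg)
        stream = synthetic.inject_dropouts(stream, [(3600.0, 7200.0)])
        _, truth = synthetic.inject_spikes(stream, cfg)
        assert truth[0].size > 0
        assert not np.any((truth[0] >= 3600.0) & (truth[0] < 3600.0 + 7200.0))

    def test_template_too_long(self):
        cfg = synthetic.SimulatorConfig(duration_days=0.1, n_channels=1,
                                        spike_rate_base=10.0,
                                        spike_template=np.ones(500), seed=0)
        with pytest.raises(synthetic.ConfigError):
            cfg.validate()


class TestInjectDropouts:
    def _stream(self, days=30.0):
        n_seg = int(days * 720)
        return SegmentStream(np.arange(n_seg) * 120.0,
                             np.zeros((1, n_seg, 4)), np.zeros(n_seg, bool))

    def test_empty_spec(self):
        out = synthetic.inject_dropouts(self._stream(1.0), None)
        assert not out.mask.any()
        out = synthetic.inject_dropouts(self._stream(1.0), [])
        assert not out.mask.any()

    def test_three_day_gap_fraction(self):
        out = synthetic.inject_dropouts(self._stream(30.0),
                                        [(0.0, 3 * 86400.0)])
        assert out.missing_fraction == pytest.approx(0.1, abs=1e-3)

    def test_overlapping_gaps_merged(self):
        out = synthetic.inject_dropouts(self._stream(1.0),
                                        [(0.0, 3600.0), (1800.0, 3600.0)])
        assert out.missing_fraction == pytest.approx(5400.0 / 86400.0, abs=1e-3)

    def test_random_model_hits_target(self):
        fracs = []
        for seed in range(10):
            out = synthetic.inject_dropouts(self._stream(30.0),
                                            {"target_fraction": 0.26},
                                            seed=seed)
            fracs.append(out.missing_fraction)
        assert all(abs(f - 0.26) <= 0.03 for f in fracs)

    def test_masked_data_nan(self):
        out = synthetic.inject_dropouts(self._stream(1.0), [(0.0, 3600.0)])
        assert np.isnan(out.data[:, out.mask, :]).all()


class TestRecordingOrchestration:
    def test_bit_reproducibility(self):
        cfg = synthetic.SimulatorConfig(duration_days=5.0, n_channels=2,
                                        k_multidien_amp=50.0, spike_rate_base=60.0,
                                        dropout_spec={"target_fraction": 0.1},
                                        seed=21)
        r1 = synthetic.simulate_recording(cfg, render="features")
        r2 = synthetic.simulate_recording(cfg, render="features")
        np.testing.assert_array_equal(r1.features.acfw, r2.features.acfw)
        np.testing.assert_array_equal(r1.features.spike_rate, r2.features.spike_rate)
        np.testing.assert_array_equal(r1.seizure_catalog.onsets_s,
                                      r2.seizure_catalog.onsets_s)
        np.testing.assert_array_equal(r1.true_drive, r2.true_drive)

    def test_catalog_invariants(self):
        cfg = synthetic.SimulatorConfig(duration_days=10.0, n_channels=1,
                                        noise_sd=0.4, k_baseline=110.0, seed=5)
        rec = synthetic.simulate_recording(cfg, render="features")
        onsets = rec.seizure_catalog.onsets_s
        if onsets.size > 1:
            assert np.all(np.diff(onsets) > 0)
        assert np.all(onsets >= 0)
        assert np.all(onsets <= cfg.duration_h * 3600.0)


class TestPhaseLockedCatalog:
    def test_si_near_target(self):
        cfg = synthetic.SimulatorConfig(duration_days=90.0, seed=0)
        kappa = synthetic.kappa_for_si(0.9)
        catalog = synthetic.phase_locked_catalog(cfg, 200, kappa_multidien=kappa)
        phases = synthetic.drive_phase(catalog.onsets_s / 3600.0,
                                       cfg.multidien_period_h)
        si, _ = synchrony.synchronization_index(phases)
        assert si == pytest.approx(0.9, abs=0.06)

    def test_min_separation(self):
        cfg = synthetic.SimulatorConfig(duration_days=60.0, seed=1)
        catalog = synthetic.phase_locked_catalog(cfg, 50, kappa_multidien=2.0,
                                                 min_separation_s=3600.0)
        assert np.all(np.diff(catalog.onsets_s) >= 3600.0)

    def test_kappa_for_si_roundtrip(self):
        from scipy.special import i0, i1
        for target in (0.3, 0.6, 0.9, 0.95):
            kp = synthetic.kappa_for_si(target)
            assert i1(kp) / i0(kp) == pytest.approx(target, abs=1e-6)
        assert synthetic.kappa_for_si(0.0) == 0.0
        with pytest.raises(ValueError):
            synthetic.kappa_for_si(1.0)


class TestSeizureClusterAtDrivePhase:
    def test_fold_crossings_lock_to_drive(self):
        # strong multidien modulation sweeping k toward (but not past) the
        # fold: noise-driven escapes concentrate near the drive maximum
        cfg = synthetic.SimulatorConfig(duration_days=40.0, n_channels=1,
                                        noise_sd=0.12, k_baseline=20.0,
                                        k_multidien_amp=100.0,
                                        multidien_period_h=96.0, seed=8)
        traj = synthetic.simulate_state(cfg)
        catalog = synthetic.label_seizures(traj, cfg)
        assert len(catalog) >= 5
        phases = synthetic.drive_phase(catalog.onsets_s / 3600.0, 96.0)
        si, _ = synchrony.synchronization_index(phases)
        assert si > 0.8
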