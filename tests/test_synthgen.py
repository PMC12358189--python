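"""Generator tests: templates, evoked samplers, DC thinning, rendering and
session structure."""

import itertools

import numpy as np
import pytest

from dcblock import synthgen as sg


class TestTemplates:
    def test_deterministic_under_seed(self):
        geom = sg.poly2_geometry(3)
        a = sg.make_templates(2, geom, seed=7)
        b = sg.make_templates(2, geom, seed=7)
        assert a.shape == (2, 3, 48)
        np.testing.assert_array_equal(a, b)

    def test_peak_amplitude_is_snr_times_noise(self):
        tpl = sg.make_templates(5, sg.poly2_geometry(3), seed=0, snr=8, noise_sd_uV=5)
        peaks = np.abs(tpl).max(axis=(1, 2))
        np.testing.assert_allclose(peaks, 40.0, rtol=1e-9)

    def test_flank_attenuation_and_distinctness(self):
        tpl = sg.make_templates(6, sg.poly2_geometry(3), seed=3)
        for t in tpl:
            ch_peaks = np.abs(t).min(axis=1) * 0 + np.abs(t).max(axis=1)
            dom = np.argmax(ch_peaks)
            flanks = np.delete(ch_peaks, dom)
            assert np.all(flanks <= 0.6 * ch_peaks[dom] + 1e-9)
        for a, b in itertools.combinations(tpl, 2):
            c = abs(np.dot(a.ravel(), b.ravel())) / (
                np.linalg.norm(a) * np.linalg.norm(b))
            assert c < 0.95

    def test_too_few_channels_rejected(self):
        with pytest.raises(sg.ConfigurationError):
            sg.make_templates(1, sg.poly2_geometry(2), seed=0)


class TestEvokedSampler:
    def test_tactile_naive_mean_latency(self):
        # 1000 trials reproduce the configured 8.31 ms mean within 1 ms
        par = sg.default_paradigm("tactile", 1000)
        prof = sg.default_profile("tactile", "naive")
        trials = sg.sample_evoked_times(par, prof, seed=1)
        lat = np.concatenate(trials) * 1000.0
        assert abs(lat.mean() - 8.31) < 1.0

    def test_zero_rate_profile_is_empty(self):
        par = sg.default_paradigm("noxious_thermal", 5)
        prof = sg.EvokedProfile(0.0, 1150.0, 150.0, (800.0, 1500.0))
        trials = sg.sample_evoked_times(par, prof, seed=0)
        assert all(t.size == 0 for t in trials)

    def test_proprioceptive_bimodal_histogram_peaks(self):
        # brute-force histogram of the sampler's own draws
        par = sg.default_paradigm("proprioceptive", 500)
        prof = sg.EvokedProfile(6.0, 50.0, 10.0, (0.0, 400.0), 250.0, 10.0, 0.5)
        lat = np.concatenate(sg.sample_evoked_times(par, prof, seed=2)) * 1000.0
        counts, edges = np.histogram(lat, bins=np.arange(0, 401, 10))
        centres = edges[:-1] + 5
        early = centres < 150
        peak_early = centres[early][np.argmax(counts[early])]
        peak_late = centres[~early][np.argmax(counts[~early])]
        assert abs(peak_early - 50) <= 10
        assert abs(peak_late - 250) <= 10

    def test_pain_profiles_match_reported_mean_latencies(self):
        assert abs(sg.default_profile("tactile", "neuropathic").mean_latency_ms
                   - 10.85) < 1e-9
        assert abs(sg.default_profile("tactile", "inflammatory").mean_latency_ms
                   - 10.41) < 1e-9


class TestApplyDC:
    def _setup(self, n=10000, window=(0.0, 40.0)):
        rng = np.random.default_rng(3)
        triggers = np.arange(1, 11, dtype=float) * 10.0
        times = np.sort(np.concatenate(
            [trig + rng.uniform(window[0], window[1]) / 1000.0 * np.ones(1)
             for trig in np.repeat(triggers, n // 10)
             ]))
        # n spikes uniformly inside the window across 10 triggers
        times = np.sort(np.repeat(triggers, n // 10)
                        + rng.uniform(*window, size=n) / 1000.0)
        return times, triggers, {"main": window}

    def test_r_zero_is_identity(self):
        times, trig, win = self._setup(1000)
        sched = sg.DCSchedule("during", 500.0, "cathodic_centre")
        out = sg.apply_dc_effect(times, trig, win, {"main": 0.0}, sched, seed=0)
        np.testing.assert_array_equal(out, times)

    def test_r_one_blocks_all_windowed(self):
        times, trig, win = self._setup(10000)
        sched = sg.DCSchedule("during", 1000.0, "anodic_centre")
        out = sg.apply_dc_effect(times, trig, win, {"main": 1.0}, sched, seed=0)
        assert out.size == 0

    def test_binomial_thinning_at_half(self):
        times, trig, win = self._setup(10000)
        sched = sg.DCSchedule("during", 1000.0, "anodic_centre")
        out = sg.apply_dc_effect(times, trig, win, {"main": 0.5}, sched, seed=3)
        sd = np.sqrt(10000 * 0.25)
        assert abs(out.size - 5000) < 3 * sd

    @pytest.mark.parametrize("r", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_thinning_conservation(self, r):
        # mean windowed count within 3 binomial SDs of (1-r) x pre mean
        times, trig, win = self._setup(10000)
        sched = sg.DCSchedule("during", 500.0, "cathodic_centre")
        out = sg.apply_dc_effect(times, trig, win, {"main": r}, sched, seed=11)
        expect = 10000 * (1 - r)
        sd = np.sqrt(10000 * r * (1 - r))
        assert abs(out.size - expect) <= 3 * sd + 1e-9

    def test_invalid_r_rejected(self):
        times, trig, win = self._setup(100)
        sched = sg.DCSchedule("during", 500.0, "cathodic_centre")
        with pytest.raises(sg.ConfigurationError):
            sg.apply_dc_effect(times, trig, win, {"main": 1.5}, sched, seed=0)

    def test_post_release_restores_activity(self):
        times, trig, win = self._setup(2000)
        sched = sg.DCSchedule("post", time_since_dc_end_s=600.0)
        blocked = sg.apply_dc_effect(times, trig, win, {"main": 1.0}, sched,
                                     seed=0, tau_release_s=1200.0)
        released = sg.apply_dc_effect(times, trig, win, {"main": 1.0}, sched,
                                      seed=0, tau_release_s=300.0)
        assert blocked.size == 0
        np.testing.assert_array_equal(released, times)


class TestRenderVoltage:
    def _session(self, n_units=1, seed=0, noise=5.0, n_stimuli=5):
        cfg = sg.GeneratorConfig(modality="tactile", n_units_per_modality=n_units,
                                 shared_footprint=True, n_pre_sets=1, n_post_sets=0,
                                 n_stimuli=n_stimuli, noise_sd_uV=noise, seed=seed)
        return sg.generate_session(cfg)

    def test_noise_sd_within_two_percent(self):
        sess = self._session(1, noise=5.0, n_stimuli=11)
        s = sess.sets[0]
        s.unit_times = {0: np.empty(0)}   # zero units: pure noise
        tpl = sg.make_templates(1, sg.poly2_geometry(3), seed=0)
        v, _ = sg.render_voltage(s, sess.truth, tpl, n_channels=3,
                                 noise_sd_uV=5.0, seed=1)
        assert v.size > 1e6
        assert abs(v.std() - 5.0) / 5.0 < 0.02

    def test_noiseless_single_spike_equals_template(self):
        sess = self._session(1)
        s = sess.sets[0]
        s.unit_times = {0: np.array([0.5])}
        tpl = sg.make_templates(1, sg.poly2_geometry(3), seed=4)
        v, _ = sg.render_voltage(s, sess.truth, tpl, n_channels=3,
                                 noise_sd_uV=0.0, seed=0)
        c = int(round(0.5 * 30000))
        np.testing.assert_allclose(
            v[:, c - sg.TEMPLATE_PRE:c + sg.TEMPLATE_POST], tpl[0])
        v[:, c - sg.TEMPLATE_PRE:c + sg.TEMPLATE_POST] = 0.0
        assert np.all(v == 0)

    def test_rendering_is_linear_and_reproducible(self):
        sess = self._session(2)
        s = sess.sets[0]
        tpl = sg.make_templates(2, sg.poly2_geometry(3), seed=4)
        v1, _ = sg.render_voltage(s, sess.truth, tpl, noise_sd_uV=0.0, seed=0)
        v2, _ = sg.render_voltage(s, sess.truth, tpl, noise_sd_uV=0.0, seed=0)
        np.testing.assert_array_equal(v1, v2)
        # sum of separately rendered unit sets equals the merged rendering
        import copy
        sa, sb = copy.copy(s), copy.copy(s)
        sa.unit_times = {0: s.unit_times[0], 1: np.empty(0)}
        sb.unit_times = {0: np.empty(0), 1: s.unit_times[1]}
        va, _ = sg.render_voltage(sa, sess.truth, tpl, noise_sd_uV=0.0, seed=0)
        vb, _ = sg.render_voltage(sb, sess.truth, tpl, noise_sd_uV=0.0, seed=0)
        np.testing.assert_allclose(v1, va + vb, atol=1e-9)


class TestSession:
    def test_during_sets_cover_all_permutations_once(self):
        sess = sg.generate_session(sg.GeneratorConfig(seed=5))
        during = [(s.schedule.amplitude_uA, s.schedule.polarity)
                  for s in sess.sets_by_phase("during")]
        assert sorted(during) == sorted(
            (a, p) for a in (500.0, 1000.0)
            for p in ("cathodic_centre", "anodic_centre"))

    def test_post_schedule_arithmetic(self):
        cfg = sg.GeneratorConfig(n_post_sets=9, post_interval_min=5.0, seed=0)
        sess = sg.generate_session(cfg)
        times = [s.schedule.time_since_dc_end_s for s in sess.sets_by_phase("post")]
        assert times == sorted(times) and len(times) == 9
        assert times[0] == 300.0 and times[-1] == 45 * 60.0

    def test_same_seed_identical_sessions(self):
        a = sg.generate_session(sg.GeneratorConfig(seed=9))
        b = sg.generate_session(sg.GeneratorConfig(seed=9))
        for sa, sb in zip(a.sets, b.sets):
            assert sa.set_id == sb.set_id
            for u in sa.unit_times:
                np.testing.assert_array_equal(sa.unit_times[u], sb.unit_times[u])

    def test_ground_truth_reduction_relation_exact(self):
        cfg = sg.GeneratorConfig(modality="noxious_thermal",
                                 treatment_group="neuropathic", seed=2)
        sess = sg.generate_session(cfg)
        for u in sess.truth.units.values():
            for name, exp in u.expected_window_counts.items():
                for amp in (500.0, 1000.0):
                    r = sess.truth.reductions[name][amp]
                    assert exp[amp] == pytest.approx((1 - r) * exp["pre"])

    def test_refractory_dead_time_enforced(self):
        sess = sg.generate_session(sg.GeneratorConfig(
            modality="tactile", seed=3, n_stimuli=30))
        for s in sess.sets:
            for t in s.unit_times.values():
                if t.size > 1:
                    assert np.diff(t).min() >= sg.REFRACTORY_S - 1e-12

    def test_invalid_configs_rejected(self):
        with pytest.raises(sg.ConfigurationError):
            sg.GeneratorConfig(snr=0.0)
        with pytest.raises(sg.ConfigurationError):
            sg.GeneratorConfig(dc_spontaneous_gain=0.9)
        with pytest.raises(sg.ConfigurationError):
            sg.DCSchedule("pre", amplitude_uA=500.0)
        with pytest.raises(sg.ConfigurationError):
            sg.StimulusParadigm("tactile", 10, 0.1, 0.2)


def test_hdf5_roundtrip(tmp_path):
    cfg = sg.GeneratorConfig(n_units_per_modality=2, shared_footprint=True,
                             n_pre_sets=1, n_post_sets=0, n_stimuli=5, seed=0)
    sess = sg.generate_session(cfg)
    s = sess.sets[0]
    tpl = sg.make_templates(2, sg.poly2_geometry(3), seed=0)
    v, trig = sg.render_voltage(s, sess.truth, tpl, n_channels=3, seed=0)
    path = tmp_path / "set.h5"
    sg.save_set_hdf5(path, v, trig, s, sg.poly2_geometry(3))
    v2, trig2, fs, geom, meta = sg.load_set_hdf5(path)
    assert fs == 30000.0
    np.testing.assert_array_equal(trig, trig2)
    assert np.abs(v - v2).max() <= 0.05  # int16 quantisation at the stored scale
    assert meta["phase"] == "pre" and meta["paradigm"]["modality"] == "tactile"
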