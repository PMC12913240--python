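"""Synthetic EEG: component logic, additivity, noise spectrum, topography."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import welch

from pairlg.paradigm import ParadigmConfig, generate_session
from pairlg.simulate import (ComponentSpec, NoiseSpec, build_default_components,
                             component_topography, simulate_cohort,
                             simulate_recording)

QUIET = NoiseSpec(broadband_sd_uv=0.0, alpha_amplitude_uv=0.0,
                  spatial_smoothing=0.0)


def _single_pair_schedule(seed=0):
    cfg = ParadigmConfig(n_total_pairs=1, n_regularity_pairs=0, n_ss=1, n_sf=0,
                         n_st=0, n_st_context_ss=0, n_st_context_sf=0, seed=seed)
    return generate_session(cfg)


class TestDefaultComponents:
    def test_passive_has_no_p3b(self):
        names = [c.name for c in build_default_components("passive")]
        assert names == ["P1", "N1", "P2", "MMN", "P3a"]

    def test_conditions_differ_only_in_p3b(self):
        active = build_default_components("active")
        passive = build_default_components("passive")
        assert [c for c in active if not c.active_only] == passive
        assert [c.name for c in active if c.active_only] == ["P3b"]

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            build_default_components("resting")

    def test_zero_amplitudes_reduce_to_pure_noise(self, montage):
        sched = _single_pair_schedule()
        comps = [replace(c, amplitude_uv=0.0)
                 for c in build_default_components("passive")]
        with_zero = simulate_recording(sched, comps, NoiseSpec(), montage, seed=4)
        noise_only = simulate_recording(sched, [], NoiseSpec(), montage, seed=4)
        assert np.array_equal(with_zero.data, noise_only.data)


class TestAdditivity:
    def test_component_sum_is_additive_under_shared_seed(self, montage):
        sched = _single_pair_schedule()
        comps = build_default_components("passive")
        a, b = comps[:2], comps[2:]
        both = simulate_recording(sched, a + b, NoiseSpec(), montage, seed=9)
        only_a = simulate_recording(sched, a, NoiseSpec(), montage, seed=9)
        only_b = simulate_recording(sched, b, NoiseSpec(), montage, seed=9)
        noise = simulate_recording(sched, [], NoiseSpec(), montage, seed=9)
        np.testing.assert_allclose(
            both.data, only_a.data + only_b.data - noise.data, atol=1e-10)

    def test_noise_free_waveform_is_template_sum(self, montage):
        # Single standard pair, zero jitter: the trace at any channel must be
        # exactly the sum of the P1/N1/P2 Gaussians scaled by the channel's
        # CPz-referenced gain.
        sched = _single_pair_schedule()
        comps = [replace(c, latency_jitter_sd_ms=0.0)
                 for c in build_default_components("passive")]
        rec = simulate_recording(sched, comps, QUIET, montage, seed=0)
        t_ms = np.arange(rec.n_samples)
        cpz = montage.index("CPz")
        for ch in ("Fz", "Cz"):
            expected = np.zeros(rec.n_samples)
            for comp, onset in ((c, ev.onset_ms) for c in comps
                                for ev in sched.events
                                if c.applies(ev, "passive")):
                g = component_topography(comp.topography, montage)
                gain = g[montage.index(ch)] - g[cpz]
                sigma = comp.half_width_ms / (2 * np.sqrt(2 * np.log(2)))
                expected += gain * comp.amplitude_uv * np.exp(
                    -((t_ms - onset - comp.peak_latency_ms) ** 2) / (2 * sigma**2))
            # kernel support is truncated at 4 sigma, hence the loose atol
            np.testing.assert_allclose(rec.data[montage.index(ch)], expected,
                                       atol=3e-3)

    def test_event_past_allocated_duration_raises(self, montage):
        sched = _single_pair_schedule()
        with pytest.raises(ValueError):
            simulate_recording(sched, post_ms=10, montage=montage, seed=0)


class TestNoise:
    def test_spectral_slope_matches_configured_exponent(self, montage):
        sched = _single_pair_schedule()
        spec = NoiseSpec(one_over_f_exponent=1.0, broadband_sd_uv=5.0,
                         alpha_amplitude_uv=0.0, spatial_smoothing=0.0)
        rec = simulate_recording(sched, [], spec, montage, seed=0, post_ms=60000)
        f, pxx = welch(rec.data[0], fs=rec.srate, nperseg=4096)
        band = (f >= 2) & (f <= 80)
        slope = np.polyfit(np.log(f[band]), np.log(pxx[band]), 1)[0]
        assert abs(-slope - spec.one_over_f_exponent) < 0.3

    def test_evoked_average_vanishes_without_components(self, montage):
        # Law of large numbers: with no components the event-locked average
        # shrinks like sd/sqrt(n).
        cfg = ParadigmConfig(n_total_pairs=60, n_regularity_pairs=0, n_ss=60,
                             n_sf=0, n_st=0, n_st_context_ss=0,
                             n_st_context_sf=0, seed=1)
        sched = generate_session(cfg)
        spec = NoiseSpec(broadband_sd_uv=5.0, alpha_amplitude_uv=0.0)
        rec = simulate_recording(sched, [], spec, montage, seed=2)
        samples = [rec.event_sample(ev) for ev in sched.events[::2]]
        epochs = np.stack([rec.data[0, s:s + 300] for s in samples])
        assert np.abs(epochs.mean(axis=0)).max() < 5 * 5.0 / np.sqrt(60)

    def test_artifact_rate_injects_rejectable_excursions(self, montage):
        cfg = ParadigmConfig(n_total_pairs=20, n_regularity_pairs=0, n_ss=20,
                             n_sf=0, n_st=0, n_st_context_ss=0,
                             n_st_context_sf=0, seed=0)
        sched = generate_session(cfg)
        spec = NoiseSpec(broadband_sd_uv=1.0, alpha_amplitude_uv=0.0,
                         artifact_rate=0.5)
        rec = simulate_recording(sched, [], spec, montage, seed=3)
        assert (np.abs(rec.data) > 100).any()


class TestTopography:
    def test_channel_profile_matches_gain_map(self, montage):
        # Noise-free MMN-only simulation, mastoid re-referenced: the peak
        # deflection across channels must reproduce the configured gains.
        cfg = ParadigmConfig(n_total_pairs=1, n_regularity_pairs=0, n_ss=0,
                             n_sf=1, n_st=0, n_st_context_ss=0,
                             n_st_context_sf=0)
        sched = generate_session(cfg)
        mmn = ComponentSpec("MMN", 148, 44, -3.5, "frontocentral",
                            "deviant_second", latency_jitter_sd_ms=0.0)
        rec = simulate_recording(sched, [mmn], QUIET, montage, seed=0)
        ref = rec.data[montage.indices(("M1", "M2"))].mean(axis=0)
        data = rec.data - ref
        peak = int(round(sched.events[1].onset_ms + 148))
        profile = data[:, peak] / mmn.amplitude_uv
        np.testing.assert_allclose(profile,
                                   component_topography("frontocentral", montage),
                                   atol=1e-6)

    def test_gains_in_unit_interval_and_reference_free(self, montage):
        for kind in ("frontocentral", "centroparietal"):
            g = component_topography(kind, montage)
            assert g.min() >= 0 and g.max() == pytest.approx(1.0)
            assert g[montage.index("M1")] == 0 and g[montage.index("M2")] == 0


class TestCohort:
    def test_cohort_is_paired_and_deterministic(self, montage):
        cfg = ParadigmConfig(n_total_pairs=10, n_regularity_pairs=1, n_ss=4,
                             n_sf=3, n_st=2, n_st_context_ss=1,
                             n_st_context_sf=1)
        a = simulate_cohort(2, cfg, seed=5, montage=montage)
        b = simulate_cohort(2, cfg, seed=5, montage=montage)
        assert len(a) == 2
        for (act, pas), (act2, _) in zip(a, b):
            assert act.events.condition == "active"
            assert pas.events.condition == "passive"
            # identical auditory stimulation across conditions
            assert [e.stimulus_code for e in act.events.events] == \
                   [e.stimulus_code for e in pas.events.events]
            np.testing.assert_array_equal(act.data, act2.data)

    def test_zero_between_subject_sd_gives_identical_evokeds(self, montage):
        cfg = ParadigmConfig(n_total_pairs=2, n_regularity_pairs=0, n_ss=2,
                             n_sf=0, n_st=0, n_st_context_ss=0,
                             n_st_context_sf=0)
        comps = [replace(c, latency_jitter_sd_ms=0.0)
                 for c in build_default_components("active")]
        cohort = simulate_cohort(2, cfg, components=comps, noise=QUIET,
                                 between_subject_sd=0.0, seed=1, montage=montage)
        (a1, _), (a2, _) = cohort
        # schedules differ in jitter across participants, but the noise-free
        # response to the first pair (locked at 0 ms in both) must match
        np.testing.assert_allclose(a1.data[:, :550], a2.data[:, :550], atol=1e-10)
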