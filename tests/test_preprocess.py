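"""Filter chain, epoch extraction geometry, matched artifact rejection."""

from dataclasses import replace

import numpy as np
import pytest

from pairlg.montage import Montage
from pairlg.paradigm import ParadigmConfig, generate_session
from pairlg.preprocess import (CONTRASTS, ContrastError, EpochSet,
                               extract_epochs, filter_chain, load_epochs,
                               reject_amplitude, save_epochs)
from pairlg.simulate import RawRecording


def _flat_recording(montage, schedule, srate=250.0, value=0.0):
    n = int(schedule.duration_ms() / 1000 * srate) + int(srate)
    data = np.full((len(montage.labels), n), value)
    return RawRecording(data=data, srate=srate, montage=montage, events=schedule)


class TestFilterChain:
    def _raw(self, montage, data):
        sched = generate_session(ParadigmConfig(
            n_total_pairs=1, n_regularity_pairs=0, n_ss=1, n_sf=0, n_st=0,
            n_st_context_ss=0, n_st_context_sf=0))
        return RawRecording(data=data, srate=1000.0, montage=montage, events=sched)

    def test_notch_attenuates_mains_by_40_db(self, montage):
        t = np.arange(10000) / 1000.0
        data = np.tile(np.sin(2 * np.pi * 50 * t), (64, 1)) * 10
        out = filter_chain(self._raw(montage, data))
        mid = out.data[0, 200:-200]          # ignore filter edges
        assert np.abs(mid).max() < 10 * 10 ** (-40 / 20)

    def test_high_pass_removes_dc(self, montage):
        data = np.full((64, 8000), 25.0)
        out = filter_chain(self._raw(montage, data))
        assert abs(out.data[0, 200:-200].mean()) < 0.1

    def test_downsample_rate_and_length(self, montage):
        n = 10001
        data = np.zeros((64, n))
        out = filter_chain(self._raw(montage, data))
        assert out.srate == 250.0
        assert out.n_samples == int(np.ceil(n / 4))

    def test_missing_mastoids_rejected(self):
        bad = Montage(labels=("Fz", "Pz", "CPz"), positions=np.eye(3),
                      adjacency=np.zeros((3, 3), dtype=bool))
        sched = generate_session(ParadigmConfig(
            n_total_pairs=1, n_regularity_pairs=0, n_ss=1, n_sf=0, n_st=0,
            n_st_context_ss=0, n_st_context_sf=0))
        raw = RawRecording(data=np.zeros((3, 2000)), srate=1000.0,
                           montage=bad, events=sched)
        with pytest.raises(ValueError, match="reference"):
            filter_chain(raw)


class TestEpochGeometry:
    def test_trial_counts_match_schedule_composition(self, montage, mini_config):
        sched = generate_session(mini_config)
        raw = _flat_recording(montage, sched)
        counts = {}
        for name in CONTRASTS:
            A, B = extract_epochs(raw, name)
            assert A.n_trials == B.n_trials
            counts[name] = A.n_trials
        assert counts["P1N1P2"] == mini_config.n_analyzed
        assert counts["Local_SF"] == mini_config.n_sf
        assert counts["Local_ST"] == mini_config.n_st
        assert counts["Global_SS_ST1"] == mini_config.n_st_context_ss
        assert counts["Global_SF_ST2"] == mini_config.n_st_context_sf

    def test_sample_counts_at_250_hz(self, montage, mini_config):
        sched = generate_session(mini_config)
        raw = _flat_recording(montage, sched)
        A, _ = extract_epochs(raw, "Local_SF")
        assert A.data.shape[2] == 113          # 450-ms epoch
        G, _ = extract_epochs(raw, "Global_SS_ST1")
        assert G.data.shape[2] == 225          # 900-ms epoch
        assert A.times[0] == -100 and A.times[-1] == 348

    def test_baseline_means_are_zero(self, mini_filtered):
        for name in CONTRASTS:
            A, B = extract_epochs(mini_filtered, name)
            for es in (A, B):
                mask = (es.times >= es.baseline_window[0]) & \
                       (es.times < es.baseline_window[1])
                means = es.data[:, :, mask].mean(axis=2)
                assert np.abs(means).max() < 1e-9 * max(1, np.abs(es.data).max())

    def test_resting_state_epochs_precede_stimulus(self, montage, mini_config):
        # Place a spike 200 ms before one S onset: it lies inside that
        # trial's resting-state interval (-450..0 ms) but outside its
        # stimulus epoch (-100..350 ms), and must surface in the RS epoch
        # at virtual time -200 + 350 = 150 ms.
        sched = generate_session(mini_config)
        raw = _flat_recording(montage, sched)
        first_analyzed = 2 * mini_config.n_regularity_pairs
        lock = raw.event_sample(sched.events[first_analyzed])
        raw.data[:, lock - 50] = 40.0          # -200 ms at 250 Hz
        A, B = extract_epochs(raw, "P1N1P2")
        peak = int(np.argmax(B.data[0, 0]))
        assert B.data[0, 0, peak] > 30          # spike visible in RS epoch
        assert abs(B.times[peak] - 150) <= 4    # at virtual ~150 ms
        assert np.abs(A.data[0, 0]).max() < 10  # absent from stimulus epoch
        assert A.times.shape == B.times.shape

    def test_global_contrast_empty_without_train_deviants(self, montage):
        cfg = ParadigmConfig(n_total_pairs=10, n_regularity_pairs=2, n_ss=5,
                             n_sf=3, n_st=0, n_st_context_ss=0,
                             n_st_context_sf=0)
        raw = _flat_recording(montage, generate_session(cfg))
        with pytest.raises(ContrastError):
            extract_epochs(raw, "Global_SS_ST1")


class TestRejection:
    def _epochs(self, n_trials, n_ch=4, n_t=10, value=0.0):
        data = np.full((n_trials, n_ch, n_t), value)
        return EpochSet(data=data, times=np.arange(n_t) * 4.0,
                        baseline_window=(0, 8), labels=np.array(["x"] * n_trials),
                        participant_id="p", contrast_name="c",
                        channels=("Fz", "Pz", "M1", "M2"))

    def test_clean_data_passes_unchanged(self):
        A, B = self._epochs(5), self._epochs(5)
        A2, B2 = reject_amplitude(A, B)
        assert A2.n_trials == B2.n_trials == 5

    def test_matched_rejection_drops_both_members(self):
        A, B = self._epochs(5), self._epochs(5)
        A.data[2, 0, 3] = 150.0
        A2, B2 = reject_amplitude(A, B, matched=True)
        assert A2.n_trials == B2.n_trials == 4

    def test_reference_channels_do_not_trigger_rejection(self):
        A, B = self._epochs(5), self._epochs(5)
        A.data[2, 2, 3] = 500.0                # M1 excursion
        A2, _ = reject_amplitude(A, B)
        assert A2.n_trials == 5

    def test_matched_counts_under_random_artifacts(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A, B = self._epochs(30), self._epochs(30)
            for es in (A, B):
                k = rng.integers(0, 6)
                idx = rng.choice(30, size=k, replace=False)
                es.data[idx, 0, 0] = 200.0
            A2, B2 = reject_amplitude(A, B, matched=True)
            assert A2.n_trials == B2.n_trials > 0

    def test_zero_threshold_rejects_everything(self):
        A, B = self._epochs(5, value=1.0), self._epochs(5, value=1.0)
        with pytest.raises(ValueError, match="all trials"):
            reject_amplitude(A, B, threshold_uv=0.0)


def test_epochs_roundtrip_via_npz(tmp_path):
    rng = np.random.default_rng(1)
    es = EpochSet(data=rng.normal(size=(3, 2, 5)), times=np.arange(5) * 4.0,
                  baseline_window=(0, 8), labels=np.array(["a", "a", "b"]),
                  participant_id="sub-01", contrast_name="Local_SF",
                  channels=("Fz", "Pz"))
    save_epochs(es, tmp_path / "ep")
    back = load_epochs(tmp_path / "ep")
    np.testing.assert_array_equal(es.data, back.data)
    assert back.contrast_name == "Local_SF"
    assert tuple(back.channels) == ("Fz", "Pz")
    assert list(back.labels) == ["a", "a", "b"]
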