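import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from oddball_erp import (
    DesignSpec,
    PreprocessConfig,
    Recording,
    apply_timing_offset,
    bandpass_filter,
    epoch,
    equalize_trials,
    generate_sequence,
    inclusion_filter,
    preprocess_recording,
    reject_artifacts,
    synthesize_recording,
)
from oddball_erp.preprocess import design_fir

from conftest import make_epochs, make_noise_free_subject

FS = 500.0


def _recording(samples, events=None):
    if events is None:
        events = pd.DataFrame({"onset_sample": [], "condition": [],
                               "stimulus_id": [], "ordinal": []})
    return Recording(samples=samples, sample_rate_hz=FS, events=events)


def _sine_recording(freq_hz, duration_s=60.0, amp=10.0):
    t = np.arange(int(duration_s * FS)) / FS
    sig = amp * np.sin(2 * np.pi * freq_hz * t)
    return _recording(np.tile(sig, (8, 1)))


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        rec = _sine_recording(10.0)
        out = bandpass_filter(rec, PreprocessConfig())
        mid = slice(int(20 * FS), int(40 * FS))  # avoid edge transients
        ratio = out.samples[0, mid].std() / rec.samples[0, mid].std()
        assert ratio > 0.95

    def test_stopband_drift_removed_and_matches_designed_response(self):
        cfg = PreprocessConfig()
        rec = _sine_recording(0.05, duration_s=120.0)
        out = bandpass_filter(rec, cfg)
        mid = slice(int(40 * FS), int(80 * FS))
        realized = out.samples[0, mid].std() / rec.samples[0, mid].std()
        assert realized < 0.10  # > 90% attenuation
        # independent oracle: the designed kernel's magnitude response
        taps = design_fir(cfg, FS)
        _, h = sps.freqz(taps, worN=[0.05], fs=FS)
        assert abs(realized - abs(h[0])) < 0.01

    def test_step_input_output_symmetric_about_step(self):
        n = 12000
        sig = np.zeros((8, n))
        sig[:, n // 2:] = 50.0
        out = bandpass_filter(_recording(sig), PreprocessConfig())
        y = out.samples[0]
        # zero-phase: response is antisymmetric about the step location
        w = 400
        left = y[n // 2 - w: n // 2]
        right = y[n // 2: n // 2 + w]
        np.testing.assert_allclose(left, -right[::-1], atol=1e-6 * 50)

    def test_recording_shorter_than_kernel_errors_with_minimum(self):
        with pytest.raises(ValueError, match="5501"):
            bandpass_filter(_recording(np.zeros((8, 1000))),
                            PreprocessConfig())


class TestTimingOffset:
    @pytest.mark.parametrize("offset_ms,expected", [
        (32.0, 16), (0.0, 0), (3.0, 2),  # 3 ms * 0.5 = 1.5 -> 2 (half away)
    ])
    def test_shift_in_samples(self, offset_ms, expected):
        events = pd.DataFrame({
            "onset_sample": [100, 200], "condition": ["Frequent"] * 2,
            "stimulus_id": ["tone"] * 2, "ordinal": [0, 1]})
        rec = _recording(np.zeros((8, 6000)), events)
        out = apply_timing_offset(
            rec, PreprocessConfig(offset_ms=offset_ms))
        assert (out.events["onset_sample"]
                == np.array([100, 200]) + expected).all()

    def test_event_shifted_beyond_end_is_dropped(self):
        events = pd.DataFrame({
            "onset_sample": [100, 5995], "condition": ["Frequent"] * 2,
            "stimulus_id": ["tone"] * 2, "ordinal": [0, 1]})
        rec = _recording(np.zeros((8, 6000)), events)
        out = apply_timing_offset(rec, PreprocessConfig(offset_ms=32.0))
        assert len(out.events) == 1
        assert out.meta["events_dropped_by_offset"] == 1


class TestEpoching:
    def test_epoch_length_501_samples_inclusive(self):
        events = pd.DataFrame({
            "onset_sample": [500], "condition": ["Frequent"],
            "stimulus_id": ["tone"], "ordinal": [0]})
        rec = _recording(np.random.default_rng(0).normal(size=(8, 2000)),
                         events)
        es = epoch(rec, PreprocessConfig(offset_ms=0.0))
        assert es.data.shape == (1, 8, 501)
        assert es.times_ms[0] == -200.0 and es.times_ms[-1] == 800.0

    def test_constant_signal_baselines_to_zero(self):
        events = pd.DataFrame({
            "onset_sample": [500], "condition": ["Frequent"],
            "stimulus_id": ["tone"], "ordinal": [0]})
        rec = _recording(np.full((8, 2000), 7.5), events)
        es = epoch(rec, PreprocessConfig(offset_ms=0.0,
                                         baseline_correct=True))
        np.testing.assert_allclose(es.data, 0.0, atol=1e-12)

    def test_event_too_close_to_edge_is_excluded_and_counted(self):
        events = pd.DataFrame({
            "onset_sample": [10, 500], "condition": ["Frequent"] * 2,
            "stimulus_id": ["tone"] * 2, "ordinal": [0, 1]})
        rec = _recording(np.zeros((8, 2000)), events)
        es = epoch(rec, PreprocessConfig(offset_ms=0.0))
        assert len(es) == 1
        assert es.meta["events_dropped_at_edge"] == 1


class TestRejection:
    def test_large_transient_rejected_with_reason_ptp(self):
        waves = np.zeros((3, 501))
        waves += np.sin(np.linspace(0, 20, 501))  # keep others alive
        es = make_epochs(waves, ["Frequent"] * 3)
        es.data[1, 4, 250] = 250.0  # one channel, 250 uV spike
        out = reject_artifacts(es, PreprocessConfig())
        assert not out.valid[1] and out.reason[1] == "ptp"
        assert out.valid[[0, 2]].all()

    def test_all_zero_epoch_rejected_as_flatline(self):
        waves = np.zeros((2, 501))
        waves[0] += np.sin(np.linspace(0, 20, 501))
        es = make_epochs(waves, ["Frequent"] * 2)
        out = reject_artifacts(es, PreprocessConfig())
        assert out.reason[1] == "flatline"
        assert out.valid[0]

    def test_rejection_matches_brute_force_scan_on_300_epoch_fixture(self):
        rng = np.random.default_rng(13)
        waves = rng.normal(0, 20, size=(300, 501))
        conds = rng.choice(["Frequent", "Infrequent", "TrialUnique"], 300)
        es = make_epochs(waves, conds)
        # inject known artifacts and flats
        for i in rng.choice(300, 40, replace=False):
            es.data[i, rng.integers(8), 100:130] += 400.0
        ptps = (es.data.max(axis=2) - es.data.min(axis=2)).max(axis=1)
        for i in rng.choice(np.flatnonzero(ptps < 200), 5, replace=False):
            es.data[i] = 0.05
        out = reject_artifacts(es, PreprocessConfig())
        for i in range(300):  # independent per-epoch loop
            invalid = False
            reason = "none"
            for ch in range(8):
                ptp = es.data[i, ch].max() - es.data[i, ch].min()
                if ptp < 0.1:
                    invalid, reason = True, "flatline"
            for ch in range(8):
                ptp = es.data[i, ch].max() - es.data[i, ch].min()
                if ptp > 200.0:
                    invalid, reason = True, "ptp"
            assert out.valid[i] == (not invalid)
            assert out.reason[i] == reason

    def test_rejection_is_permutation_invariant(self):
        rng = np.random.default_rng(5)
        waves = rng.normal(0, 80, size=(60, 501))
        conds = ["Frequent"] * 60
        es = make_epochs(waves, conds)
        out = reject_artifacts(es, PreprocessConfig())
        perm = rng.permutation(60)
        es_p = make_epochs(waves[perm], conds)
        out_p = reject_artifacts(es_p, PreprocessConfig())
        np.testing.assert_array_equal(out.valid[perm], out_p.valid)

    def test_rerunning_rejection_on_clean_set_changes_nothing(self):
        waves = np.random.default_rng(2).normal(0, 10, size=(20, 501))
        es = make_epochs(waves, ["Frequent"] * 20)
        once = reject_artifacts(es, PreprocessConfig())
        twice = reject_artifacts(once, PreprocessConfig())
        np.testing.assert_array_equal(once.valid, twice.valid)
        np.testing.assert_array_equal(once.reason, twice.reason)


class TestEqualization:
    def _mixed_set(self, n_f=80, n_i=23, n_t=61, seed=1):
        rng = np.random.default_rng(seed)
        n = n_f + n_i + n_t
        conds = np.array(["Frequent"] * n_f + ["Infrequent"] * n_i
                         + ["TrialUnique"] * n_t, dtype=object)
        rng.shuffle(conds)
        return make_epochs(rng.normal(0, 5, size=(n, 501)), conds)

    def test_downsamples_to_minimum_count(self):
        es = reject_artifacts(self._mixed_set(), PreprocessConfig())
        out = equalize_trials(es, seed=3)
        assert out.counts("kept") == {"Frequent": 23, "Infrequent": 23,
                                      "TrialUnique": 23}
        # kept sets are subsets of valid sets
        assert np.all(out.valid[out.kept])

    def test_equal_counts_is_a_no_op(self):
        es = reject_artifacts(self._mixed_set(20, 20, 20),
                              PreprocessConfig())
        out = equalize_trials(es, seed=3)
        np.testing.assert_array_equal(out.kept, es.valid)

    def test_same_seed_gives_identical_kept_sets(self):
        es = reject_artifacts(self._mixed_set(), PreprocessConfig())
        a = equalize_trials(es, seed=11)
        b = equalize_trials(es, seed=11)
        np.testing.assert_array_equal(a.kept, b.kept)

    def test_kept_epochs_preserve_presentation_order(self):
        es = reject_artifacts(self._mixed_set(), PreprocessConfig())
        out = equalize_trials(es, seed=7)
        for cond in ("Frequent", "TrialUnique"):
            idx = out.select(cond, "kept")
            ords = out.ordinals[idx]
            assert list(ords) == sorted(ords)

    def test_zero_valid_condition_marks_dataset_unusable(self):
        es = self._mixed_set(10, 5, 5)
        es.data[es.conditions == "Infrequent"] = 0.0  # all flatline
        es = reject_artifacts(es, PreprocessConfig())
        out = equalize_trials(es, seed=0)
        assert out.meta["usable"] is False


class TestInclusion:
    @pytest.mark.parametrize("m,expected", [(15, True), (14, False)])
    def test_boundary(self, m, expected):
        es = reject_artifacts(
            TestEqualization()._mixed_set(m, m, m), PreprocessConfig())
        es = equalize_trials(es, seed=0)
        assert inclusion_filter(es, PreprocessConfig()).included is expected

    def test_boundary_sweep_matches_configured_threshold(self):
        cfg = PreprocessConfig()
        smallest = None
        for m in range(1, 41):
            es = reject_artifacts(
                TestEqualization()._mixed_set(m, m, m), PreprocessConfig())
            es = equalize_trials(es, seed=0)
            if inclusion_filter(es, cfg).included and smallest is None:
                smallest = m
        assert smallest == cfg.min_trials_per_condition


def test_full_preprocess_matches_straight_line_reference(small_design):
    """End-to-end oracle: the pipeline on a 50-trial noisy fixture must
    match an independent straight-line reimplementation epoch-for-epoch
    (filter, offset, epoching, thresholds, equalization)."""
    design = DesignSpec(n_trials_total=50, n_frequent=30, n_infrequent=10,
                        n_trial_unique=10)
    seq = generate_sequence(design, seed=17)
    spec = make_noise_free_subject(design, seed=18, noise_sd_uv=4.0,
                                   drift_amplitude_uv=15.0,
                                   artifact_epoch_fraction=0.1)
    rec = synthesize_recording(spec, seq)
    cfg = PreprocessConfig(equalize_seed=99)
    es, decision = preprocess_recording(rec, cfg)

    # ---- reference: plain numpy/scipy, no shared pipeline code ----
    taps = sps.firwin(5501, [0.5, 30.0], pass_zero=False,
                      window="blackman", fs=FS)
    x = rec.samples - rec.samples.mean(axis=1, keepdims=True)
    filt = np.stack([np.convolve(x[ch], taps, mode="same")
                     for ch in range(8)])
    onsets = rec.events["onset_sample"].to_numpy() + 16
    ref_epochs, ref_conds, ref_ords = [], [], []
    for onset, cond, o in zip(onsets, rec.events["condition"],
                              rec.events["ordinal"]):
        seg = filt[:, onset - 100: onset + 401].copy()
        seg -= seg[:, :101].mean(axis=1, keepdims=True)
        ref_epochs.append(seg)
        ref_conds.append(cond)
        ref_ords.append(o)
    ref_epochs = np.stack(ref_epochs)
    np.testing.assert_allclose(es.data, ref_epochs, atol=1e-7)

    ref_valid = np.array([
        not ((ep.max(axis=1) - ep.min(axis=1) > 200).any()
             or (ep.max(axis=1) - ep.min(axis=1) < 0.1).any())
        for ep in ref_epochs])
    np.testing.assert_array_equal(es.valid, ref_valid)

    m = min(np.sum(ref_valid & (np.array(ref_conds) == c))
            for c in ("Frequent", "Infrequent", "TrialUnique"))
    rng = np.random.default_rng(99)
    ref_kept = np.zeros(len(ref_epochs), dtype=bool)
    for cond in ("Frequent", "Infrequent", "TrialUnique"):
        idx = np.flatnonzero(ref_valid & (np.array(ref_conds) == cond))
        idx = idx[np.argsort(np.array(ref_ords)[idx], kind="stable")]
        if len(idx) > m:
            idx = np.sort(rng.choice(idx, size=m, replace=False))
        ref_kept[idx] = True
    np.testing.assert_array_equal(es.kept, ref_kept)
    assert decision.included == all(
        np.sum(ref_kept & (np.array(ref_conds) == c)) >= 15
        for c in ("Frequent", "Infrequent", "TrialUnique"))
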