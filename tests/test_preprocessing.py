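"""Signal chain: filter vs analytic response, epoching, rejection,
baseline, downsampling — each against an independent oracle where one
exists."""

import numpy as np
import pytest
from scipy import signal

from vibrotap import (EEGRecording, SubjectProfile, bandpass, baseline_correct,
                      build_vt2_schedule, downsample_features, extract_epochs,
                      preprocess, reject_artifacts, simulate_session)
from vibrotap.preprocessing import (N_BINS, POST_SAMPLES, PRE_SAMPLES,
                                    butter_sos)

FS = 256.0


def _sine_recording(freq_hz, duration_s=60.0, amplitude=10.0, n_ch=2):
    t = np.arange(int(duration_s * FS)) / FS
    data = np.tile(amplitude * np.sin(2 * np.pi * freq_hz * t), (n_ch, 1))
    return EEGRecording(data=data, fs_hz=FS,
                        channel_names=tuple(f"ch{i}" for i in range(n_ch)))


def _analytic_gain(freq_hz):
    """|H(f)| of the single-pass Butterworth band-pass (the oracle)."""
    w, h = signal.sosfreqz(butter_sos(fs_hz=FS), worN=[freq_hz], fs=FS)
    return float(np.abs(h[0]))


def _central_rms(x, fraction=0.5):
    n = x.shape[-1]
    lo = int(n * (1 - fraction) / 2)
    return np.sqrt(np.mean(x[..., lo : n - lo] ** 2))


class TestBandpass:
    def test_stopband_attenuation_at_50hz(self):
        rec = _sine_recording(50.0)
        out = bandpass(rec)
        assert _central_rms(out.data) <= _analytic_gain(50.0) * _central_rms(rec.data)

    def test_dc_removed(self):
        rec = EEGRecording(data=np.full((2, int(30 * FS)), 7.0), fs_hz=FS,
                           channel_names=("a", "b"))
        out = bandpass(rec)
        assert _central_rms(out.data) < 1e-6 * 7.0  # |H(0)| = 0

    def test_passband_gain_matches_two_pass_analytic_response(self):
        rec = _sine_recording(10.0, duration_s=120.0)
        out = bandpass(rec)  # zero-phase: gain is |H|^2
        measured = _central_rms(out.data) / _central_rms(rec.data)
        assert measured == pytest.approx(_analytic_gain(10.0) ** 2, rel=0.01)

    def test_causal_mode_single_pass_gain(self):
        rec = _sine_recording(10.0, duration_s=120.0)
        out = bandpass(rec, zero_phase=False)
        measured = _central_rms(out.data) / _central_rms(rec.data)
        assert measured == pytest.approx(_analytic_gain(10.0), rel=0.01)

    def test_band_outside_nyquist_rejected(self):
        rec = _sine_recording(10.0, duration_s=5.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, low_hz=0.1, high_hz=200.0)


class TestEpoching:
    def test_epoch_count_and_width(self, null_profile):
        schedule = build_vt2_schedule(seed=2)
        rec = simulate_session(schedule, null_profile, seed=3)
        ep = extract_epochs(rec)
        assert ep.epochs.shape == (480, 8, PRE_SAMPLES + POST_SAMPLES)
        assert ep.epochs.shape[2] == 179

    def test_labels_tally_matches_schedule(self, null_profile):
        schedule = build_vt2_schedule(seed=2)
        rec = simulate_session(schedule, null_profile, seed=3)
        ep = extract_epochs(rec)
        assert (ep.labels["trial_type"] == "deviant").sum() == 60
        assert (ep.labels["trial_type"] == "standard").sum() == 420

    def test_event_near_edge_flagged_not_dropped(self):
        # an event 10 samples from the start cannot host a 25-sample baseline
        import pandas as pd
        rec = EEGRecording(data=np.zeros((1, 1000)), fs_hz=FS,
                           channel_names=("a",))
        events = pd.DataFrame({
            "onset": [10 / FS, 500 / FS],
            "duration": [0.03, 0.03],
            "trial_type": ["deviant", "standard"],
            "site": ["right_wrist", "left_wrist"],
            "is_target": [1, 0],
        })
        ep = extract_epochs(rec, events)
        assert ep.n_trials == 2
        assert ep.rejected_mask.tolist() == [True, False]
        assert ep.rejection_reason[0] == "edge"

    def test_no_events_error(self):
        rec = EEGRecording(data=np.zeros((1, 100)), fs_hz=FS,
                           channel_names=("a",))
        with pytest.raises(ValueError, match="no events"):
            extract_epochs(rec)


class TestRejection:
    def _toy_epochs(self, values):
        import pandas as pd
        n = len(values)
        epochs = np.zeros((n, 2, 179))
        for i, v in enumerate(values):
            epochs[i, 0, 40] = v
        labels = pd.DataFrame({"trial_type": ["deviant"] * n,
                               "site": ["right_wrist"] * n,
                               "is_target": [True] * n})
        from vibrotap.preprocessing import EpochSet
        return EpochSet(epochs=epochs, labels=labels, fs_hz=FS,
                        window=(PRE_SAMPLES, POST_SAMPLES),
                        rejected_mask=np.zeros(n, bool),
                        rejection_reason=np.array([""] * n, object),
                        channel_names=("a", "b"))

    def test_single_sample_over_threshold_rejected(self):
        ep = reject_artifacts(self._toy_epochs([150.0, 50.0, -150.0, 0.0]))
        assert ep.rejected_mask.tolist() == [True, False, True, False]
        assert ep.n_rejected == 2
        assert set(ep.rejection_reason[ep.rejected_mask]) == {"amplitude"}

    def test_all_zero_epochs_kept(self):
        ep = reject_artifacts(self._toy_epochs([0.0] * 5))
        assert ep.n_rejected == 0

    def test_exact_threshold_not_rejected(self):
        ep = reject_artifacts(self._toy_epochs([100.0]))
        assert ep.n_rejected == 0  # strictly "exceeding"

    def test_counts_match_brute_force_scan(self):
        prof = SubjectProfile(p3_amplitude_uv=0, noise_sd_uv=5,
                              artifact_rate_per_min=10)
        schedule = build_vt2_schedule(seed=4)
        rec = simulate_session(schedule, prof, seed=5)
        filtered = bandpass(rec)
        ep = reject_artifacts(extract_epochs(filtered))
        # independent full scan over the raw filtered array
        expected = []
        for e in filtered.events.events:
            i0 = int(round(e.onset_s * FS)) - PRE_SAMPLES
            window = filtered.data[:, i0 : i0 + 179]
            expected.append(bool((np.abs(window) > 100.0).any()))
        assert ep.rejected_mask.tolist() == expected
        assert ep.n_rejected == sum(expected) > 0

    def test_rejected_plus_retained_is_total(self, null_profile):
        schedule = build_vt2_schedule(n_stimuli=64, seed=1)
        rec = simulate_session(schedule, null_profile, seed=1)
        ep = reject_artifacts(extract_epochs(bandpass(rec)))
        assert ep.n_rejected + ep.n_retained == ep.n_trials == 64


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        r = TestRejection()
        ep = r._toy_epochs([0.0])
        ep.epochs[:] = 3.5
        out = baseline_correct(ep)
        assert np.allclose(out.epochs, 0.0)

    def test_pre_onset_mean_is_zero(self, null_profile):
        schedule = build_vt2_schedule(n_stimuli=64, seed=6)
        rec = simulate_session(schedule, null_profile, seed=6)
        out = baseline_correct(extract_epochs(rec))
        pre_means = out.epochs[:, :, :PRE_SAMPLES].mean(axis=2)
        assert np.allclose(pre_means, 0.0, atol=1e-12)

    def test_offset_invariance(self, null_profile):
        schedule = build_vt2_schedule(n_stimuli=32, seed=6)
        rec = simulate_session(schedule, null_profile, seed=6)
        ep = extract_epochs(rec)
        shifted = ep.copy()
        shifted.epochs[3, 1, :] += 42.0
        a = baseline_correct(ep)
        b = baseline_correct(shifted)
        assert np.allclose(a.epochs, b.epochs, atol=1e-12)


class TestFeatures:
    def test_dimensionality_is_56(self, high_snr_vt2_features):
        _, feats = high_snr_vt2_features
        assert feats.X.shape[1] == 56 == N_BINS * 8

    def test_constant_epoch_gives_constant_bins(self):
        r = TestRejection()
        ep = r._toy_epochs([0.0])
        ep.epochs[:] = 2.5
        feats = downsample_features(ep)
        assert np.allclose(feats.X, 2.5)
        assert feats.X.shape == (1, 2 * N_BINS)

    def test_linear_ramp_bin_means_closed_form(self):
        r = TestRejection()
        ep = r._toy_epochs([0.0])
        ramp = np.arange(POST_SAMPLES, dtype=float)
        ep.epochs[0, :, PRE_SAMPLES:] = ramp
        ep.epochs[0, :, :PRE_SAMPLES] = 0.0
        feats = downsample_features(ep)
        # mean of samples [22b, 22b+21] = 22b + 10.5
        expected = 22 * np.arange(N_BINS) + 10.5
        assert np.allclose(feats.X[0, :N_BINS], expected)
        assert np.allclose(feats.X[0, N_BINS:], expected)  # channel-major

    def test_channel_major_ordering(self, null_profile):
        schedule = build_vt2_schedule(n_stimuli=32, seed=8)
        rec = simulate_session(schedule, null_profile, seed=8)
        ep = baseline_correct(extract_epochs(rec))
        feats = downsample_features(ep)
        ch = 3
        seg = ep.epochs[0, ch, PRE_SAMPLES:]
        manual = seg.reshape(N_BINS, 22).mean(axis=1)
        assert np.allclose(feats.X[0, ch * N_BINS : (ch + 1) * N_BINS], manual)

    def test_rejected_trials_excluded(self):
        r = TestRejection()
        ep = r._toy_epochs([150.0, 10.0, 20.0])
        ep = reject_artifacts(ep)
        feats = downsample_features(ep)
        assert feats.X.shape[0] == 2
        assert feats.trial_index.tolist() == [1, 2]

    def test_features_match_brute_force_loop(self, null_profile):
        # oracle: recompute every feature straight from the filtered samples
        schedule = build_vt2_schedule(n_stimuli=24, seed=9)
        rec = simulate_session(schedule, null_profile, seed=9)
        ep, feats = preprocess(rec)
        filtered = bandpass(rec)
        rows = []
        for i in feats.trial_index:
            e = filtered.events.events[i]
            i0 = int(round(e.onset_s * FS)) - PRE_SAMPLES
            win = filtered.data[:, i0 : i0 + 179].copy()
            win -= win[:, :PRE_SAMPLES].mean(axis=1, keepdims=True)
            post = win[:, PRE_SAMPLES:]
            rows.append(post.reshape(8, N_BINS, 22).mean(axis=2).ravel())
        assert np.allclose(feats.X, np.vstack(rows), atol=1e-10)


class TestPipelineOrder:
    def test_reject_baseline_commute_for_retained_trials(self, null_profile):
        schedule = build_vt2_schedule(n_stimuli=64, seed=10)
        prof = SubjectProfile(p3_amplitude_uv=0, noise_sd_uv=5,
                              artifact_rate_per_min=5)
        rec = simulate_session(schedule, prof, seed=10)
        ep = extract_epochs(bandpass(rec))
        a = baseline_correct(reject_artifacts(ep))
        b = reject_artifacts(baseline_correct(ep))
        keep = ~a.rejected_mask & ~b.rejected_mask
        assert keep.any()
        assert np.allclose(a.epochs[keep], b.epochs[keep])
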