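"""Index extraction: oracles, closed forms, and ground-truth recovery."""

import numpy as np
import pytest
import dyadphys as dp
from dyadphys.errors import (DegenerateError, InsufficientDataError,
                             QualityError)
from dyadphys.features import IBISeries, _clean_pupil


def series(intervals_ms, t0=0.0):
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    beats = np.concatenate([[t0], t0 + np.cumsum(intervals_ms) / 1000.0])
    return IBISeries(intervals_ms, beats)


class TestArtifactCorrection:
    def test_clean_series_unchanged(self):
        ibi = series([800, 810, 790, 805, 795, 800])
        out = dp.correct_ibi_artifacts(ibi)
        np.testing.assert_array_equal(out.intervals_ms, ibi.intervals_ms)
        assert not out.artifact_flags.any()

    def test_single_ectopic_interpolated(self):
        out = dp.correct_ibi_artifacts(series([800, 800, 400, 800, 800]))
        assert list(out.artifact_flags) == [False, False, True, False, False]
        assert out.intervals_ms[2] == pytest.approx(800.0, abs=1.0)

    def test_too_many_artifacts_is_quality_error(self):
        with pytest.raises(QualityError):
            dp.correct_ibi_artifacts(series([800, 400, 1400, 400, 800]))

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            dp.correct_ibi_artifacts(series([800, 800]))


class TestTimeDomain:
    def test_constant_series(self):
        hr, nn50, rmssd = dp.hrv_time_domain(series([800] * 10))
        assert (hr, nn50, rmssd) == (pytest.approx(75.0), 0, 0.0)

    def test_hand_computed_example(self):
        hr, nn50, rmssd = dp.hrv_time_domain(series([800, 860, 870, 940]))
        assert nn50 == 2
        assert rmssd == pytest.approx(np.sqrt((60 ** 2 + 10 ** 2 + 70 ** 2) / 3),
                                      abs=0.01)

    def test_exactly_50ms_does_not_count(self):
        _, nn50, _ = dp.hrv_time_domain(series([800, 850, 800]))
        assert nn50 == 0

    def test_oracle_equivalence_on_random_series(self):
        """Brute-force loop over interval pairs as the independent oracle."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x = rng.uniform(400, 1500, size=rng.integers(2, 40))
            hr, nn50, rmssd = dp.hrv_time_domain(series(x))
            nn50_brute = sum(1 for i in range(len(x) - 1)
                             if abs(x[i + 1] - x[i]) > 50.0)
            sq = [(x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1)]
            rmssd_brute = (sum(sq) / len(sq)) ** 0.5
            assert nn50 == nn50_brute
            assert rmssd == pytest.approx(rmssd_brute, rel=1e-12)
            assert hr == pytest.approx(60000.0 / np.mean(x), rel=1e-12)

    def test_nn50_bounded_by_pair_count(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(500, 1200, 30)
        _, nn50, rmssd = dp.hrv_time_domain(series(x))
        assert 0 <= nn50 <= len(x) - 1
        assert rmssd >= 0


class TestSpectral:
    def test_equal_amplitudes_balanced(self):
        ibi = dp.synthesize_ibi_train(400, 800, lf_amp_ms=30, hf_amp_ms=30,
                                      lf_freq_hz=0.1, hf_freq_hz=0.25)
        sp = dp.hrv_spectral(ibi)
        assert 0.8 <= sp.lf_hf_ratio <= 1.25

    def test_single_lf_modulation_dominates(self):
        ibi = dp.synthesize_ibi_train(400, 800, lf_amp_ms=30,
                                      lf_freq_hz=0.1)
        sp = dp.hrv_spectral(ibi)
        assert sp.lf_power / (sp.lf_power + sp.hf_power) >= 0.9

    def test_constant_series_flagged_nan(self):
        with pytest.warns(UserWarning):
            sp = dp.hrv_spectral(series([800] * 300))
        assert np.isnan(sp.lf_hf_ratio)

    def test_band_sum_below_total_integral(self):
        rng = np.random.default_rng(5)
        ibi = dp.synthesize_ibi_train(400, 800, lf_amp_ms=25, hf_amp_ms=20,
                                      jitter_ms=4, rng=rng)
        sp = dp.hrv_spectral(ibi)
        mask = sp.frequency_grid <= 0.5
        total = np.trapezoid(sp.psd[mask], sp.frequency_grid[mask])
        assert (sp.vlf_power + sp.lf_power + sp.hf_power) <= total * 1.01

    def test_short_record_falls_back_with_warning(self):
        ibi = dp.synthesize_ibi_train(60, 800, lf_amp_ms=20, lf_freq_hz=0.1)
        with pytest.warns(UserWarning):
            dp.hrv_spectral(ibi)


class TestRespiration:
    def make_rsp(self, freq, duration=300.0, rate=256.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * rate)) / rate
        x = np.sin(2 * np.pi * freq * t) if freq else np.zeros(t.size)
        return dp.ChannelRecording("RSP", rate,
                                   x + noise * rng.standard_normal(t.size))

    def test_quarter_hz_clean(self):
        report = dp.respiration_check(self.make_rsp(0.25))
        assert report.rate_hz == pytest.approx(0.25, abs=0.02)
        assert not report.lf_contamination and not report.indeterminate

    def test_slow_breathing_contaminates_lf(self):
        report = dp.respiration_check(self.make_rsp(0.10))
        assert report.lf_contamination

    def test_white_noise_is_indeterminate(self):
        report = dp.respiration_check(self.make_rsp(0.0, noise=1.0, seed=2))
        assert report.indeterminate


class TestScalarChannels:
    def test_sc_constant(self):
        rec = dp.ChannelRecording("GSR", 32.0, np.full(320, 5.0))
        assert dp.sc_statistics(rec) == (pytest.approx(5.0), pytest.approx(0.0))

    def test_sc_ramp_closed_form(self):
        rec = dp.ChannelRecording("GSR", 32.0, np.linspace(0, 1, 32 * 60))
        mean, sd = dp.sc_statistics(rec)
        assert mean == pytest.approx(0.5, abs=1e-3)
        assert sd == pytest.approx(1 / np.sqrt(12), abs=1e-3)

    def test_sc_resampled_from_256hz(self):
        rec = dp.ChannelRecording("GSR", 256.0, np.full(2560, 4.0))
        mean, _ = dp.sc_statistics(rec)
        assert mean == pytest.approx(4.0, rel=1e-3)

    def test_emg_constant_offset_is_zero(self):
        rec = dp.ChannelRecording("EMG_CS", 256.0, np.full(2560, 7.0))
        assert dp.emg_rms_envelope(rec) == pytest.approx(0.0, abs=1e-12)

    def test_emg_sinusoid(self):
        t = np.arange(2560) / 256.0
        rec = dp.ChannelRecording("EMG_CS", 256.0, 3.0 * np.sin(2 * np.pi * 30 * t))
        assert dp.emg_rms_envelope(rec) == pytest.approx(3.0 / np.sqrt(2),
                                                         rel=1e-3)

    def test_emg_orthogonal_sinusoids_parseval(self):
        t = np.arange(256 * 20) / 256.0
        x = 2.0 * np.sin(2 * np.pi * 25 * t) + 3.0 * np.sin(2 * np.pi * 40 * t)
        rec = dp.ChannelRecording("EMG_CS", 256.0, x)
        assert dp.emg_rms_envelope(rec) == pytest.approx(
            np.sqrt((4.0 + 9.0) / 2), rel=1e-3)


class TestEEGBandPower:
    def sinusoid(self, freq, amp=10.0, duration=60.0, rate=256.0):
        t = np.arange(int(duration * rate)) / rate
        return dp.ChannelRecording("EEG_FP1", rate,
                                   amp * np.sin(2 * np.pi * freq * t))

    def test_alpha_sinusoid_parseval(self):
        power = dp.eeg_band_power(self.sinusoid(8.0, amp=10.0), "slow_alpha")
        assert power == pytest.approx(50.0, rel=0.1)  # A^2/2
        assert dp.eeg_band_power(self.sinusoid(8.0), "beta") < 1.0

    def test_beta_sinusoid_parseval(self):
        power = dp.eeg_band_power(self.sinusoid(20.0, amp=10.0), "beta")
        assert power == pytest.approx(50.0, rel=0.1)
        assert dp.eeg_band_power(self.sinusoid(20.0), "slow_alpha") < 1.0

    def test_zero_signal(self):
        rec = dp.ChannelRecording("EEG_FP1", 256.0, np.zeros(256 * 10))
        assert dp.eeg_band_power(rec, "slow_alpha") == 0.0

    def test_blink_excision_leaves_too_little_data(self):
        rec = self.sinusoid(8.0, duration=5.0)
        with pytest.raises(InsufficientDataError):
            dp.eeg_band_power(rec, "slow_alpha",
                              blink_times=np.arange(0.2, 5.0, 0.4))

    def test_asymmetry_properties(self):
        assert dp.alpha_asymmetry(4.0, 4.0) == 0.0
        assert dp.alpha_asymmetry(4.0 * np.e, 4.0) == pytest.approx(1.0)
        assert dp.alpha_asymmetry(2.0, 5.0) == pytest.approx(
            -dp.alpha_asymmetry(5.0, 2.0))
        with pytest.raises(DegenerateError):
            dp.alpha_asymmetry(0.0, 1.0)


class TestPupil:
    def gaze(self, value, n=600, invalid_fraction=0.0, rate=60.0):
        t = np.arange(n) / rate
        validity = np.ones(n, dtype=bool)
        k = int(invalid_fraction * n)
        if k:
            validity[:k] = False
        pupil = np.where(validity, value, np.nan)
        return dp.GazeRecording(rate, t, pupil.copy(), pupil.copy(), validity)

    def test_difference_is_phase_minus_baseline(self):
        assert dp.pupil_dilation(self.gaze(3.4252), self.gaze(3.0)) == \
            pytest.approx(0.4252)

    def test_identical_windows_give_zero(self):
        assert dp.pupil_dilation(self.gaze(3.1), self.gaze(3.1)) == 0.0

    def test_mostly_invalid_is_quality_error(self):
        with pytest.raises(QualityError):
            dp.pupil_dilation(self.gaze(3.0, invalid_fraction=0.6),
                              self.gaze(3.0))

    def test_short_gaps_bridged(self):
        n, rate = 600, 60.0
        t = np.arange(n) / rate
        validity = np.ones(n, dtype=bool)
        validity[100:110] = False  # 167 ms blink
        pupil = np.where(validity, 3.0, np.nan)
        gaze = dp.GazeRecording(rate, t, pupil.copy(), pupil.copy(), validity)
        cleaned = _clean_pupil(gaze)
        assert cleaned.size == n
        assert np.allclose(cleaned, 3.0)


class TestFullExtraction:
    def test_ground_truth_recovery(self, pc_session, pc_features, pc_alignment):
        """Round trip: extraction recovers the generator's index targets."""
        _, truth = pc_session
        fv = pc_features
        t = truth.indices
        assert fv.heart_rate == pytest.approx(t["heart_rate"], rel=0.05)
        assert fv.skin_conductance == pytest.approx(t["skin_conductance"],
                                                    rel=0.02)
        assert fv.pupil_dilation == pytest.approx(t["pupil_dilation"],
                                                  abs=0.02)
        assert fv.lf_hf == pytest.approx(t["lf_hf"], rel=0.2)
        assert fv.emg_corrugator == pytest.approx(t["emg_corrugator"],
                                                  rel=0.05)
        # asymmetry: sign agreement when the sides differ enough
        if abs(t["alpha_asymmetry"] - 1.0) > 0.2:
            assert np.sign(fv.alpha_asymmetry - 1.0) == \
                np.sign(t["alpha_asymmetry"] - 1.0)

    def test_missing_channel_marks_exclusion(self, pc_session):
        session, _ = pc_session
        channels = {k: v for k, v in session.channels.items()
                    if k != dp.ChannelName.GSR}
        stripped = dp.SessionRecord(session.subject_id, session.condition,
                                    session.role, channels, session.gaze,
                                    session.timeline, session.decision)
        df = dp.extract_cohort_features([stripped])
        assert bool(df.loc[0, "excluded"])
        assert "GSR" in df.loc[0, "exclusion_reason"]

    def test_cohort_frame_shape(self, small_cohort_features):
        feats, truths = small_cohort_features
        assert len(feats) == 8
        assert set(feats.condition) == {"PC", "IC"}
        for m in ("heart_rate", "rmssd", "pupil_dilation"):
            assert np.isfinite(feats.loc[~feats.excluded, m]).all()
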