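"""HRV formulas, SCG/PPG fiducial estimators, marker-table orchestration."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cvawear.beats import NNSeries
from cvawear.io import preprocess_record
from cvawear.markers import (MARKER_NAMES, build_marker_table, detect_ao_ac,
                             extract_window_markers, interpolate_nn_gaps,
                             nn_spectrum, pat_from_foot, ppg_amplitude,
                             ppg_foot, ptt_from_pat_pep, rmssd, scg_amplitude,
                             sdnn, systolic_intervals)
from cvawear.quality import BeatMatrix, segment_beats
from cvawear.simulate import (SimConfig, gen_dose_response, gen_ppg,
                              gen_rr_series, gen_scg)


class TestGapFill:
    def _series(self, nn, valid):
        nn = np.asarray(nn, float)
        valid = np.asarray(valid, bool)
        t = np.cumsum(nn) / 1000.0
        reason = np.where(valid, "", "mad_outlier")
        return NNSeries(t, nn, valid, reason)

    def test_no_gaps_is_identity(self):
        s = self._series([800, 810, 790], [1, 1, 1])
        _, filled = interpolate_nn_gaps(s)
        assert np.array_equal(filled, s.nn_ms)

    def test_fill_is_monotone_between_neighbours(self):
        s = self._series([800, 0, 820], [1, 0, 1])
        _, filled = interpolate_nn_gaps(s)
        assert 800.0 <= filled[1] <= 820.0

    def test_linear_ramp_gap_filled_exactly(self):
        nn = np.linspace(700, 900, 11)
        valid = np.ones(11, bool)
        valid[5] = False
        s = self._series(nn, valid)
        _, filled = interpolate_nn_gaps(s)
        assert filled[5] == pytest.approx(nn[5], abs=1e-9)

    def test_all_masked_rejected(self):
        s = self._series([800, 810], [0, 0])
        with pytest.raises(ValueError):
            interpolate_nn_gaps(s)


class TestTimeDomainHRV:
    def test_worked_series_rmssd(self):
        assert rmssd([800, 810, 790, 805]) == pytest.approx(
            np.sqrt((10**2 + 20**2 + 15**2) / 3), abs=1e-9)

    def test_worked_series_sdnn(self):
        assert sdnn([800, 810, 790, 805]) == pytest.approx(
            np.std([800, 810, 790, 805], ddof=1), abs=1e-9)

    def test_constant_series_gives_zero(self):
        assert rmssd([800.0] * 50) == 0.0
        assert sdnn([800.0] * 50) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rmssd([800.0])


class TestSpectrum:
    def test_lf_only_modulation_dominates_lf(self):
        t, rr = gen_rr_series(300, 60, 30, 0, 0, seed=2)
        lf, hf, ratio = nn_spectrum(t[1:], rr)
        assert ratio > 10

    def test_hf_only_modulation_dominates_hf(self):
        t, rr = gen_rr_series(300, 60, 0, 30, 0, seed=2)
        lf, hf, ratio = nn_spectrum(t[1:], rr)
        assert ratio < 0.1

    def test_band_power_follows_amplitude_square_law(self):
        powers = []
        for amp in (15.0, 30.0):
            t, rr = gen_rr_series(600, 60, amp, 0, 0, seed=3)
            lf, _, _ = nn_spectrum(t[1:], rr)
            powers.append(lf)
        assert powers[1] / powers[0] == pytest.approx(4.0, rel=0.10)

    def test_short_series_single_segment_fallback_warns(self):
        t, rr = gen_rr_series(300, 60, 20, 10, 3, seed=4)
        with pytest.warns(UserWarning, match="single segment"):
            nn_spectrum(t[1:61], rr[:60])


class TestSCGFiducials:
    def _ensemble(self, pep, n=40, noise=0.0):
        times = np.arange(0.5, 0.5 + n, 1.0)
        pep = np.broadcast_to(np.asarray(pep, float), times.shape)
        sig = gen_scg(times, pep, 300.0, duration_s=n + 1.0, fs=500.0,
                      noise_sd=noise, seed=1)
        return segment_beats(sig, 500.0, times)

    def test_constant_pep_recovered_within_10ms(self):
        fid = detect_ao_ac(self._ensemble(80.0))
        assert abs(np.nanmedian(fid["ao"]) - 80.0) <= 10.0
        assert abs(np.nanmedian(fid["ac"]) - 380.0) <= 10.0

    def test_pep_ramp_tracked_with_correct_slope(self):
        n = 40
        pep = np.linspace(60.0, 120.0, n)
        fid = detect_ao_ac(self._ensemble(pep, n=n))
        ok = np.isfinite(fid["ao"])
        slope = np.polyfit(np.flatnonzero(ok), fid["ao"][ok], 1)[0]
        true_slope = (120.0 - 60.0) / (n - 1)
        assert slope == pytest.approx(true_slope, rel=0.15)

    def test_single_candidate_median_is_that_candidate(self):
        # one isolated positive bump per beat: its time is the fiducial
        beats = np.zeros((12, 300))
        beats[:, 40] = 1.0   # 80 ms at 500 Hz
        beats[:, 41] = 0.5
        beats[:, 39] = 0.5
        bm = BeatMatrix(beats, np.arange(12.0), 500.0)
        fid = detect_ao_ac(bm)
        assert np.allclose(fid["ao"], 80.0)

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            detect_ao_ac(self._ensemble(80.0, n=5))


class TestSystolicIntervals:
    def test_worked_example(self):
        pep, lvet, lveti, ratio = systolic_intervals(80.0, 380.0, 70.0)
        assert pep == 80.0
        assert lvet == 300.0
        assert lveti == pytest.approx(419.0)
        assert ratio == pytest.approx(80.0 / 419.0)

    def test_zero_correction_slope_disables_hr_correction(self):
        _, lvet, lveti, _ = systolic_intervals(80.0, 380.0, 70.0, c_hr=0.0)
        assert lveti == lvet

    def test_ratio_monotone_in_pep(self):
        ratios = [systolic_intervals(p, p + 300.0, 70.0)[3]
                  for p in (60.0, 80.0, 100.0)]
        assert ratios[0] < ratios[1] < ratios[2]

    def test_ac_before_ao_rejected(self):
        with pytest.raises(ValueError):
            systolic_intervals(300.0, 200.0, 70.0)


class TestSCGAmplitude:
    def test_packet_amplitude_recovered(self):
        beat = gen_scg(np.array([0.0]), 80.0, 300.0, amp=1.0,
                       duration_s=0.6, fs=500.0)
        a = scg_amplitude(beat, 80.0, 500.0)
        assert a == pytest.approx(np.ptp(beat[15:75]), rel=1e-6)
        assert 1.0 <= a <= 1.4  # peak-to-trough of a unit packet

    def test_linear_in_scale(self):
        beat = gen_scg(np.array([0.0]), 80.0, 300.0, duration_s=0.6,
                       fs=500.0)
        assert scg_amplitude(2 * beat, 80.0, 500.0) == \
            pytest.approx(2 * scg_amplitude(beat, 80.0, 500.0))

    def test_flat_beat_gives_zero(self):
        assert scg_amplitude(np.zeros(300), 80.0, 500.0) == 0.0

    def test_window_outside_beat_rejected(self):
        with pytest.raises(ValueError):
            scg_amplitude(np.zeros(300), 900.0, 500.0)


class TestPPGFoot:
    def _linear_pulse(self, foot_ms=200.0, fs=500.0):
        n = 300
        x = np.zeros(n)
        i0 = int(foot_ms * fs / 1000)
        i1 = int((foot_ms + 150.0) * fs / 1000)
        x[i0:i1] = np.linspace(0, 1, i1 - i0, endpoint=False)
        x[i1:] = 1.0
        return x

    def test_tangent_estimator_exact_on_piecewise_linear_pulse(self):
        x = self._linear_pulse()
        foot, est = ppg_foot(x, 500.0)
        assert est["tangents"] == pytest.approx(200.0, abs=1e-9)
        assert foot == pytest.approx(200.0, abs=2.0)  # within one sample

    def test_all_estimators_shift_equivariant(self):
        _, e1 = ppg_foot(self._linear_pulse(150.0), 500.0)
        _, e2 = ppg_foot(self._linear_pulse(200.0), 500.0)
        for k in e1:
            assert e2[k] - e1[k] == pytest.approx(50.0, abs=2.1)

    def test_timings_invariant_to_amplitude_scaling(self):
        x = self._linear_pulse()
        _, e1 = ppg_foot(x, 500.0)
        _, e2 = ppg_foot(7.3 * x, 500.0)
        for k in e1:
            assert e1[k] == pytest.approx(e2[k], abs=1e-9)

    def test_flat_beat_reported_missing(self):
        foot, est = ppg_foot(np.zeros(300), 500.0)
        assert np.isnan(foot) and est == {}

    def test_generated_pulse_foot_within_one_ppg_sample(self):
        times, _ = gen_rr_series(300, 60, 0, 0, 0, seed=1)
        from cvawear.io import bandpass, resample_uniform

        y = gen_ppg(times, 200.0, 1.0, duration_s=300.0, fs=67.0)
        y = bandpass(resample_uniform(y, 67.0, 500.0), 500.0, 1.0, 8.0)
        bm = segment_beats(y, 500.0, times, channel="ppg")
        feet = [ppg_foot(b, 500.0)[0] for b in bm.beats[5:50]]
        assert abs(np.median(feet) - 200.0) <= 1000.0 / 67.0


class TestPATPTT:
    def test_ptt_definition(self):
        assert ptt_from_pat_pep(200.0, 80.0) == 120.0

    def test_implausible_ptt_rejected(self):
        with pytest.raises(ValueError):
            ptt_from_pat_pep(80.0, 90.0)

    def test_ppg_amplitude_and_pat_accessors(self):
        beat = np.concatenate([np.zeros(50), np.linspace(0, 1.0, 50)])
        assert ppg_amplitude(beat) == 1.0
        assert pat_from_foot(123.0) == 123.0


@pytest.fixture(scope="module")
def sim_table():
    cfg = SimConfig(n_subjects=3, seed=21)
    subs = gen_dose_response(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = build_marker_table(subs)
    return cfg, subs, table


class TestMarkerTable:
    def test_one_row_per_subject_state(self, sim_table):
        _, subs, table = sim_table
        assert len(table) == 2 * len(subs)
        assert set(table["state"]) == {"OFF", "ON"}
        assert set(MARKER_NAMES) <= set(table.columns)

    def test_pipeline_recovers_ground_truth_timings(self, sim_table):
        _, subs, table = sim_table
        truth = {(s["subject"], st): s[f"truth_{st.lower()}"]
                 for s in subs for st in ("OFF", "ON")}
        for _, row in table.iterrows():
            tr = truth[(row["subject"], row["state"])]
            assert abs(row["PEP"] - tr.pep_true[0]) <= 10.0
            assert abs(row["PAT"] - tr.pat_true[0]) <= 1000.0 / 67.0
            assert row["PTT"] == pytest.approx(row["PAT"] - row["PEP"])

    def test_hr_matches_generator_within_2pct(self, sim_table):
        _, subs, table = sim_table
        truth = {(s["subject"], st): s[f"truth_{st.lower()}"]
                 for s in subs for st in ("OFF", "ON")}
        for _, row in table.iterrows():
            tr = truth[(row["subject"], row["state"])]
            hr_true = 60_000.0 / np.mean(tr.rr_ms)
            assert row["HR"] == pytest.approx(hr_true, rel=0.02)

    def test_window_shorter_than_5min_rejected(self, sim_table):
        _, subs, _ = sim_table
        rec = preprocess_record(subs[0]["off"])
        with pytest.raises(ValueError):
            extract_window_markers(rec, (0.0, 100.0))

    def test_missing_markers_are_nan_not_zero(self):
        # record with ECG only: cardiomechanical markers must be NaN
        subs = gen_dose_response(SimConfig(n_subjects=1, seed=22))
        rec = preprocess_record(subs[0]["off"])
        for ch in ("scg_z", "ppg_ir"):
            del rec.channels[ch]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = extract_window_markers(rec, (10.0, 310.0))
        for k in ("PEP", "PAT", "PTT", "SCGamp", "PPGamp"):
            assert np.isnan(m[k])
        assert np.isfinite(m["HR"])
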