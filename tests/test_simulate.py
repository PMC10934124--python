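"""Generator ground truth, determinism, and the sensor acquisition model."""

import numpy as np
import pytest

from biopot import features as feat
from biopot import preprocess as pp
from biopot import simulate as sim
from biopot.signals import GlucoseScenario, ScenarioSpec, SensorModel, SignalTrace


class TestGenEcg:
    def test_constant_rr_puts_peaks_on_the_second(self):
        ecg = sim.gen_ecg([1000.0] * 60, fs=240.0, seed=0)
        assert ecg.meta["r_peak_times_s"].size == 60
        assert np.allclose(ecg.meta["r_peak_times_s"],
                           np.arange(1, 61, dtype=float))

    def test_ground_truth_is_cumulative_sum_of_rr(self):
        rr = [800.0, 900.0, 1000.0, 750.0, 1200.0]
        ecg = sim.gen_ecg(rr, fs=240.0, seed=0)
        # independent oracle: direct summation
        expect = np.cumsum(np.asarray(rr)) / 1000.0
        assert np.allclose(ecg.meta["r_peak_times_s"], expect)

    def test_r_amplitude_about_1mv(self, ecg_60beats):
        assert ecg_60beats.samples.max() == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("bad", [[250.0, 1000.0], [-100.0]])
    def test_short_rr_rejected(self, bad):
        with pytest.raises(ValueError, match="RR"):
            sim.gen_ecg(bad)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            sim.gen_ecg([1000.0] * 3, fs=100.0)

    def test_mean_750ms_rr_reads_80bpm_downstream(self):
        ecg = sim.gen_ecg(hr_profile={"mean_rr_ms": 750.0, "jitter_ms": 10.0,
                                      "duration_s": 120.0}, fs=240.0, seed=4)
        rr = feat.detect_r_peaks(pp.apply_filter(ecg, pp.preset("ecg")))
        rr_ms, _ = rr.gated()
        assert np.mean(60000.0 / rr_ms) == pytest.approx(80.0, abs=1.0)


class TestGenAlphaEeg:
    def test_spindle_carries_about_ten_peaks(self):
        eeg = sim.gen_alpha_eeg(10.0, f0=10.0, fs=240.0, seed=0,
                                background_uv=0.0)
        filt = pp.apply_filter(eeg, pp.preset("alpha"))
        counts = [feat.count_spindle_peaks(filt, iv[:2])
                  for iv in eeg.meta["spindles"]]
        assert all(c == 10 for c in counts)

    def test_zero_amplitude_gives_background_only(self):
        eeg = sim.gen_alpha_eeg(20.0, amp_uv=0.0, fs=240.0, seed=1)
        filt = pp.apply_filter(eeg, pp.preset("alpha"))
        # no spindle rises above the background in any marked interval
        for a, b, _ in eeg.meta["spindles"]:
            seg = filt.slice(a, b).samples
            assert np.max(np.abs(seg)) < 5 * np.std(filt.samples)

    @pytest.mark.parametrize("f0", [7.9, 13.5])
    def test_non_alpha_frequency_rejected(self, f0):
        with pytest.raises(ValueError, match=r"\[8, 13\]"):
            sim.gen_alpha_eeg(10.0, f0=f0)

    def test_fixed_seed_reproduces_exactly(self):
        a = sim.gen_alpha_eeg(15.0, seed=7)
        b = sim.gen_alpha_eeg(15.0, seed=7)
        assert np.array_equal(a.samples, b.samples)


class TestGenFrontalEeg:
    def test_blink_dominates_after_frontal_filter(self):
        eog = sim.gen_frontal_eeg(90.0, blink_times_s=[61.0], fs=240.0, seed=2)
        filt = pp.apply_filter(eog, pp.preset("frontal"))
        t_peak = filt.times[np.argmax(np.abs(filt.samples))]
        assert t_peak == pytest.approx(61.0, abs=0.25)

    def test_blink_recall_via_peak_matching(self):
        truth = [10.0, 25.0, 40.0, 55.0, 70.0]
        eog = sim.gen_frontal_eeg(80.0, blink_times_s=truth, fs=240.0, seed=3)
        filt = pp.apply_filter(eog, pp.preset("frontal"))
        # oracle: argmax of |signal| within +/-2 s of each truth time
        hits = 0
        for t in truth:
            seg = filt.slice(t - 2.0, t + 2.0)
            t_hat = seg.times[np.argmax(np.abs(seg.samples))]
            hits += abs(t_hat - t) <= 0.25
        assert hits == 5

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="closer"):
            sim.gen_frontal_eeg(30.0, blink_times_s=[10.0, 10.2])

    def test_event_outside_trace_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sim.gen_frontal_eeg(30.0, blink_times_s=[31.0])


class TestGenEmg:
    def test_three_cycles_give_three_truth_bursts(self, emg_three_bursts):
        assert len(emg_three_bursts.meta["activation_intervals"]) == 3

    def test_zero_amplitude_is_silent(self):
        emg = sim.gen_emg([(2.0, 4.0)], fs=960.0, amp_mv=0.0, seed=0)
        env = pp.emg_envelope(emg)
        assert env.meta.get("all_zero", False) or env.samples.max() < 1e-12

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sim.gen_emg([(0.0, 5.0), (4.0, 8.0)], fs=960.0)

    def test_constant_gate_plateau_matches_rectified_mean(self):
        # Monte-Carlo oracle: the envelope plateau of unit-gate EMG equals
        # the long-run mean of |carrier| * amplitude.
        amp = 0.8
        emg = sim.gen_emg([(0.0, 60.0)], fs=960.0, amp_mv=amp,
                          duration_s=60.0, seed=9)
        oracle = np.mean(np.abs(emg.samples[960 * 2:960 * 58]))
        env = pp.emg_envelope(emg, normalize_output=False)
        plateau = np.mean(env.samples[960 * 2:960 * 58])
        assert plateau == pytest.approx(oracle, rel=0.02)


class TestGenGlucose:
    def test_linear_decay_alarm_at_minute_120(self):
        scn = GlucoseScenario(decay_profile=[(0.0, 120.0), (150.0, 70.0)])
        g = sim.gen_glucose(scn)
        assert g.meta["alarmed"]
        assert g.meta["alarm_time_min"] == pytest.approx(120.0)
        assert g.fs == pytest.approx(1.0 / 60.0)

    def test_constant_profile_never_alarms(self):
        scn = GlucoseScenario(decay_profile=[(0.0, 120.0), (100.0, 120.0)])
        g = sim.gen_glucose(scn)
        assert not g.meta["alarmed"]
        assert g.meta["alarm_time_min"] is None

    def test_both_crossings_recorded(self):
        # oracle: root of each linear segment
        scn = GlucoseScenario()  # crosses 100 at 120 min, 80 at 210 min
        g = sim.gen_glucose(scn)
        assert g.meta["drift_onset_time_min"] == pytest.approx(120.0)
        assert g.meta["alarm_time_min"] == pytest.approx(210.0)


class TestComposeNight:
    def test_single_rem_block_ground_truth(self):
        scn = ScenarioSpec(duration_s=1650.0,
                           hypnogram=[("NREM", 600.0), ("REM", 1020.0),
                                      ("NREM", 0.5 * 60.0)], seed=1)
        night = sim.compose_night(scn)
        rem = [(a, b) for a, b, lab in night["hypnogram"] if lab == "REM"]
        assert rem == [(600.0, 1620.0)]
        assert night["ecg"].n == night["eog"].n == night["emg"].n

    def test_empty_hypnogram_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(duration_s=10.0, hypnogram=[])

    def test_seeded_night_reproduces_byte_identically(self):
        scn = ScenarioSpec(duration_s=300.0,
                           hypnogram=[("NREM", 180.0), ("REM", 120.0)], seed=5)
        a = sim.compose_night(scn)
        b = sim.compose_night(scn)
        for key in ("ecg", "eog", "emg"):
            assert a[key].samples.tobytes() == b[key].samples.tobytes()

    def test_nrem_mean_rr_1100_reads_below_55bpm(self):
        scn = ScenarioSpec(duration_s=1800.0, hypnogram=[("NREM", 1800.0)],
                           seed=2)
        night = sim.compose_night(scn)
        rr = feat.detect_r_peaks(pp.apply_filter(night["ecg"], pp.preset("ecg")))
        rr_ms, _ = rr.gated()
        assert np.mean(60000.0 / rr_ms) < 55.0


class TestApplySensor:
    def test_dc_1mv_maps_to_gain_counts(self):
        dc = SignalTrace(np.full(240, 1.0), fs=240.0, units="mV")
        out = sim.apply_sensor(dc, SensorModel(noise_uv_rms=0.0))
        assert out.units == "LSB"
        assert np.all(out.samples == 78)

    def test_dc_0mv_maps_to_zero(self):
        dc = SignalTrace(np.zeros(240), fs=240.0, units="mV")
        out = sim.apply_sensor(dc, SensorModel(noise_uv_rms=0.0))
        assert np.all(out.samples == 0)

    def test_overrange_clips_with_saturation_flag(self):
        dc = SignalTrace(np.full(240, 1000.0), fs=240.0, units="mV")
        out = sim.apply_sensor(dc, SensorModel(noise_uv_rms=0.0))
        # closed-form oracle: clip(round(1000 * 78), -2048, 2047)
        assert np.all(out.samples == 2047)
        assert out.meta["saturated"]

    def test_roundtrip_within_quantization_bound(self):
        m = SensorModel(noise_uv_rms=0.0)
        levels = np.linspace(-20.0, 20.0, 41)
        dc = SignalTrace(np.repeat(levels, 24), fs=240.0, units="mV")
        back = sim.lsb_to_mv(sim.apply_sensor(dc, m), m)
        assert np.max(np.abs(back.samples - dc.samples)) <= 0.5 / 78.0 + 1e-12

    def test_noise_level_close_to_specified(self):
        quiet = SignalTrace(np.zeros(240 * 60), fs=240.0, units="mV")
        out = sim.apply_sensor(quiet, SensorModel(bits=24), seed=3)
        mv = sim.lsb_to_mv(out)
        assert np.std(mv.samples) * 1000 == pytest.approx(54.0, rel=0.05)

    def test_resampling_to_odr(self):
        tr = SignalTrace(np.sin(2 * np.pi * 5 * np.arange(4800) / 480.0),
                         fs=480.0, units="mV")
        out = sim.apply_sensor(tr, SensorModel(odr_hz=240.0, noise_uv_rms=0.0))
        assert out.fs == 240.0
        assert out.n == 2400

    def test_lsb_input_rejected(self):
        tr = SignalTrace(np.zeros(10), fs=240.0, units="LSB")
        with pytest.raises(ValueError, match="mV"):
            sim.apply_sensor(tr)


def test_hg_night_scenario_times():
    traces = sim.gen_hg_night(GlucoseScenario(seed=3), seed=3)
    meta = traces["ecg"].meta
    assert meta["alarm_s"] == pytest.approx(210.0 * 60.0)
    assert meta["drift_onset_s"] == pytest.approx(120.0 * 60.0)
    assert meta["eeg_shift_s"] == pytest.approx(195.0 * 60.0)
    assert traces["glucose"].samples[0] == pytest.approx(120.0)
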