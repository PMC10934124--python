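"""Screening rules: rolling features, onset detection, REM conjunction,
and the device/gold-standard agreement report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biopot import features as feat
from biopot import preprocess as pp
from biopot import screening as scr
from biopot import simulate as sim
from biopot.signals import FeatureSeries, RRSeries, ScenarioSpec, SignalTrace


def _glucose_with_alarm(alarm_min=210.0):
    from biopot.signals import GlucoseScenario
    return sim.gen_glucose(GlucoseScenario())


def _series(values, step_s=60.0, window_s=300.0):
    starts = step_s * np.arange(len(values))
    return FeatureSeries("x", starts, starts + window_s, values)


class TestRollingFeatures:
    def test_window_count_arithmetic(self):
        ecg = sim.gen_ecg(hr_profile={"mean_rr_ms": 900.0, "jitter_ms": 20.0,
                                      "duration_s": 610.0}, fs=240.0, seed=1)
        series = scr.rolling_features({"ecg": ecg}, window_s=300.0, step_s=60.0)
        assert series["sdnn"].n_windows == 6

    def test_stationary_night_stays_near_global_mean(self):
        ecg = sim.gen_ecg(hr_profile={"mean_rr_ms": 950.0, "jitter_ms": 30.0,
                                      "duration_s": 1800.0}, fs=240.0, seed=2)
        series = scr.rolling_features({"ecg": ecg}, window_s=300.0,
                                      step_s=60.0)
        v = series["sdnn"].values
        z = np.abs(v - np.nanmean(v)) / np.nanstd(v, ddof=1)
        assert np.nanmax(z) < 3.5


class TestOnsetVsAlarm:
    def test_flat_series_has_no_onset(self):
        rng = np.random.default_rng(0)
        fs_ = _series(10.0 + 0.1 * rng.standard_normal(250))
        res = scr.onset_vs_alarm(fs_, _glucose_with_alarm())
        assert not res.detected
        assert np.isnan(res.lead_time_min)

    @pytest.mark.parametrize("lead_min", [15.0, 30.0, 60.0, 90.0])
    def test_programmed_step_recovered(self, lead_min):
        # alarm at 210 min; step injected lead_min before it
        rng = np.random.default_rng(3)
        n = 256
        starts = 60.0 * np.arange(n)
        vals = 10.0 + 0.2 * rng.standard_normal(n)
        step_t = (210.0 - lead_min) * 60.0
        vals[(starts + 150.0) >= step_t] += 5.0
        fs_ = FeatureSeries("x", starts, starts + 300.0, vals)
        res = scr.onset_vs_alarm(fs_, _glucose_with_alarm())
        assert res.detected
        assert res.lead_time_min == pytest.approx(lead_min, abs=2.0)
        assert res.post_onset_mean > res.pre_onset_mean + 3.0

    def test_reports_pre_and_post_trend_means(self):
        vals = np.concatenate([np.full(60, 1.0), np.full(60, 4.0)])
        fs_ = _series(vals, step_s=300.0, window_s=300.0)
        res = scr.onset_vs_alarm(fs_, _glucose_with_alarm(), baseline_s=6000.0)
        assert res.pre_onset_mean == pytest.approx(1.0, abs=0.01)
        assert res.post_onset_mean == pytest.approx(4.0, abs=0.01)


class TestHrBurstFlags:
    def test_constant_54bpm_all_false(self):
        times = np.cumsum([60.0 / 54.0] * 300)
        flags = scr.hr_burst_flags(RRSeries(times), epoch_s=30.0)
        assert not flags.any()

    def test_burst_epochs_flagged(self):
        # epochs alternating 54 bpm / 80 bpm regimes
        rr = ([60.0 / 54.0] * 27 + [0.75] * 40) * 4
        times = np.cumsum(rr)
        series = RRSeries(times)
        flags = scr.hr_burst_flags(series, epoch_s=30.0)
        assert flags.any()
        # oracle: per-epoch max instantaneous HR from the interval midpoints
        hr = 60000.0 / series.rr_ms
        mid = series.rr_times_s
        for e in range(flags.size):
            sel = (mid >= e * 30.0) & (mid < (e + 1) * 30.0)
            if sel.sum() >= 2 and hr[sel].max() >= 80.0:
                assert flags[e]

    def test_mean_hr_feature_series_fallback(self):
        starts = 30.0 * np.arange(4)
        fs_ = FeatureSeries("mean_hr_bpm", starts, starts + 30.0,
                            [50.0, 70.0, 50.0, 90.0])
        assert list(scr.hr_burst_flags(fs_)) == [False, True, False, True]


class TestAtoniaFlags:
    def test_zero_envelope_is_atonia_everywhere(self):
        env = SignalTrace(np.zeros(240 * 120), fs=240.0, units="normalized")
        assert scr.atonia_flags(env, epoch_s=30.0).all()

    def test_residual_tone_is_not_atonia(self):
        env = SignalTrace(np.full(240 * 120, 0.2), fs=240.0,
                          units="normalized")
        assert not scr.atonia_flags(env, epoch_s=30.0).any()

    def test_requires_normalized_envelope(self):
        env = SignalTrace(np.zeros(240 * 60), fs=240.0, units="mV")
        with pytest.raises(ValueError, match="normalized"):
            scr.atonia_flags(env)


class TestRemScreen:
    def test_all_false_gives_empty_set(self):
        n = 100
        f = np.zeros(n, bool)
        assert len(scr.rem_screen(f, f, f)) == 0

    def test_34_true_epochs_make_a_17min_episode(self):
        n = 100
        f = np.zeros(n, bool)
        f[20:54] = True
        eps = scr.rem_screen(f, f, f)
        assert len(eps) == 1
        assert eps.durations_s[0] == pytest.approx(1020.0)  # 17 min

    def test_two_blocks_17_and_15_min(self):
        n = 160
        f = np.zeros(n, bool)
        f[10:44] = True    # 34 epochs = 17 min
        f[90:120] = True   # 30 epochs = 15 min
        eps = scr.rem_screen(f, f, f)
        assert len(eps) == 2
        assert np.allclose(eps.durations_s, [1020.0, 900.0])

    def test_single_epoch_gap_is_bridged(self):
        f = np.zeros(60, bool)
        f[10:25] = True
        f[26:40] = True    # one-epoch hole
        eps = scr.rem_screen(f, f, f)
        assert len(eps) == 1

    def test_short_blips_dropped(self):
        f = np.zeros(60, bool)
        f[10:13] = True    # 90 s < 5 min minimum
        assert len(scr.rem_screen(f, f, f)) == 0

    def test_length_mismatch_named(self):
        with pytest.raises(ValueError, match="lengths differ"):
            scr.rem_screen(np.zeros(5, bool), np.zeros(6, bool),
                           np.zeros(5, bool))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.booleans(), min_size=30, max_size=90),
           st.integers(0, 89))
    def test_monotone_adding_flags_never_shrinks_coverage(self, flags, flip):
        f = np.asarray(flags, bool)
        flip = flip % f.size
        more = f.copy()
        more[flip] = True
        base = scr.rem_screen(f, f, f, min_episode_s=60.0)
        grown = scr.rem_screen(more, more, more, min_episode_s=60.0)
        assert sum(grown.durations_s) >= sum(base.durations_s)

    def test_durations_are_epoch_multiples(self):
        f = np.zeros(80, bool)
        f[5:30] = True
        eps = scr.rem_screen(f, f, f)
        assert np.allclose(eps.durations_s % 30.0, 0.0)


class TestNightRecovery:
    """End-to-end conjunction screening on simulated nights."""

    @pytest.mark.parametrize("seed", range(4))
    def test_two_rem_blocks_recovered(self, seed):
        scn = ScenarioSpec.two_rem_night(seed=seed)
        night = sim.compose_night(scn)
        n_ep = int(scn.duration_s // 30)
        rr = feat.detect_r_peaks(pp.apply_filter(night["ecg"],
                                                 pp.preset("ecg")))
        hrf = scr.hr_burst_flags(rr, n_epochs=n_ep)
        eogf = scr.eog_flags(pp.apply_filter(night["eog"],
                                             pp.preset("frontal")),
                             n_epochs=n_ep)
        atf = scr.atonia_flags(pp.emg_envelope(night["emg"]), n_epochs=n_ep)
        eps = scr.rem_screen(hrf, eogf, atf)
        truth = [(a, b) for a, b, lab in night["hypnogram"] if lab == "REM"]
        assert len(eps) == len(truth) == 2
        for (a, b, _), (ta, tb) in zip(eps, truth):
            assert abs((b - a) - (tb - ta)) <= 30.0  # within one epoch

    def test_all_nrem_night_is_empty(self):
        scn = ScenarioSpec(duration_s=1200.0, hypnogram=[("NREM", 1200.0)],
                           seed=3)
        night = sim.compose_night(scn)
        n_ep = int(scn.duration_s // 30)
        rr = feat.detect_r_peaks(pp.apply_filter(night["ecg"],
                                                 pp.preset("ecg")))
        hrf = scr.hr_burst_flags(rr, n_epochs=n_ep)
        eogf = scr.eog_flags(pp.apply_filter(night["eog"],
                                             pp.preset("frontal")),
                             n_epochs=n_ep)
        atf = scr.atonia_flags(pp.emg_envelope(night["emg"]), n_epochs=n_ep)
        assert len(scr.rem_screen(hrf, eogf, atf)) == 0


class TestDiscrepancyReport:
    def test_identical_maps_all_zero(self):
        df = scr.discrepancy_report({"a": 1.0, "b": 2.0},
                                    {"a": 1.0, "b": 2.0})
        assert np.allclose(df["discrepancy_pct"], 0.0)
        assert df.attrs["max_discrepancy_pct"] == 0.0

    def test_published_rows_reproduce_printed_percentages(self):
        df = scr.discrepancy_report({"SDNN": 149.9, "CF (Hz)": 102.13},
                                    {"SDNN": 149.1, "CF (Hz)": 102.28})
        assert round(df.loc["SDNN", "discrepancy_pct"], 1) == 0.5
        assert round(df.loc["CF (Hz)", "discrepancy_pct"], 1) == 0.1

    def test_zero_gold_gives_sentinel(self):
        df = scr.discrepancy_report({"a": 1.0}, {"a": 0.0})
        assert np.isnan(df.loc["a", "discrepancy_pct"])

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError, match="keys"):
            scr.discrepancy_report({"a": 1.0}, {"b": 1.0})
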