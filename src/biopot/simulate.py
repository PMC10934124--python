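"""Synthetic biopotential, glucose, and full-night scenario generators.

Every generator returns a :class:`~biopot.signals.SignalTrace` whose ``meta``
dict carries the construction ground truth (R-peak times, spindle and burst
intervals, event times, threshold-crossing times), so every downstream stage
can be validated without recorded data.  All randomness flows through one
``numpy.random.Generator`` seeded per call; a fixed seed reproduces the
output byte for byte.

The acquisition chain itself is modeled by :func:`apply_sensor`: additive
white front-end noise, resampling to the configured output data rate,
gain in LSB/mV, integer quantization, and clipping at the bit-depth range.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .signals import (
    EpisodeSet,
    GlucoseScenario,
    ScenarioSpec,
    SensorModel,
    SignalTrace,
)

__all__ = [
    "ECG_WAVES",
    "gen_ecg",
    "gen_alpha_eeg",
    "gen_frontal_eeg",
    "gen_emg",
    "gen_glucose",
    "compose_night",
    "gen_hg_night",
    "apply_sensor",
    "lsb_to_mv",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS pink (1/f) noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / (np.std(x) + 1e-30)


# Beat template: one Gaussian bump per wave, (amplitude rel. R, center s
# rel. R, width sigma s).  The T center is set per beat so that the
# constructed QT follows QT = qtc_s * sqrt(RR_s) with qtc_s = 0.4 s.
ECG_WAVES = {
    "P": (0.12, -0.180, 0.028),
    "Q": (-0.12, -0.035, 0.009),
    "R": (1.00, 0.000, 0.011),
    "S": (-0.18, 0.032, 0.009),
    "T": (0.30, None, 0.050),
}

# Constructed Q onset precedes the Q center by this many sigmas (the point
# where a Gaussian's descent reaches 5% of its steepest slope, the same
# convention the QT delineator uses); the constructed T end is 2 sigma past
# the T center (the tangent through the steepest downslope of a Gaussian on
# a zero baseline crosses it there).
_Q_ONSET_SIGMAS = 3.05
_T_END_SIGMAS = 2.0


def gen_ecg(rr_ms: Sequence[float] | None = None, fs: float = 240.0,
            seed=None, *, hr_profile: dict | None = None,
            r_amp_mv: float = 1.0, qtc_s: float = 0.4,
            noise_rms_mv: float = 0.0, waves: dict | None = None) -> SignalTrace:
    """Single-lead ECG with P-QRS-T morphology from an RR-interval sequence.

    Parameters
    ----------
    rr_ms : sequence of float, optional
        Successive RR intervals in ms (each >= 300).  The k-th R peak falls
        at the cumulative sum of the first k intervals, so a constant train
        ``[1000]*60`` puts peaks at exactly 1, 2, ..., 60 s.
    hr_profile : dict, optional
        Alternative to ``rr_ms``: ``{"mean_rr_ms", "jitter_ms",
        "n_beats" or "duration_s"}`` draws RR from a normal distribution
        (truncated at 300 ms).
    noise_rms_mv : float
        Additive white noise level.

    Returns
    -------
    SignalTrace
        In mV; ``meta["r_peak_times_s"]`` holds the true R times and
        ``meta["qt_ms"]`` the constructed per-beat QT.
    """
    if fs < 120:
        raise ValueError(f"fs must be >= 120 Hz, got {fs}")
    rng = _rng(seed)
    if rr_ms is None:
        if hr_profile is None:
            raise ValueError("provide rr_ms or hr_profile")
        mean = float(hr_profile["mean_rr_ms"])
        jit = float(hr_profile.get("jitter_ms", 0.0))
        if "n_beats" in hr_profile:
            n = int(hr_profile["n_beats"])
        else:
            n = int(np.ceil(float(hr_profile["duration_s"]) * 1000.0 / mean)) + 1
        rr = np.maximum(mean + jit * rng.standard_normal(n), 300.0)
    else:
        rr = np.asarray(rr_ms, dtype=float)
    if rr.size == 0:
        raise ValueError("rr_ms must contain at least one interval")
    if np.any(rr < 300.0):
        raise ValueError("all RR intervals must be >= 300 ms "
                         f"(min given: {rr.min():.1f} ms)")

    waves = dict(ECG_WAVES if waves is None else waves)
    r_times = np.cumsum(rr) / 1000.0
    duration = r_times[-1] + 0.6 * rr[-1] / 1000.0
    n_samp = int(round(duration * fs))
    x = np.zeros(n_samp)

    amp_q, c_q, s_q = waves["Q"]
    amp_t, _, s_t = waves["T"]
    q_onset_rel = c_q - _Q_ONSET_SIGMAS * s_q
    rr_s = rr / 1000.0
    qt_s = qtc_s * np.sqrt(rr_s)
    t_centers_rel = q_onset_rel + qt_s - _T_END_SIGMAS * s_t

    for k, t_r in enumerate(r_times):
        for name, (amp, center, sig) in waves.items():
            c = t_centers_rel[k] if name == "T" else center
            t_c = t_r + c
            i0 = max(0, int((t_c - 4 * sig) * fs))
            i1 = min(n_samp, int((t_c + 4 * sig) * fs) + 1)
            if i1 <= i0:
                continue
            tt = np.arange(i0, i1) / fs
            x[i0:i1] += amp * np.exp(-0.5 * ((tt - t_c) / sig) ** 2)
    x *= r_amp_mv
    if noise_rms_mv > 0:
        x = x + noise_rms_mv * rng.standard_normal(n_samp)

    meta = {
        "r_peak_times_s": r_times,
        "rr_ms": rr,
        "qt_ms": qt_s * 1000.0,
        "qtc_ms": np.full(rr.size, qtc_s * 1000.0),
    }
    return SignalTrace(x, fs=fs, label="ecg", units="mV", meta=meta)


def gen_alpha_eeg(duration_s: float, spindle_duration_s: float = 1.0,
                  gap_s: float = 1.0, f0: float = 10.0, amp_uv: float = 30.0,
                  fs: float = 240.0, seed=None, *, background_uv: float = 3.0,
                  f0_steps: Sequence[tuple] | None = None) -> SignalTrace:
    """Occipital alpha activity: fusiform spindles over pink background noise.

    Each spindle is a sinusoid at ``f0`` (8-13 Hz) under a raised-cosine
    envelope, so a 1 s spindle at 10 Hz carries about ten oscillation peaks.
    ``f0_steps`` optionally makes the spindle frequency piecewise constant,
    as ``[(start_s, f0), ...]``; each spindle uses the frequency in force at
    its start.  Output is in mV (amplitudes given in uV).
    """

    def _check_f0(f):
        if not (8.0 <= f <= 13.0):
            raise ValueError(f"alpha spindle frequency must lie in [8, 13] Hz, "
                             f"got {f}")

    if f0_steps is None:
        _check_f0(f0)
        steps = [(0.0, float(f0))]
    else:
        steps = sorted((float(t), float(f)) for t, f in f0_steps)
        for _, f in steps:
            _check_f0(f)
    if spindle_duration_s <= 0 or gap_s < 0:
        raise ValueError("spindle duration must be positive and gap >= 0")

    rng = _rng(seed)
    n = int(round(duration_s * fs))
    x = background_uv * 1e-3 * _pink_noise(n, rng)

    spindles = []
    t = gap_s
    while t + spindle_duration_s <= duration_s:
        f_here = steps[0][1]
        for ts, f in steps:
            if ts <= t:
                f_here = f
        i0 = int(round(t * fs))
        i1 = int(round((t + spindle_duration_s) * fs))
        tt = np.arange(i0, i1) / fs - t
        env = 0.5 * (1 - np.cos(2 * np.pi * tt / spindle_duration_s))
        x[i0:i1] += amp_uv * 1e-3 * env * np.sin(2 * np.pi * f_here * tt)
        spindles.append((t, t + spindle_duration_s, f_here))
        t += spindle_duration_s + gap_s

    meta = {"spindles": spindles, "f0_steps": steps}
    return SignalTrace(x, fs=fs, label="eeg_alpha", units="mV", meta=meta)


# Stereotyped eye-event transients added to the frontal channel, in seconds /
# mV: a blink is a large monophasic bump, a saccade a smaller biphasic one.
_BLINK_WIDTH_S = 0.30
_BLINK_AMP_MV = 0.200
_SACCADE_WIDTH_S = 0.20
_SACCADE_AMP_MV = 0.040
_EVENT_MIN_GAP_S = 0.5


def gen_frontal_eeg(duration_s: float, blink_times_s: Sequence[float] = (),
                    saccade_times_s: Sequence[float] = (), fs: float = 240.0,
                    seed=None, *, background_uv: float = 8.0) -> SignalTrace:
    """Frontal channel: slow background with blink/eye-movement transients.

    Event times must lie inside the trace and be separated by at least
    0.5 s (the transient width); overlapping events are rejected.
    """
    blink = sorted(float(t) for t in blink_times_s)
    sacc = sorted(float(t) for t in saccade_times_s)
    events = sorted([(t, "blink") for t in blink] + [(t, "saccade") for t in sacc])
    for t, _ in events:
        if not (0.0 <= t <= duration_s):
            raise ValueError(f"event time {t} s outside trace of {duration_s} s")
    for (t0, _), (t1, _) in zip(events, events[1:]):
        if t1 - t0 < _EVENT_MIN_GAP_S:
            raise ValueError(f"events at {t0} s and {t1} s closer than the "
                             f"{_EVENT_MIN_GAP_S} s transient width")

    rng = _rng(seed)
    n = int(round(duration_s * fs))
    x = background_uv * 1e-3 * _pink_noise(n, rng)
    t_axis = np.arange(n) / fs

    for t, kind in events:
        if kind == "blink":
            sig = _BLINK_WIDTH_S / 4.0
            i0 = max(0, int((t - 3 * sig) * fs))
            i1 = min(n, int((t + 3 * sig) * fs) + 1)
            tt = t_axis[i0:i1]
            x[i0:i1] += _BLINK_AMP_MV * np.exp(-0.5 * ((tt - t) / sig) ** 2)
        else:
            sig = _SACCADE_WIDTH_S / 4.0
            i0 = max(0, int((t - 4 * sig) * fs))
            i1 = min(n, int((t + 4 * sig) * fs) + 1)
            tt = t_axis[i0:i1]
            x[i0:i1] += (-_SACCADE_AMP_MV * (tt - t) / sig
                         * np.exp(-0.5 * ((tt - t) / sig) ** 2))

    meta = {"blink_times_s": blink, "saccade_times_s": sacc}
    return SignalTrace(x, fs=fs, label="eog_frontal", units="mV", meta=meta)


def _band_noise(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + int(fs)))[int(fs):]
    return x / (np.std(x) + 1e-30)


def _smooth_gate(n: int, fs: float, intervals, ramp_s: float = 0.1,
                 levels=None) -> np.ndarray:
    """0/1 (or leveled) gate from intervals, with raised-cosine ramps."""
    g = np.zeros(n)
    for i, (a, b) in enumerate(intervals):
        lev = 1.0 if levels is None else levels[i]
        i0, i1 = int(round(a * fs)), min(n, int(round(b * fs)))
        g[i0:i1] = np.maximum(g[i0:i1], lev)
    if ramp_s > 0:
        w = int(round(ramp_s * fs))
        if w >= 2:
            win = np.hanning(2 * w + 1)
            win /= win.sum()
            g = np.convolve(g, win, mode="same")
    return g


def gen_emg(schedule: Sequence[tuple], fs: float = 1000.0,
            amp_mv: float = 0.5, seed=None, *, duration_s: float | None = None,
            band=(10.0, 250.0), tone_mv: float = 0.0) -> SignalTrace:
    """Surface EMG: band-limited Gaussian noise under an on/off gate.

    ``schedule`` lists contraction intervals ``(on_s, off_s)``; intervals may
    not overlap.  The carrier is 10-250 Hz noise (truncated at 0.45 * fs when
    the rate cannot carry the full band), scaled so the contraction RMS is
    ``amp_mv``; ``tone_mv`` adds a constant baseline tone outside bursts.
    """
    sched = sorted((float(a), float(b)) for a, b in schedule)
    for a, b in sched:
        if b <= a:
            raise ValueError(f"schedule interval ({a}, {b}) has end <= start")
    for (_, b0), (a1, _) in zip(sched, sched[1:]):
        if a1 < b0:
            raise ValueError("schedule intervals overlap")
    if duration_s is None:
        duration_s = (sched[-1][1] + 1.0) if sched else 10.0
    rng = _rng(seed)
    n = int(round(duration_s * fs))
    carrier = _band_noise(n, fs, band[0], band[1], rng)
    gate = _smooth_gate(n, fs, sched)
    level = tone_mv + (amp_mv - tone_mv) * gate if tone_mv else amp_mv * gate
    x = carrier * level
    meta = {"activation_intervals": sched, "band_hz": (band[0], min(band[1], 0.45 * fs))}
    return SignalTrace(x, fs=fs, label="emg", units="mV", meta=meta)


def _profile_crossings(profile, threshold: float) -> list:
    """Downward crossing times (min) of a piecewise-linear profile."""
    out = []
    for (t0, v0), (t1, v1) in zip(profile, profile[1:]):
        if v0 >= threshold > v1:
            out.append(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0))
    return out


def gen_glucose(scn: GlucoseScenario) -> SignalTrace:
    """Interstitial glucose at one sample per minute from a decay profile.

    ``meta["alarm_time_min"]`` is the first crossing below the alarm
    threshold (analysis t = 0); ``meta["alarmed"]`` is False when the
    profile never crosses.  The drift-onset crossing (default 100 mg/dL)
    is recorded alongside.
    """
    minutes = np.arange(0.0, scn.duration_min + 0.5, 1.0)
    tp = [t for t, _ in scn.decay_profile]
    vp = [v for _, v in scn.decay_profile]
    g = np.interp(minutes, tp, vp)
    if scn.noise_mgdl > 0:
        g = g + scn.noise_mgdl * _rng(scn.seed).standard_normal(g.size)
    alarms = _profile_crossings(scn.decay_profile, scn.alarm_threshold_mgdl)
    drifts = _profile_crossings(scn.decay_profile, scn.ecg_drift_onset_glucose)
    meta = {
        "alarmed": bool(alarms),
        "alarm_time_min": alarms[0] if alarms else None,
        "alarm_threshold_mgdl": scn.alarm_threshold_mgdl,
        "drift_onset_time_min": drifts[0] if drifts else None,
        "crossings_min": {scn.alarm_threshold_mgdl: alarms,
                          scn.ecg_drift_onset_glucose: drifts},
    }
    return SignalTrace(g, fs=1.0 / 60.0, label="glucose", units="mg/dL", meta=meta)


def _rem_rr_sequence(duration_s: float, profile: dict, burst: dict,
                     rng: np.random.Generator) -> np.ndarray:
    """RR sequence (ms) for a REM block: baseline with bursts to the RR floor.

    Cycle layout (defaults): ramp down over ramp_s, hold at min_rr_ms for
    hold_s, ramp up, then baseline for the rest of cycle_s.  The hold is
    longer than one 30 s scoring epoch so an epoch of heart rate at the
    floor (80 bpm for a 750 ms floor) is guaranteed.
    """
    base = profile["mean_rr_ms"]
    jit = profile["jitter_ms"]
    floor = burst["min_rr_ms"]
    cyc, hold, ramp = burst["cycle_s"], burst["hold_s"], burst["ramp_s"]
    rr, t = [], 0.0
    while t < duration_s:
        ph = t % cyc
        if ph < ramp:
            mean = base + (floor - base) * ph / ramp
            j = jit * 0.3
        elif ph < ramp + hold:
            mean, j = floor, 3.0
        elif ph < 2 * ramp + hold:
            mean = floor + (base - floor) * (ph - ramp - hold) / ramp
            j = jit * 0.3
        else:
            mean, j = base, jit
        val = max(mean + j * rng.standard_normal(), 300.0)
        if ph < ramp + hold:            # never undershoot the programmed floor
            val = max(val, floor - 3.0 * 2)
        rr.append(val)
        t += val / 1000.0
    return np.asarray(rr)


def _stage_rr_sequence(scn: ScenarioSpec, rng: np.random.Generator):
    """Concatenated RR sequence across the hypnogram; returns (rr_ms, stages)."""
    rr_all, stage_of_beat = [], []
    for stage, dur in scn.hypnogram:
        prof = scn.hr_profile[stage]
        if stage == "REM":
            rr = _rem_rr_sequence(dur, prof, scn.burst_spec, rng)
        else:
            rr, t = [], 0.0
            while t < dur:
                val = max(prof["mean_rr_ms"]
                          + prof["jitter_ms"] * rng.standard_normal(), 300.0)
                rr.append(val)
                t += val / 1000.0
            rr = np.asarray(rr)
        rr_all.append(rr)
        stage_of_beat.extend([stage] * rr.size)
    return np.concatenate(rr_all), stage_of_beat


def compose_night(scn: ScenarioSpec, fs: float = 240.0) -> dict:
    """Simulate a hypnogram-driven night: ECG, EOG, and masseter sEMG.

    Stage-conditional structure: REM shows heart-rate bursts, dense eye
    events, and EMG atonia simultaneously; NREM a low steady heart rate,
    near-zero eye activity, and a residual constant muscle tone.

    Returns a dict with keys ``"ecg"``, ``"eog"``, ``"emg"`` (SignalTrace,
    mV) and ``"hypnogram"`` (ground-truth EpisodeSet).
    """
    rng = _rng(scn.seed)
    hypnogram = scn.stage_intervals()

    rr, _ = _stage_rr_sequence(scn, rng)
    ecg = gen_ecg(rr, fs=fs, seed=rng.integers(2**31))
    # Trim/pad to the scheduled duration so the three channels align.
    n = int(round(scn.duration_s * fs))
    ecg = _fit_length(ecg, n)

    # Eye events: Poisson per stage at the configured rate, thinned to the
    # generator's minimum separation.
    events = []
    for a, b, stage in hypnogram:
        rate = scn.eog_rate[stage] / 60.0
        n_ev = rng.poisson(rate * (b - a))
        events.extend(np.sort(rng.uniform(a, b, n_ev)))
    events = np.sort(np.asarray(events))
    kept, last = [], -np.inf
    for t in events:
        if t - last >= _EVENT_MIN_GAP_S:
            kept.append(t)
            last = t
    eog = gen_frontal_eeg(scn.duration_s, blink_times_s=kept, fs=fs,
                          seed=rng.integers(2**31))
    eog = _fit_length(eog, n)

    # Muscle tone: stage-leveled gate over a 10-Nyquist carrier.
    carrier = _band_noise(n, fs, 10.0, 250.0, rng)
    intervals = [(a, b) for a, b, _ in hypnogram]
    levels = [scn.emg_tone[s] for _, _, s in hypnogram]
    gate = _smooth_gate(n, fs, intervals, ramp_s=0.2, levels=levels)
    amp_mv = 0.5
    emg = SignalTrace(carrier * gate * amp_mv, fs=fs, label="emg_masseter",
                      units="mV",
                      meta={"tone_levels": dict(zip([s for _, _, s in hypnogram],
                                                    levels)),
                            "stage_intervals": list(hypnogram)})
    emg = _fit_length(emg, n)

    ecg.meta["hypnogram"] = list(hypnogram)
    eog.meta["event_times_s"] = kept
    return {"ecg": ecg, "eog": eog, "emg": emg, "hypnogram": hypnogram}


def _fit_length(trace: SignalTrace, n: int) -> SignalTrace:
    x = trace.samples
    if x.size >= n:
        x = x[:n]
    else:
        x = np.concatenate([x, np.zeros(n - x.size)])
    return trace.copy_with(samples=x, meta=dict(trace.meta))


def gen_hg_night(scn: GlucoseScenario, fs: float = 240.0, seed=None) -> dict:
    """Simulate the hypoglycemia-night scenario: ECG + alpha EEG + glucose.

    The ECG's beat-to-beat variability and its low-frequency (0.1 Hz)
    autonomic modulation step up when glucose falls below the drift-onset
    level (default 100 mg/dL), emulating the slow sympathoadrenal response;
    the alpha spindle frequency steps up ``eeg_shift_lead_min`` minutes
    before the alarm crossing, emulating the sudden late EEG change.

    Returns ``{"ecg", "eeg", "glucose"}`` plus scenario times in
    ``meta``: ``alarm_s``, ``drift_onset_s``, ``eeg_shift_s``.
    """
    rng = _rng(scn.seed if seed is None else seed)
    glucose = gen_glucose(scn)
    if not glucose.meta["alarmed"]:
        raise ValueError("scenario profile never crosses the alarm threshold")
    alarm_s = glucose.meta["alarm_time_min"] * 60.0
    drift_s = (glucose.meta["drift_onset_time_min"] or 0.0) * 60.0
    shift_s = alarm_s - scn.eeg_shift_lead_min * 60.0
    duration_s = scn.duration_min * 60.0

    # RR sequence: mean 950 ms; deterministic LF (0.1 Hz) and HF (0.25 Hz)
    # modulation dominating their bands, plus white jitter.  Post-drift the
    # LF amplitude and the jitter step up (sympathoadrenal response).
    mean_rr, hf_amp = 950.0, 25.0
    lf_amp = (20.0, 70.0)
    jitter = (15.0, 40.0)
    rr, t = [], 0.0
    while t < duration_s:
        post = int(t >= drift_s)
        val = (mean_rr
               + lf_amp[post] * np.sin(2 * np.pi * 0.10 * t)
               + hf_amp * np.sin(2 * np.pi * 0.25 * t)
               + jitter[post] * rng.standard_normal())
        val = max(val, 400.0)
        rr.append(val)
        t += val / 1000.0
    ecg = gen_ecg(np.asarray(rr), fs=fs, seed=rng.integers(2**31))
    ecg = _fit_length(ecg, int(round(duration_s * fs)))

    eeg = gen_alpha_eeg(duration_s, fs=fs, seed=rng.integers(2**31),
                        f0_steps=[(0.0, 10.0), (shift_s, 12.0)])

    for tr in (ecg, eeg, glucose):
        tr.meta.update(alarm_s=alarm_s, drift_onset_s=drift_s, eeg_shift_s=shift_s)
    return {"ecg": ecg, "eeg": eeg, "glucose": glucose}


def apply_sensor(trace: SignalTrace, m: SensorModel | None = None,
                 seed=None) -> SignalTrace:
    """Pass a physical (mV) trace through the modeled acquisition chain.

    Steps: add white Gaussian front-end noise (``noise_uv_rms``), resample to
    the output data rate, multiply by the gain (LSB/mV), round to integer
    counts, and clip to the signed bit-depth range.  Saturation does not
    raise; it clips and sets ``meta["saturated"] = True``.
    """
    m = m or SensorModel()
    if trace.units != "mV":
        raise ValueError(f"apply_sensor expects a mV trace, got units "
                         f"{trace.units!r}")
    rng = _rng(seed)
    x = trace.samples.astype(float)
    if m.noise_uv_rms > 0:
        x = x + (m.noise_uv_rms * 1e-3) * rng.standard_normal(x.size)
    fs = trace.fs
    if abs(m.odr_hz - fs) > 1e-9:
        frac = Fraction(m.odr_hz / fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
        fs = m.odr_hz
    counts = np.rint(x * m.gain_lsb_per_mv)
    saturated = bool(np.any(counts < m.lsb_min) or np.any(counts > m.lsb_max))
    counts = np.clip(counts, m.lsb_min, m.lsb_max).astype(np.int32)
    meta = dict(trace.meta)
    meta.update(saturated=saturated, sensor=m)
    return SignalTrace(counts, fs=fs, t0=trace.t0, label=trace.label,
                       units="LSB", meta=meta)


def lsb_to_mv(trace: SignalTrace, m: SensorModel | None = None) -> SignalTrace:
    """Invert the sensor gain: LSB counts back to millivolts."""
    m = m or trace.meta.get("sensor") or SensorModel()
    if trace.units != "LSB":
        raise ValueError(f"lsb_to_mv expects an LSB trace, got {trace.units!r}")
    x = trace.samples.astype(float) / m.gain_lsb_per_mv
    return SignalTrace(x, fs=trace.fs, t0=trace.t0, label=trace.label,
                       units="mV", meta=dict(trace.meta))
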