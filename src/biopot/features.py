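"""Feature extraction: R peaks, HR, QT/QTc, HRV statistics, spectral moments,
EMG activations, and EOG activity flags.

Undefined values (too few beats, zero in-band power, zero high-frequency
power) are reported as NaN sentinels, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .signals import EpisodeSet, FeatureSeries, RRSeries, SignalTrace

__all__ = [
    "detect_r_peaks", "heart_rate", "sdnn", "rmssd", "lf_hf", "HRVMetrics",
    "qt_measure", "QTMeasure", "spectrum_moments", "moments_from_spectrum",
    "SpectrumMoments", "emg_activations", "eog_activity",
    "count_spindle_peaks",
]

# Physiologic RR gate (ms) applied before variability statistics.
RR_GATE_MS = (300.0, 2000.0)


def _rr_array(rr) -> np.ndarray:
    """Accept an RRSeries or a plain interval list (ms), with gating."""
    if isinstance(rr, RRSeries):
        vals, _ = rr.gated(*RR_GATE_MS)
        return vals
    return np.asarray(rr, dtype=float)


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(trace: SignalTrace, refractory_s: float = 0.2,
                   threshold_frac: float = 0.25) -> RRSeries:
    """QRS detection by derivative -> squaring -> moving-window integration.

    The classic energy-transform chain: the band-limited input (use the ECG
    preset first) is differentiated, squared, and integrated over a 150 ms
    window; peaks of the integrated energy separated by the 200 ms
    physiological refractory period and exceeding an adaptive threshold
    (a fraction of the upper-percentile energy) mark beats.  Each beat is
    then snapped to the local maximum of the input within +/-100 ms, so
    every returned peak is a true local maximum of the trace.

    A flatline input yields an empty series with ``meta["flatline"]``.
    """
    x = trace.samples.astype(float)
    fs = trace.fs
    if fs < 120:
        raise ValueError(f"detect_r_peaks needs fs >= 120 Hz, got {fs}")
    if np.ptp(x) < 1e-12:
        return RRSeries(np.empty(0), meta={"flatline": True})

    deriv = np.gradient(x) * fs
    energy = deriv ** 2
    win = max(3, int(round(0.150 * fs)))
    integ = uniform_filter1d(energy, size=win)

    height = threshold_frac * np.percentile(integ, 99)
    distance = max(1, int(round(refractory_s * fs)))
    locs, _ = sps.find_peaks(integ, height=height, distance=distance)
    if locs.size == 0:
        return RRSeries(np.empty(0), meta={"n_candidates": 0})

    # Snap to the R maximum of the raw input.
    half = int(round(0.100 * fs))
    peaks = []
    for i in locs:
        a, b = max(0, i - half), min(x.size, i + half + 1)
        peaks.append(a + int(np.argmax(x[a:b])))
    peaks = np.unique(peaks)
    # Enforce the refractory period after snapping (keep the larger peak).
    kept = [peaks[0]]
    for p in peaks[1:]:
        if (p - kept[-1]) / fs < refractory_s:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    times = trace.t0 + np.asarray(kept) / fs
    return RRSeries(times, meta={"n_candidates": locs.size})


# ---------------------------------------------------------------------------
# Heart rate and time-domain HRV
# ---------------------------------------------------------------------------

def heart_rate(rr: RRSeries, window_s: float, step_s: float | None = None,
               t_start: float | None = None,
               t_end: float | None = None) -> FeatureSeries:
    """Windowed mean heart rate, HR = 60000 / RR(ms), in bpm.

    Each RR interval is stamped at the midpoint of its two beats; a window
    averages the instantaneous HR of the intervals it contains and reports
    NaN when it holds fewer than one interval (i.e. < 2 peaks).
    """
    if rr.n_beats < 2:
        return FeatureSeries("mean_hr_bpm", np.empty(0), np.empty(0), np.empty(0))
    step_s = window_s if step_s is None else step_s
    rr_ms, rr_t = rr.gated(*RR_GATE_MS)
    hr = 60000.0 / rr_ms
    t0 = rr.peak_times_s[0] if t_start is None else t_start
    t1 = rr.peak_times_s[-1] if t_end is None else t_end
    starts, ends, vals, sds, maxs = [], [], [], [], []
    a = t0
    while a + window_s <= t1 + 1e-9:
        b = a + window_s
        m = (rr_t >= a) & (rr_t < b)
        starts.append(a)
        ends.append(b)
        if m.sum() >= 1:
            vals.append(float(np.mean(hr[m])))
            sds.append(float(np.std(hr[m], ddof=1)) if m.sum() >= 2 else 0.0)
            maxs.append(float(np.max(hr[m])))
        else:
            vals.append(np.nan)
            sds.append(np.nan)
            maxs.append(np.nan)
        a += step_s
    return FeatureSeries("mean_hr_bpm", starts, ends, vals,
                         meta={"hr_sd_bpm": np.asarray(sds),
                               "hr_max_bpm": np.asarray(maxs)})


def sdnn(rr) -> float:
    """Standard deviation of normal-to-normal intervals, ms (sample SD)."""
    vals = _rr_array(rr)
    if vals.size < 2:
        return float("nan")
    return float(np.std(vals, ddof=1))


def rmssd(rr) -> float:
    """Root-mean-square of successive RR differences, ms."""
    vals = _rr_array(rr)
    if vals.size < 3:
        return float("nan")
    d = np.diff(vals)
    return float(np.sqrt(np.mean(d ** 2)))


# ---------------------------------------------------------------------------
# Frequency-domain HRV
# ---------------------------------------------------------------------------

@dataclass
class HRVMetrics:
    sdnn_ms: float
    rmssd_ms: float
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    mean_hr_bpm: float


# Task-Force convention: LF 0.04-0.15 Hz, HF 0.15-0.40 Hz, tachogram
# resampled at 4 Hz.
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TACHO_FS = 4.0


def lf_hf(rr: RRSeries, lf_band=LF_BAND, hf_band=HF_BAND,
          fs_interp: float = TACHO_FS) -> HRVMetrics:
    """Low/high-frequency power ratio of the RR tachogram spectrum.

    The (gated) tachogram is linearly interpolated onto a uniform 4 Hz grid,
    mean-detrended, and Welch-averaged; LF and HF are trapezoid-integrated
    band powers.  Requires at least 2 min of beats; zero HF power gives a
    NaN ratio sentinel.
    """
    rr_ms, rr_t = rr.gated(*RR_GATE_MS)
    if rr_ms.size < 2 or rr_t[-1] - rr_t[0] < 120.0:
        raise ValueError("lf_hf needs at least 2 min of beats")
    grid = np.arange(rr_t[0], rr_t[-1], 1.0 / fs_interp)
    tach = np.interp(grid, rr_t, rr_ms)
    tach = tach - tach.mean()
    nperseg = min(tach.size, int(120 * fs_interp))
    f, p = sps.welch(tach, fs=fs_interp, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant")
    lf = float(np.trapezoid(p[(f >= lf_band[0]) & (f < lf_band[1])],
                            f[(f >= lf_band[0]) & (f < lf_band[1])]))
    hf = float(np.trapezoid(p[(f >= hf_band[0]) & (f <= hf_band[1])],
                            f[(f >= hf_band[0]) & (f <= hf_band[1])]))
    total = float(np.trapezoid(p, f))
    # Degenerate (constant RR) spectra carry no physiologic power at all.
    if total <= 0 or hf <= 1e-12 * max(total, 1.0):
        ratio = float("nan")
    else:
        ratio = lf / hf
    return HRVMetrics(sdnn_ms=sdnn(rr), rmssd_ms=rmssd(rr), lf_power=lf,
                      hf_power=hf, lf_hf_ratio=ratio,
                      mean_hr_bpm=float(np.mean(60000.0 / rr_ms)))


# ---------------------------------------------------------------------------
# QT interval
# ---------------------------------------------------------------------------

@dataclass
class QTMeasure:
    r_time_s: float
    qt_ms: float
    rr_ms: float
    qtc_ms: float


def qtc_bazett(qt_ms: float, rr_ms: float) -> float:
    """QTc = QT / sqrt(RR) with RR in seconds."""
    return qt_ms / np.sqrt(rr_ms / 1000.0)


def qt_measure(trace: SignalTrace, rr: RRSeries,
               baseline: float = 0.0) -> list[QTMeasure]:
    """Per-beat QT and rate-corrected QTc (QT / sqrt(RR_s)).

    Q onset: within the 80 ms before each R peak, the start of the steepest
    descent into the Q wave (walk back from the maximum downslope until the
    slope falls below 5% of it).  T end: tangent method — the line through
    the steepest point of the T-wave downslope, extrapolated to the
    baseline.  Beats without a detectable T wave are skipped and counted in
    the result list's absence.
    """
    x = trace.samples.astype(float)
    fs = trace.fs
    t = rr.peak_times_s - trace.t0
    out: list[QTMeasure] = []
    for k in range(rr.n_beats - 1):
        rr_s = t[k + 1] - t[k]
        rr_ms_k = rr_s * 1000.0
        i_r = int(round(t[k] * fs))
        # --- Q onset ---
        a = max(0, i_r - int(round(0.080 * fs)))
        seg = x[a:i_r + 1]
        if seg.size < 3:
            continue
        d = np.gradient(seg) * fs
        i_min = int(np.argmin(d))
        if d[i_min] >= 0:
            continue
        thr = 0.05 * abs(d[i_min])
        j = i_min
        while j > 0 and abs(d[j]) > thr:
            j -= 1
        q_onset = (a + j) / fs
        # --- T end (tangent method) ---
        b0 = i_r + int(round(0.100 * fs))
        b1 = min(x.size, i_r + int(round(min(0.6 * rr_s, 0.55) * fs)))
        if b1 - b0 < 5:
            continue
        i_t = b0 + int(np.argmax(x[b0:b1]))
        if x[i_t] - baseline < 0.05 * (np.max(x[i_r:i_r + 2]) - baseline):
            continue  # T wave too small to delineate
        c1 = min(x.size, i_t + int(round(0.20 * fs)))
        if c1 - i_t < 3:
            continue
        dd = np.gradient(x[i_t:c1]) * fs
        i_s = i_t + int(np.argmin(dd))
        slope = dd[i_s - i_t]
        if slope >= 0:
            continue
        t_end = i_s / fs + (baseline - x[i_s]) / slope
        qt_ms_k = (t_end - q_onset) * 1000.0
        if not (0 < qt_ms_k < rr_ms_k):
            continue
        out.append(QTMeasure(r_time_s=trace.t0 + t[k], qt_ms=qt_ms_k,
                             rr_ms=rr_ms_k,
                             qtc_ms=float(qtc_bazett(qt_ms_k, rr_ms_k))))
    return out


# ---------------------------------------------------------------------------
# Spectral moments
# ---------------------------------------------------------------------------

@dataclass
class SpectrumMoments:
    freqs: np.ndarray
    power: np.ndarray
    G: tuple
    cf_hz: float
    radius_hz: float


def moments_from_spectrum(freqs: Sequence[float], power: Sequence[float],
                          n_moments: int = 5) -> SpectrumMoments:
    """Spectral moments Gn = integral f^n P(f) df, with CF and radius.

    Centroid frequency CF = G1/G0; rotational radius = sqrt(G2/G0), the RMS
    frequency of the spectral mass.  Zero total power yields NaN sentinels.
    """
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(power, dtype=float)
    if f.size != p.size or f.size < 2:
        raise ValueError("freqs and power must be equal-length, size >= 2")
    G = tuple(float(np.trapezoid(p * f ** n, f)) for n in range(n_moments))
    if G[0] <= 0:
        return SpectrumMoments(f, p, G, float("nan"), float("nan"))
    cf = G[1] / G[0]
    radius = float(np.sqrt(G[2] / G[0]))
    return SpectrumMoments(f, p, G, cf, radius)


def spectrum_moments(trace: SignalTrace, band: tuple,
                     nperseg_s: float = 4.0) -> SpectrumMoments:
    """Welch spectrum restricted to ``band`` and its moments (Hann, 50%)."""
    if trace.duration_s < 10.0:
        raise ValueError("spectrum_moments needs a trace of >= 10 s")
    nperseg = min(trace.n, int(round(nperseg_s * trace.fs)))
    f, p = sps.welch(trace.samples.astype(float), fs=trace.fs, window="hann",
                     nperseg=nperseg, noverlap=nperseg // 2)
    m = (f >= band[0]) & (f <= band[1])
    if m.sum() < 2:
        raise ValueError(f"band {band} contains fewer than two spectral bins")
    return moments_from_spectrum(f[m], p[m])


def count_spindle_peaks(trace: SignalTrace, interval: tuple | None = None,
                        frac: float = 0.5, floor_frac: float = 0.01) -> int:
    """Count oscillation peaks in a spindle: local maxima above ``frac`` of
    the local (Hilbert) envelope and above ``floor_frac`` of the maximum."""
    x = trace.samples.astype(float)
    if interval is not None:
        i0 = int(round((interval[0] - trace.t0) * trace.fs))
        i1 = int(round((interval[1] - trace.t0) * trace.fs))
        x = x[max(0, i0):i1]
    env = np.abs(sps.hilbert(x))
    locs, _ = sps.find_peaks(x)
    floor = floor_frac * np.max(np.abs(x)) if x.size else 0.0
    return int(np.sum((x[locs] > frac * env[locs]) & (x[locs] > floor)))


# ---------------------------------------------------------------------------
# EMG activations and EOG activity
# ---------------------------------------------------------------------------

def emg_activations(env: SignalTrace, on_frac: float = 0.2,
                    off_frac: float = 0.1,
                    min_duration_s: float = 0.5) -> EpisodeSet:
    """Burst detection on a normalized envelope by hysteresis thresholding.

    A burst opens when the envelope rises above ``on_frac`` of its maximum
    and closes when it falls below ``off_frac``; bursts shorter than
    ``min_duration_s`` are discarded.
    """
    x = env.samples.astype(float)
    peak = float(np.max(x)) if x.size else 0.0
    if peak <= 0:
        return EpisodeSet([], source="emg_activations")
    on_thr, off_thr = on_frac * peak, off_frac * peak
    fs = env.fs
    intervals = []
    state, start = False, 0
    for i, v in enumerate(x):
        if not state and v >= on_thr:
            state, start = True, i
        elif state and v < off_thr:
            state = False
            if (i - start) / fs >= min_duration_s:
                intervals.append((env.t0 + start / fs, env.t0 + i / fs,
                                  "activation"))
    if state and (x.size - start) / fs >= min_duration_s:
        intervals.append((env.t0 + start / fs, env.t0 + x.size / fs,
                          "activation"))
    return EpisodeSet(intervals, source="emg_activations")


def eog_activity(trace: SignalTrace, epoch_s: float, k: float = 3.0,
                 baseline_quantile: float = 0.25) -> FeatureSeries:
    """Per-epoch eye-activity flags from RMS against a baseline quantile.

    An epoch is flagged active when its RMS exceeds ``k`` times the
    ``baseline_quantile`` of all epoch RMS values (the quiet-background
    level).  Values are 1.0 (active) / 0.0; epoch RMS is kept in
    ``meta["rms"]``.
    """
    if epoch_s > trace.duration_s:
        raise ValueError(f"epoch ({epoch_s} s) longer than trace "
                         f"({trace.duration_s:.1f} s)")
    spe = int(round(epoch_s * trace.fs))
    n_ep = trace.n // spe
    segs = trace.samples[: n_ep * spe].reshape(n_ep, spe).astype(float)
    rms = np.sqrt(np.mean(segs ** 2, axis=1))
    baseline = float(np.quantile(rms, baseline_quantile)) + 1e-30
    flags = (rms > k * baseline).astype(float)
    starts = trace.t0 + epoch_s * np.arange(n_ep)
    return FeatureSeries("eog_activity", starts, starts + epoch_s, flags,
                         meta={"rms": rms, "baseline_rms": baseline})
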