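"""Clinical screening procedures.

Two rule-based procedures built on the rolling feature series:

* **Pre-hypoglycemia trend onset** — rolling ECG (SDNN, RMSSD, LF:HF, mean
  HR) and alpha-EEG (centroid frequency) parameters are screened for the
  first sustained departure from their early-night baseline, and the
  departure time is reported as a lead time in minutes before the glucose
  alarm crossing.

* **REM epoch screening** — an epoch is a REM candidate only when three
  conditions coincide: heart-rate burst variability, eye activity on the
  frontal channel, and masseter atonia.  Candidate epochs are merged across
  short gaps and episodes below a minimum duration are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from .signals import EpisodeSet, FeatureSeries, RRSeries, SignalTrace

__all__ = [
    "rolling_features", "onset_vs_alarm", "OnsetResult", "rem_screen",
    "hr_burst_flags", "atonia_flags", "eog_flags", "discrepancy_report",
    "alarm_crossing_time_s",
]

EPOCH_S = 30.0  # sleep-medicine scoring convention


# ---------------------------------------------------------------------------
# Rolling features
# ---------------------------------------------------------------------------

def _window_grid(duration_s: float, window_s: float, step_s: float):
    n = int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1
    if n < 1:
        raise ValueError("trace shorter than one analysis window")
    starts = step_s * np.arange(n)
    return starts, starts + window_s


def rolling_features(traces: Mapping[str, SignalTrace], window_s: float = 300.0,
                     step_s: float = 60.0,
                     alpha_band: tuple = (8.0, 13.0)) -> dict:
    """Per-window feature series for ECG and/or alpha-EEG traces.

    ``traces`` maps ``"ecg"`` and/or ``"eeg"`` to SignalTraces (the ECG is
    band-passed with the ECG preset internally before peak detection).
    Returns a dict of FeatureSeries keyed ``sdnn``, ``rmssd``, ``lf_hf``,
    ``mean_hr`` (from ECG) and ``cf`` (from EEG).  Windows with fewer than
    two beats keep their slot with a NaN sentinel.
    """
    from .preprocess import apply_filter, preset

    out: dict[str, FeatureSeries] = {}
    if "ecg" in traces:
        ecg = traces["ecg"]
        filtered = apply_filter(ecg, preset("ecg"))
        rr = feat.detect_r_peaks(filtered)
        starts, ends = _window_grid(ecg.duration_s, window_s, step_s)
        cols = {"sdnn": [], "rmssd": [], "lf_hf": [], "mean_hr": []}
        for a, b in zip(starts, ends):
            sub = rr.window(ecg.t0 + a, ecg.t0 + b)
            if sub.n_beats < 2:
                for c in cols.values():
                    c.append(np.nan)
                continue
            cols["sdnn"].append(feat.sdnn(sub))
            cols["rmssd"].append(feat.rmssd(sub))
            rr_ms, _ = sub.gated()
            cols["mean_hr"].append(float(np.mean(60000.0 / rr_ms))
                                   if rr_ms.size else np.nan)
            try:
                cols["lf_hf"].append(feat.lf_hf(sub).lf_hf_ratio)
            except ValueError:
                cols["lf_hf"].append(np.nan)
        for name, vals in cols.items():
            out[name] = FeatureSeries(name, starts, ends, vals)
    if "eeg" in traces:
        eeg = traces["eeg"]
        starts, ends = _window_grid(eeg.duration_s, window_s, step_s)
        vals = []
        for a, b in zip(starts, ends):
            seg = eeg.slice(eeg.t0 + a, eeg.t0 + b)
            try:
                vals.append(feat.spectrum_moments(seg, alpha_band).cf_hz)
            except ValueError:
                vals.append(np.nan)
        out["cf"] = FeatureSeries("cf", starts, ends, vals)
    return out


# ---------------------------------------------------------------------------
# Hypoglycemia trend onset
# ---------------------------------------------------------------------------

@dataclass
class OnsetResult:
    detected: bool
    onset_time_s: float
    lead_time_min: float
    baseline_mean: float
    baseline_sd: float
    pre_onset_mean: float
    post_onset_mean: float

    def __repr__(self) -> str:  # compact, for reports
        if not self.detected:
            return "OnsetResult(no onset)"
        return (f"OnsetResult(lead={self.lead_time_min:.1f} min, "
                f"pre={self.pre_onset_mean:.3g}, post={self.post_onset_mean:.3g})")


def alarm_crossing_time_s(glucose: SignalTrace, alarm_mgdl: float) -> float:
    """First downward crossing of the alarm threshold, in seconds.

    Uses the generator's exact crossing when present in ``meta``, else
    linear interpolation between samples.
    """
    t_min = glucose.meta.get("alarm_time_min")
    if t_min is not None and glucose.meta.get("alarm_threshold_mgdl") == alarm_mgdl:
        return float(t_min) * 60.0
    g = glucose.samples.astype(float)
    t = glucose.times
    for i in range(g.size - 1):
        if g[i] >= alarm_mgdl > g[i + 1]:
            frac = (g[i] - alarm_mgdl) / (g[i] - g[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    raise ValueError("glucose trace never crosses the alarm threshold")


def onset_vs_alarm(fs: FeatureSeries, glucose: SignalTrace,
                   alarm_mgdl: float = 80.0, baseline_s: float = 1800.0,
                   k: float = 2.0, persistence: int = 3,
                   two_sided: bool = True,
                   sd_floor_frac: float = 0.05) -> OnsetResult:
    """Lead time between a sustained feature change and the glucose alarm.

    Baseline mean and SD come from the earliest quiet segment (windows ending
    within the first ``baseline_s``).  Onset is the first sustained run of
    consecutive windows whose values depart from the baseline by more than
    ``k`` SDs (two-sided by default, since the EEG centroid may shift either
    way); the onset time is the midpoint of the first window of that run,
    and the lead time is ``alarm - onset`` in minutes.  ``persistence``
    counts *independent* windows: when windows overlap (step < window), the
    required run length is scaled by the overlap factor so that "three
    consecutive windows" means three windows of genuinely new data, not
    three copies of the same excursion.  The SD is
    floored at ``sd_floor_frac`` of the baseline mean's magnitude so that a
    numerically near-constant baseline (e.g. a locked spindle frequency)
    does not flag sub-percent fluctuations as onsets.  The
    pre/post-onset means mirror the trend-line convention of reporting a
    constant average before the change and a distinct one after.
    """
    vals = fs.values
    mids = fs.midpoints_s
    base_mask = fs.window_end_s <= fs.window_start_s[0] + baseline_s
    base = vals[base_mask & np.isfinite(vals)]
    if base.size < max(persistence, 3):
        raise ValueError("feature series has too few baseline windows")
    mu, sd = float(np.mean(base)), float(np.std(base, ddof=1))
    sd = max(sd, sd_floor_frac * abs(mu), 1e-12)
    alarm_s = alarm_crossing_time_s(glucose, alarm_mgdl)

    dev = (vals - mu) / sd
    exceed = np.abs(dev) > k if two_sided else dev > k
    exceed &= np.isfinite(vals)
    window_len = float(np.median(fs.window_end_s - fs.window_start_s))
    step = float(np.median(np.diff(fs.window_start_s))) if fs.n_windows > 1 \
        else window_len
    overlap = max(1, int(np.ceil(window_len / step - 1e-9)))
    run_needed = persistence + overlap - 1
    onset_idx = None
    run = 0
    for i, e in enumerate(exceed):
        run = run + 1 if e else 0
        if run >= run_needed:
            onset_idx = i - run_needed + 1
            break
    if onset_idx is None:
        return OnsetResult(False, float("nan"), float("nan"), mu, sd,
                           mu, float("nan"))
    onset_t = float(mids[onset_idx])
    post = vals[onset_idx:]
    pre = vals[:onset_idx]
    return OnsetResult(
        True, onset_t, (alarm_s - onset_t) / 60.0, mu, sd,
        float(np.nanmean(pre)) if pre.size else mu,
        float(np.nanmean(post)),
    )


# ---------------------------------------------------------------------------
# REM screening
# ---------------------------------------------------------------------------

def _epoch_count(duration_s: float, epoch_s: float) -> int:
    return int(np.floor(duration_s / epoch_s + 1e-9))


def hr_burst_flags(rr, epoch_s: float = EPOCH_S, n_epochs: int | None = None,
                   low_bpm: float = 55.0, high_bpm: float = 80.0,
                   sd_mult: float = 3.0) -> np.ndarray:
    """Per-epoch heart-rate burst flags.

    From an :class:`RRSeries` (preferred), an epoch is flagged when its
    instantaneous HR either reaches the burst regime (max >= ``high_bpm``,
    having a baseline below ``low_bpm``) or its HR spread exceeds
    ``sd_mult`` times the night's median epoch HR SD — the "wide
    variability with bursts" pattern.  A mean-HR FeatureSeries is accepted
    as a fallback, flagging epochs whose mean exceeds ``low_bpm``.
    """
    if isinstance(rr, FeatureSeries):
        flags = rr.values > low_bpm
        return np.asarray(flags, dtype=bool)
    if not isinstance(rr, RRSeries):
        raise TypeError("rr must be an RRSeries or a FeatureSeries")
    rr_ms, rr_t = rr.gated()
    hr = 60000.0 / rr_ms
    duration = rr.peak_times_s[-1] if rr.n_beats else 0.0
    n_ep = n_epochs if n_epochs is not None else _epoch_count(duration, epoch_s)
    maxs = np.full(n_ep, np.nan)
    sds = np.full(n_ep, np.nan)
    idx = np.floor(rr_t / epoch_s).astype(int)
    for e in range(n_ep):
        h = hr[idx == e]
        if h.size >= 2:
            maxs[e] = h.max()
            sds[e] = np.std(h, ddof=1)
    base_sd = max(float(np.nanmedian(sds)), 0.5)
    flags = (maxs >= high_bpm) | (sds >= sd_mult * base_sd)
    return np.where(np.isnan(maxs), False, flags).astype(bool)


def atonia_flags(env: SignalTrace, epoch_s: float = EPOCH_S,
                 tone_threshold: float = 0.05,
                 n_epochs: int | None = None) -> np.ndarray:
    """Per-epoch atonia flags: epoch median envelope below ``tone_threshold``.

    ``env`` must be a normalized envelope (from ``emg_envelope``); a residual
    constant contraction keeps the median above the threshold, total atonia
    drops it to near zero.
    """
    if env.units != "normalized":
        raise ValueError("atonia_flags expects a normalized envelope")
    spe = int(round(epoch_s * env.fs))
    n_ep = n_epochs if n_epochs is not None else env.n // spe
    flags = np.zeros(n_ep, dtype=bool)
    for e in range(n_ep):
        seg = env.samples[e * spe:(e + 1) * spe]
        if seg.size:
            flags[e] = float(np.median(seg)) < tone_threshold
    return flags


def eog_flags(trace: SignalTrace, epoch_s: float = EPOCH_S, k: float = 3.0,
              n_epochs: int | None = None) -> np.ndarray:
    """Per-epoch eye-activity flags (thin wrapper over ``eog_activity``)."""
    fs_act = feat.eog_activity(trace, epoch_s, k=k)
    flags = fs_act.values > 0.5
    if n_epochs is not None:
        flags = flags[:n_epochs]
        if flags.size < n_epochs:
            flags = np.concatenate([flags,
                                    np.zeros(n_epochs - flags.size, bool)])
    return flags


def rem_screen(hr_flags: Sequence[bool], eog_flags_: Sequence[bool],
               atonia_flags_: Sequence[bool], epoch_s: float = EPOCH_S,
               min_episode_s: float = 300.0,
               merge_gap_s: float = EPOCH_S) -> EpisodeSet:
    """Epoch-wise REM screening by conjunction of the three biopotentials.

    An epoch is a REM candidate iff HR bursts, eye activity, and atonia
    coincide; consecutive candidates are merged (bridging gaps up to
    ``merge_gap_s``) and episodes shorter than ``min_episode_s`` dropped.
    """
    h = np.asarray(hr_flags, dtype=bool)
    e = np.asarray(eog_flags_, dtype=bool)
    a = np.asarray(atonia_flags_, dtype=bool)
    if not (h.size == e.size == a.size):
        raise ValueError(f"flag series lengths differ: hr={h.size}, "
                         f"eog={e.size}, atonia={a.size}")
    cand = h & e & a
    # Candidate runs -> intervals.
    intervals = []
    i = 0
    while i < cand.size:
        if cand[i]:
            j = i
            while j + 1 < cand.size and cand[j + 1]:
                j += 1
            intervals.append([i * epoch_s, (j + 1) * epoch_s])
            i = j + 1
        else:
            i += 1
    # Merge across short gaps.
    merged = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] <= merge_gap_s + 1e-9:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    keep = [(a0, b0, "REM-candidate") for a0, b0 in merged
            if b0 - a0 >= min_episode_s]
    return EpisodeSet(keep, source="rem_screen")


# ---------------------------------------------------------------------------
# Agreement report
# ---------------------------------------------------------------------------

def discrepancy_report(qvar: Mapping[str, float],
                       gold: Mapping[str, float]) -> pd.DataFrame:
    """Percent discrepancy of device metrics against a gold standard.

    Per metric: ``100 * |device - gold| / gold``; a zero gold value yields a
    NaN sentinel for that row.  The maximum finite discrepancy is stored in
    ``DataFrame.attrs["max_discrepancy_pct"]``.
    """
    if set(qvar) != set(gold):
        raise ValueError(f"metric keys differ: {sorted(set(qvar) ^ set(gold))}")
    rows = []
    for key in qvar:
        q, g = float(qvar[key]), float(gold[key])
        disc = float("nan") if g == 0 else 100.0 * abs(q - g) / g
        rows.append((key, q, g, disc))
    df = pd.DataFrame(rows, columns=["metric", "device", "gold",
                                     "discrepancy_pct"]).set_index("metric")
    finite = df["discrepancy_pct"].dropna()
    df.attrs["max_discrepancy_pct"] = float(finite.max()) if len(finite) else float("nan")
    return df
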