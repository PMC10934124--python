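"""Core containers for uniformly sampled biopotential data.

All time series in this package are uniform: a trace is an array of samples
plus a sampling rate and a start time, never an explicit timestamp column.
Biopotential amplitudes are carried in millivolts, digitized sensor output in
LSB counts, interstitial glucose in mg/dL, and display/envelope signals as
dimensionless ``normalized`` values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "VALID_UNITS",
    "SignalTrace",
    "SensorModel",
    "RRSeries",
    "FeatureSeries",
    "EpisodeSet",
    "ScenarioSpec",
    "GlucoseScenario",
]

VALID_UNITS = ("mV", "LSB", "mg/dL", "normalized")


@dataclass
class SignalTrace:
    """A uniformly sampled single-channel series.

    Parameters
    ----------
    samples : array-like
        Sample values in ``units``.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds.
    label : str
        Channel name (e.g. ``"ecg"``, ``"emg_masseter"``).
    units : str
        One of :data:`VALID_UNITS`; other strings are passed through with a
        warning so externally produced files are not rejected outright.
    meta : dict
        Free-form metadata. Generators store their ground truth here
        (R-peak times, burst intervals, spindle boundaries, ...).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = "signal"
    units: str = "mV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.units not in VALID_UNITS:
            warnings.warn(
                f"unknown units {self.units!r} (expected one of {VALID_UNITS}); "
                "passing through",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds: ``t0 + i / fs``."""
        return self.t0 + np.arange(self.n) / self.fs

    def copy_with(self, samples=None, **kwargs) -> "SignalTrace":
        """Return a copy, optionally replacing samples and/or fields."""
        out = dict(
            samples=self.samples.copy() if samples is None else np.asarray(samples),
            fs=self.fs,
            t0=self.t0,
            label=self.label,
            units=self.units,
            meta=dict(self.meta),
        )
        out.update(kwargs)
        return SignalTrace(**out)

    def slice(self, start_s: float, end_s: float) -> "SignalTrace":
        """Return the sub-trace covering ``[start_s, end_s)`` (absolute time)."""
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.fs - 1e-9)))
        i1 = min(self.n, int(np.ceil((end_s - self.t0) * self.fs - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start_s}, {end_s}) for trace of "
                             f"duration {self.duration_s:.3f} s")
        return self.copy_with(samples=self.samples[i0:i1],
                              t0=self.t0 + i0 / self.fs, meta=dict(self.meta))


@dataclass
class SensorModel:
    """Front-end constants of the charge-variation acquisition chain.

    Defaults follow the platform's published electrical characteristics:
    gain 78 LSB/mV, a 12-bit converter, DC-coupled input range of +/-460 mV,
    shorted-input noise of 54 uV RMS, and a 240 Hz output data rate.  The
    78 LSB/mV gain together with 12 bits implies an effective +/-26.3 mV
    digitized span, narrower than the analog input range; both numbers are
    kept configurable and digitization simply clips at the bit-depth range.
    """

    gain_lsb_per_mv: float = 78.0
    bits: int = 12
    input_range_mv: float = 460.0
    noise_uv_rms: float = 54.0
    odr_hz: float = 240.0

    def __post_init__(self) -> None:
        for name in ("gain_lsb_per_mv", "input_range_mv", "odr_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_uv_rms < 0:
            raise ValueError("noise_uv_rms must be >= 0 (0 = ideal front-end)")
        if int(self.bits) != self.bits or self.bits <= 0:
            raise ValueError("bits must be a positive integer")
        self.bits = int(self.bits)

    @property
    def lsb_min(self) -> int:
        return -(2 ** (self.bits - 1))

    @property
    def lsb_max(self) -> int:
        return 2 ** (self.bits - 1) - 1


@dataclass
class RRSeries:
    """Beat (R-peak) times and the successive RR intervals they define."""

    peak_times_s: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.ndim != 1:
            raise ValueError("peak_times_s must be 1-D")
        if self.peak_times_s.size >= 2 and np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return self.peak_times_s.size

    @property
    def rr_ms(self) -> np.ndarray:
        """Successive RR intervals in milliseconds (length ``n_beats - 1``)."""
        return np.diff(self.peak_times_s) * 1000.0

    @property
    def rr_times_s(self) -> np.ndarray:
        """Time stamp of each RR interval: midpoint of its two beats."""
        t = self.peak_times_s
        return 0.5 * (t[1:] + t[:-1])

    def gated(self, min_ms: float = 300.0, max_ms: float = 2000.0):
        """Physiologically plausible intervals only.

        Returns ``(rr_ms, rr_times_s)`` with intervals outside
        ``[min_ms, max_ms]`` removed; ectopic-like outliers would otherwise
        dominate the variability statistics.
        """
        rr = self.rr_ms
        t = self.rr_times_s
        keep = (rr >= min_ms) & (rr <= max_ms)
        return rr[keep], t[keep]

    def window(self, start_s: float, end_s: float) -> "RRSeries":
        """Beats whose times fall in ``[start_s, end_s)``."""
        t = self.peak_times_s
        return RRSeries(t[(t >= start_s) & (t < end_s)])


@dataclass
class FeatureSeries:
    """Time-stamped rolling feature values, one metric per series."""

    metric: str
    window_start_s: np.ndarray
    window_end_s: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.window_start_s = np.asarray(self.window_start_s, dtype=float)
        self.window_end_s = np.asarray(self.window_end_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.window_start_s.shape == self.window_end_s.shape
                == self.values.shape):
            raise ValueError("window arrays and values must have equal shapes")
        if np.any(self.window_end_s <= self.window_start_s):
            raise ValueError("windows must have end > start")
        starts = self.window_start_s
        if starts.size >= 2 and np.any(np.diff(starts) <= 0):
            raise ValueError("windows must be ordered by start time")

    @property
    def n_windows(self) -> int:
        return self.values.size

    @property
    def midpoints_s(self) -> np.ndarray:
        return 0.5 * (self.window_start_s + self.window_end_s)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "window_start_s": self.window_start_s,
                "window_end_s": self.window_end_s,
                "metric": self.metric,
                "value": self.values,
            }
        )


@dataclass
class EpisodeSet:
    """Labeled, ordered, non-overlapping time intervals."""

    intervals: list
    source: str = ""

    def __post_init__(self) -> None:
        ivs = [(float(a), float(b), str(lab)) for a, b, lab in self.intervals]
        for a, b, _ in ivs:
            if b <= a:
                raise ValueError(f"interval end must exceed start, got ({a}, {b})")
        for (a0, b0, _), (a1, _, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("intervals must be ordered and non-overlapping")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([b - a for a, b, _ in self.intervals])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.intervals, columns=["start_s", "end_s", "label"])


# Sleep-stage labels understood by the night simulator and screeners.
STAGES = ("WAKE", "NREM", "REM")


def _stage_defaults() -> dict:
    return {
        "WAKE": {"mean_rr_ms": 850.0, "jitter_ms": 40.0},
        "NREM": {"mean_rr_ms": 1100.0, "jitter_ms": 30.0},
        "REM": {"mean_rr_ms": 1000.0, "jitter_ms": 20.0},
    }


def _tone_defaults() -> dict:
    # Envelope level relative to the WAKE contraction amplitude; REM shows
    # atonia (near-zero tone), NREM a residual constant contraction.
    return {"WAKE": 0.5, "NREM": 0.2, "REM": 0.005}


def _eog_rate_defaults() -> dict:
    # Eye events per minute per stage.
    return {"WAKE": 6.0, "NREM": 0.2, "REM": 25.0}


def _burst_defaults() -> dict:
    # REM heart-rate burst pattern: RR dips from the stage baseline down to
    # min_rr_ms, held long enough (> 2 scoring epochs) that one 30 s epoch
    # always lies fully inside a burst regardless of grid alignment.
    return {"min_rr_ms": 750.0, "cycle_s": 120.0, "hold_s": 65.0, "ramp_s": 5.0}


@dataclass
class ScenarioSpec:
    """A hypnogram-driven overnight multichannel scenario."""

    duration_s: float
    hypnogram: list  # list of (stage, duration_s)
    hr_profile: dict = field(default_factory=_stage_defaults)
    burst_spec: dict = field(default_factory=_burst_defaults)
    emg_tone: dict = field(default_factory=_tone_defaults)
    eog_rate: dict = field(default_factory=_eog_rate_defaults)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hypnogram:
            raise ValueError("hypnogram must contain at least one stage block")
        hyp = [(str(s), float(d)) for s, d in self.hypnogram]
        for s, d in hyp:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; expected one of {STAGES}")
            if d <= 0:
                raise ValueError("stage durations must be positive")
        self.hypnogram = hyp
        total = sum(d for _, d in hyp)
        if abs(total - self.duration_s) > 1e-6:
            raise ValueError(
                f"hypnogram durations sum to {total} s, not duration_s={self.duration_s}"
            )
        for rates in (self.eog_rate,):
            if any(v < 0 for v in rates.values()):
                raise ValueError("eog rates must be >= 0")

    @classmethod
    def two_rem_night(cls, rem_minutes=(17.0, 15.0), nrem_minutes=(10.0, 20.0, 8.0),
                      seed: int = 0, **kwargs) -> "ScenarioSpec":
        """An NREM night containing the given REM blocks (defaults 17 and 15 min)."""
        hyp = []
        for i, rem in enumerate(rem_minutes):
            hyp.append(("NREM", nrem_minutes[i] * 60.0))
            hyp.append(("REM", rem * 60.0))
        hyp.append(("NREM", nrem_minutes[len(rem_minutes)] * 60.0))
        return cls(duration_s=sum(d for _, d in hyp), hypnogram=hyp, seed=seed,
                   **kwargs)

    def stage_intervals(self) -> EpisodeSet:
        """Ground-truth hypnogram as absolute intervals."""
        out, t = [], 0.0
        for s, d in self.hypnogram:
            out.append((t, t + d, s))
            t += d
        return EpisodeSet(out, source="hypnogram")

    def to_dict(self) -> dict:
        return {
            "duration_s": self.duration_s,
            "hypnogram": [[s, d] for s, d in self.hypnogram],
            "hr_profile": self.hr_profile,
            "burst_spec": self.burst_spec,
            "emg_tone": self.emg_tone,
            "eog_rate": self.eog_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioSpec":
        d = dict(d)
        d["hypnogram"] = [tuple(x) for x in d["hypnogram"]]
        return cls(**d)


def _default_decay_profile() -> list:
    # Flat at the 120 mg/dL target for 30 min, then a steady decline of
    # 20 mg/dL per 90 min down to 70: crosses 100 at minute 120 and the
    # 80 mg/dL alarm at minute 210 (90 min later), reaching 70 at 255 min.
    return [(0.0, 120.0), (30.0, 120.0), (255.0, 70.0), (265.0, 70.0)]


@dataclass
class GlucoseScenario:
    """Overnight glucose decay crossing a hypoglycemia alarm threshold.

    The decay profile is piecewise linear in (minutes, mg/dL).  Analysis time
    t = 0 is defined as the first crossing below ``alarm_threshold_mgdl``;
    the slow ECG-parameter drift is keyed to the ``ecg_drift_onset_glucose``
    crossing (default 100 mg/dL) and the sudden alpha-EEG shift to a fixed
    lead of ``eeg_shift_lead_min`` minutes before the alarm.
    """

    baseline_mgdl: float = 120.0
    alarm_threshold_mgdl: float = 80.0
    decay_profile: list = field(default_factory=_default_decay_profile)
    ecg_drift_onset_glucose: float = 100.0
    eeg_shift_lead_min: float = 15.0
    noise_mgdl: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mgdl <= self.alarm_threshold_mgdl:
            raise ValueError("baseline must exceed the alarm threshold")
        prof = [(float(t), float(v)) for t, v in self.decay_profile]
        if len(prof) < 2:
            raise ValueError("decay profile needs at least two points")
        if any(t1 <= t0 for (t0, _), (t1, _) in zip(prof, prof[1:])):
            raise ValueError("decay profile times must be increasing")
        # Monotone non-increasing up to the alarm crossing.
        below = [i for i, (_, v) in enumerate(prof) if v < self.alarm_threshold_mgdl]
        upto = below[0] + 1 if below else len(prof)
        vals = [v for _, v in prof[:upto]]
        if any(v1 > v0 + 1e-9 for v0, v1 in zip(vals, vals[1:])):
            raise ValueError("decay profile must be non-increasing until the "
                             "alarm crossing")
        self.decay_profile = prof

    @property
    def duration_min(self) -> float:
        return self.decay_profile[-1][0]

    def to_dict(self) -> dict:
        return {
            "baseline_mgdl": self.baseline_mgdl,
            "alarm_threshold_mgdl": self.alarm_threshold_mgdl,
            "decay_profile": [[t, v] for t, v in self.decay_profile],
            "ecg_drift_onset_glucose": self.ecg_drift_onset_glucose,
            "eeg_shift_lead_min": self.eeg_shift_lead_min,
            "noise_mgdl": self.noise_mgdl,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GlucoseScenario":
        d = dict(d)
        d["decay_profile"] = [tuple(x) for x in d["decay_profile"]]
        return cls(**d)
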