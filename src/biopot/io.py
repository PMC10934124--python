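"""Readers and writers: multichannel CSV, EDF, and YAML scenarios/configs.

CSV is the canonical interchange format: a header row, a ``time_s`` column in
seconds, then one column per channel named ``label [units]``.  EDF export is
provided for interoperability with sleep-analysis viewers (16-bit samples,
physical dimension from the trace units); EDF reading goes through ``mne``.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .signals import GlucoseScenario, ScenarioSpec, SignalTrace

__all__ = [
    "read_trace", "write_trace", "read_trace_csv", "write_trace_csv",
    "read_trace_edf", "write_trace_edf", "load_scenario", "save_scenario",
    "RunConfig", "sha256_file", "write_episodes_csv", "write_features_csv",
]


def _as_list(traces) -> list:
    return list(traces) if isinstance(traces, (list, tuple)) else [traces]


def _column_name(tr: SignalTrace) -> str:
    return f"{tr.label} [{tr.units}]"


def _parse_column(name: str):
    name = name.strip()
    if name.endswith("]") and "[" in name:
        label, units = name.rsplit("[", 1)
        return label.strip(), units[:-1].strip()
    return name, "mV"


def write_trace_csv(path, traces) -> Path:
    """Write one or more equally sampled traces to a multichannel CSV."""
    traces = _as_list(traces)
    fs0, t00 = traces[0].fs, traces[0].t0
    n = min(tr.n for tr in traces)
    for tr in traces:
        if abs(tr.fs - fs0) > 1e-9 or abs(tr.t0 - t00) > 1e-9:
            raise ValueError("all channels must share fs and t0 for CSV export")
    # Time gets fixed microsecond precision so spacing stays uniform in
    # print; channel values keep 8 significant digits.
    data = {"time_s": [f"{v:.6f}" for v in t00 + np.arange(n) / fs0]}
    for tr in traces:
        data[_column_name(tr)] = tr.samples[:n]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.8g")
    return Path(path)


def read_trace_csv(path) -> list[SignalTrace]:
    """Read a multichannel CSV back into SignalTraces.

    Requires a ``time_s`` column with uniform spacing; a non-uniform time
    column is rejected naming the first offending row.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: malformed header, missing column 'time_s' "
                         f"(found {list(df.columns)})")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    # Tolerate printed-precision jitter, reject genuinely irregular sampling.
    bad = np.where(np.abs(dt - dt0) > 1e-3 * max(abs(dt0), 1e-12))[0]
    if bad.size:
        raise ValueError(f"{path}: non-uniform time column at row {bad[0] + 1} "
                         f"(dt={dt[bad[0]]:.6g} s vs {dt0:.6g} s)")
    fs = (t.size - 1) / (t[-1] - t[0])
    out = []
    for col in df.columns:
        if col == "time_s":
            continue
        label, units = _parse_column(col)
        out.append(SignalTrace(df[col].to_numpy(dtype=float), fs=fs, t0=t[0],
                               label=label, units=units))
    return out


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MAX = 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_trace_edf(path, traces, *, patient: str = "X", recording: str = "X",
                    start: datetime.datetime | None = None) -> Path:
    """Write traces as a plain EDF file (one signal per channel).

    EDF stores 16-bit samples in 1 s records, so the sampling rate must be a
    positive integer and the traces are truncated to a whole number of
    seconds.  Physical min/max are taken symmetric around zero from the
    data; the physical dimension is the trace's unit string.
    """
    traces = _as_list(traces)
    fs = traces[0].fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError(f"EDF export needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    for tr in traces:
        if int(round(tr.fs)) != fs:
            raise ValueError("all channels must share the sampling rate")
    n_rec = min(tr.n for tr in traces) // fs
    if n_rec < 1:
        raise ValueError("traces shorter than one 1 s EDF record")
    start = start or datetime.datetime(2000, 1, 1, 0, 0, 0)

    ns = len(traces)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(patient, 80),
        _edf_field(recording, 80),
        _edf_field(start.strftime("%d.%m.%y"), 8),
        _edf_field(start.strftime("%H.%M.%S"), 8),
        _edf_field(256 * (1 + ns), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(ns, 4),
    ])

    phys_max, scaled = [], []
    for tr in traces:
        x = tr.samples[: n_rec * fs].astype(float)
        pm = max(float(np.max(np.abs(x))), 1e-6)
        phys_max.append(pm)
        scaled.append(np.clip(np.rint(x / pm * _EDF_DIG_MAX),
                              -_EDF_DIG_MAX, _EDF_DIG_MAX).astype("<i2"))

    def per_signal(fmt, width):
        return b"".join(_edf_field(fmt(i, tr), width)
                        for i, tr in enumerate(traces))

    header += per_signal(lambda i, tr: tr.label[:16], 16)          # labels
    header += per_signal(lambda i, tr: "", 80)                     # transducer
    header += per_signal(lambda i, tr: tr.units[:8], 8)            # dimension
    header += per_signal(lambda i, tr: f"{-phys_max[i]:.6g}"[:8], 8)
    header += per_signal(lambda i, tr: f"{phys_max[i]:.6g}"[:8], 8)
    header += per_signal(lambda i, tr: -_EDF_DIG_MAX, 8)
    header += per_signal(lambda i, tr: _EDF_DIG_MAX, 8)
    header += per_signal(lambda i, tr: "", 80)                     # prefilter
    header += per_signal(lambda i, tr: fs, 8)                      # samples/rec
    header += per_signal(lambda i, tr: "", 32)                     # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for sig in scaled:
                fh.write(sig[r * fs:(r + 1) * fs].tobytes())
    return Path(path)


def read_trace_edf(path) -> list[SignalTrace]:
    """Read an EDF file via mne; channels come back in their physical units."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    # mne rescales known dimensions to SI; ask for the raw orig units.
    data, _ = raw[:, :]
    out = []
    for i, name in enumerate(raw.ch_names):
        unit = raw._orig_units.get(name, "mV") if hasattr(raw, "_orig_units") else "mV"
        x = data[i]
        # Undo mne's SI scaling for dimensions it recognizes.
        scale = {"mV": 1e3, "uV": 1e6, "µV": 1e6, "V": 1.0}.get(unit)
        if scale is not None:
            x = x * scale
        else:
            unit = unit or "mV"
        out.append(SignalTrace(x, fs=fs, label=name, units=unit))
    return out


def write_trace(path, traces, format: str | None = None) -> Path:
    """Write traces as ``csv`` or ``edf`` (inferred from the suffix)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "csv":
        return write_trace_csv(path, traces)
    if fmt == "edf":
        return write_trace_edf(path, traces)
    raise ValueError(f"unknown trace format {fmt!r} (expected csv or edf)")


def read_trace(path, format: str | None = None) -> list[SignalTrace]:
    """Read traces from ``csv`` or ``edf`` (inferred from the suffix)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "csv":
        return read_trace_csv(path)
    if fmt == "edf":
        return read_trace_edf(path)
    raise ValueError(f"unknown trace format {fmt!r} (expected csv or edf)")


# ---------------------------------------------------------------------------
# Feature / episode serialization
# ---------------------------------------------------------------------------

def write_features_csv(path, feature_series) -> Path:
    """FeatureSeries (one or several) to long CSV:
    window_start_s, window_end_s, metric, value."""
    frames = [fs.to_frame() for fs in _as_list(feature_series)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def write_episodes_csv(path, episodes) -> Path:
    """EpisodeSet to 3-column interval CSV (start_s, end_s, label)."""
    episodes.to_frame().to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Scenarios and run configuration
# ---------------------------------------------------------------------------

def save_scenario(path, scenario) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)
    return Path(path)


def load_scenario(path):
    """Load a night (hypnogram) or glucose scenario from YAML/JSON."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    if "hypnogram" in d:
        return ScenarioSpec.from_dict(d)
    if "decay_profile" in d:
        return GlucoseScenario.from_dict(d)
    raise ValueError(f"{path}: not a recognizable scenario (needs a "
                     "'hypnogram' or 'decay_profile' field)")


@dataclass
class RunConfig:
    """A fully serializable description of one pipeline run."""

    scenario_path: str = ""
    seed: int = 0
    sensor: dict = field(default_factory=dict)
    presets: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    output_dir: str = "."

    def to_dict(self) -> dict:
        return {
            "scenario_path": self.scenario_path,
            "seed": self.seed,
            "sensor": dict(self.sensor),
            "presets": dict(self.presets),
            "screening": dict(self.screening),
            "output_dir": self.output_dir,
        }

    def save(self, path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return Path(path)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, files: Sequence, params: dict) -> Path:
    """JSON manifest listing outputs (with sha256) and effective parameters."""
    entries = [{"file": str(Path(f).name), "sha256": sha256_file(f)}
               for f in files]
    with open(path, "w") as fh:
        json.dump({"params": params, "outputs": entries}, fh, indent=2,
                  default=str)
    return Path(path)
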