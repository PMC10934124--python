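"""Per-signal conditioning: band presets, 50 Hz notch, and the sEMG envelope.

Filters are 4th-order Butterworth (the notch is a second-order IIR, Q = 30)
applied forward-backward so event times are not shifted; one second of
reflect padding at each end suppresses edge transients.  The named presets
carry the exact band edges used throughout: ECG 1-35 Hz, occipital alpha
8-13 Hz, frontal 1-3 Hz, and the sEMG chain's 3 Hz high-pass / 10 Hz
envelope low-pass / 50 Hz notch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import SignalTrace

__all__ = ["FilterSpec", "PRESETS", "preset", "apply_filter", "emg_envelope",
           "normalize"]

_KINDS = ("bandpass", "highpass", "lowpass", "notch")


@dataclass
class FilterSpec:
    kind: str
    edges: tuple  # Hz; (low, high) for bandpass, (edge,) otherwise
    order: int = 4
    zero_phase: bool = True
    q: float = 30.0  # notch quality factor

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        e = self.edges
        self.edges = tuple(float(x) for x in (e if np.iterable(e) else (e,)))
        if self.kind == "bandpass":
            if len(self.edges) != 2 or not self.edges[0] < self.edges[1]:
                raise ValueError("bandpass needs edges (low, high) with low < high")
        elif len(self.edges) != 1:
            raise ValueError(f"{self.kind} takes a single edge")
        if any(x <= 0 for x in self.edges):
            raise ValueError("edges must be strictly positive")


PRESETS = {
    "ecg": FilterSpec("bandpass", (1.0, 35.0)),
    "alpha": FilterSpec("bandpass", (8.0, 13.0)),
    "frontal": FilterSpec("bandpass", (1.0, 3.0)),
    "emg_hp": FilterSpec("highpass", (3.0,)),
    "emg_lp": FilterSpec("lowpass", (10.0,)),
    "notch50": FilterSpec("notch", (50.0,)),
}


def preset(name: str) -> FilterSpec:
    """Return the named conditioning preset (a fresh copy)."""
    try:
        p = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; valid names: "
                         f"{sorted(PRESETS)}") from None
    return FilterSpec(p.kind, p.edges, p.order, p.zero_phase, p.q)


def _design(f: FilterSpec, fs: float):
    nyq = fs / 2.0
    for e in f.edges:
        if e >= nyq:
            raise ValueError(f"filter edge {e} Hz is at or above the Nyquist "
                             f"frequency {nyq} Hz")
    if f.kind == "notch":
        b, a = sps.iirnotch(f.edges[0], f.q, fs=fs)
        return ("ba", b, a)
    btype = {"bandpass": "bandpass", "highpass": "highpass",
             "lowpass": "lowpass"}[f.kind]
    edges = f.edges if f.kind == "bandpass" else f.edges[0]
    sos = sps.butter(f.order, edges, btype=btype, fs=fs, output="sos")
    return ("sos", sos)


def apply_filter(trace: SignalTrace, f: FilterSpec) -> SignalTrace:
    """Filter a trace, preserving length, rate and (by default) phase."""
    n = trace.n
    if n <= 3 * max(f.order, 2):
        raise ValueError("trace too short for the requested filter order")
    design = _design(f, trace.fs)
    pad = min(int(round(trace.fs)), n - 1)
    x = np.pad(trace.samples.astype(float), pad, mode="reflect")
    if design[0] == "sos":
        sos = design[1]
        y = sps.sosfiltfilt(sos, x) if f.zero_phase else sps.sosfilt(sos, x)
    else:
        _, b, a = design
        y = sps.filtfilt(b, a, x) if f.zero_phase else sps.lfilter(b, a, x)
    y = y[pad:pad + n]
    meta = dict(trace.meta)
    meta["filters"] = list(meta.get("filters", [])) + [(f.kind, f.edges)]
    return trace.copy_with(samples=y, meta=meta)


def emg_envelope(trace: SignalTrace, normalize_output: bool = True) -> SignalTrace:
    """The four-step sEMG envelope, in its fixed order.

    (1) high-pass at 3 Hz (DC/movement-artifact removal) with a 50 Hz notch;
    (2) full-wave rectification; (3) smoothing by a 10 Hz low-pass; (4)
    normalization by the envelope maximum.  Steps 2 and 3 do not commute:
    low-passing before rectification would destroy the envelope, and a
    regression test pins this order.

    For a sinusoidal carrier of amplitude a, the pre-normalization plateau is
    the full-wave-rectified mean 2a/pi.

    Returns a non-negative trace in [0, 1] (units ``normalized``) with
    ``meta["envelope_max"]`` carrying the pre-normalization maximum in mV;
    an all-zero input comes back all-zero with ``meta["all_zero"] = True``.
    """
    if trace.fs <= 100:
        raise ValueError(f"emg_envelope needs fs > 100 Hz, got {trace.fs}")
    if not np.any(trace.samples):
        out = trace.copy_with(samples=np.zeros(trace.n), units="normalized")
        out.meta["all_zero"] = True
        out.meta["envelope_max"] = 0.0
        return out
    y = apply_filter(trace, preset("emg_hp"))
    y = apply_filter(y, preset("notch50"))
    y = y.copy_with(samples=np.abs(y.samples))           # (2) rectification
    y = apply_filter(y, preset("emg_lp"))                # (3) smoothing
    env = np.maximum(y.samples, 0.0)
    peak = float(env.max())
    meta = dict(y.meta)
    meta["envelope_max"] = peak
    if normalize_output and peak > 0:
        env = env / peak
        return trace.copy_with(samples=env, units="normalized", meta=meta)
    return trace.copy_with(samples=env, units=trace.units, meta=meta)


def normalize(trace: SignalTrace) -> SignalTrace:
    """Peak-absolute normalization.

    Bipolar signals map to [-1, 1], non-negative envelopes to [0, 1].  A
    zero signal is returned unchanged with ``meta["all_zero"] = True``;
    normalization is idempotent.
    """
    x = trace.samples.astype(float)
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    peak = float(np.max(np.abs(x)))
    meta = dict(trace.meta)
    if peak == 0.0:
        meta["all_zero"] = True
        return trace.copy_with(samples=x, units="normalized", meta=meta)
    return trace.copy_with(samples=x / peak, units="normalized", meta=meta)
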