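"""Programmatically generated test fixtures and packaged reference values."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import simulate
from .io import (save_scenario, sha256_file, write_episodes_csv,
                 write_trace_csv)
from .signals import GlucoseScenario, ScenarioSpec

__all__ = ["REFERENCE_METRIC_PAIRS", "reference_metrics_frame", "make_fixtures"]

# Published 24 h averages over six control subjects: device vs certified
# gold-standard system, the worked example for the agreement report.
REFERENCE_METRIC_PAIRS = {
    "QTc (ms)": (329.0, 334.0),
    "RR (ms)": (948.4, 957.6),
    "SDNN": (149.9, 149.1),
    "LF:HF": (0.595, 0.590),
    "CF (Hz)": (102.13, 102.28),
}


def reference_metrics_frame() -> pd.DataFrame:
    rows = [(k, q, g) for k, (q, g) in REFERENCE_METRIC_PAIRS.items()]
    return pd.DataFrame(rows, columns=["metric", "device_value",
                                       "reference_value"])


def make_fixtures(outdir, seed: int = 0) -> dict:
    """Emit the packaged test fixtures and a manifest with sha256 checksums.

    Written files: a 60 s ECG, alpha-spindle EEG, three-burst sEMG, a blink
    EOG trace, scenario files for the hypoglycemia night and the two-REM
    night (plus a short rendered two-REM night), and the reference metric
    pairs CSV.  A fixed seed gives stable checksums across runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    ecg = simulate.gen_ecg(rr_ms=[1000.0] * 60, fs=240.0, seed=seed)
    files.append(write_trace_csv(outdir / "ecg_60s.csv", ecg))

    eeg = simulate.gen_alpha_eeg(duration_s=30.0, fs=240.0, seed=seed + 1)
    files.append(write_trace_csv(outdir / "alpha_eeg.csv", eeg))

    emg = simulate.gen_emg([(5, 10), (15, 20), (25, 30)], fs=960.0,
                           duration_s=35.0, seed=seed + 2)
    files.append(write_trace_csv(outdir / "emg_3burst.csv", emg))

    eog = simulate.gen_frontal_eeg(90.0, blink_times_s=[15, 35, 61, 75],
                                   fs=240.0, seed=seed + 3)
    files.append(write_trace_csv(outdir / "eog_blinks.csv", eog))

    files.append(save_scenario(outdir / "hg_night.yaml",
                               GlucoseScenario(seed=seed)))

    night_spec = ScenarioSpec.two_rem_night(rem_minutes=(7.0, 6.0),
                                            nrem_minutes=(4.0, 6.0, 3.0),
                                            seed=seed)
    files.append(save_scenario(outdir / "two_rem_night.yaml", night_spec))
    night = simulate.compose_night(night_spec)
    files.append(write_trace_csv(outdir / "two_rem_night.csv",
                                 [night["ecg"], night["eog"], night["emg"]]))
    files.append(write_episodes_csv(outdir / "two_rem_night_hypnogram.csv",
                                    night["hypnogram"]))

    ref = outdir / "reference_metrics.csv"
    reference_metrics_frame().to_csv(ref, index=False)
    files.append(ref)

    manifest = {
        "seed": seed,
        "files": [{"file": f.name, "sha256": sha256_file(f)} for f in files],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
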