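# biopot

Biopotential acquisition modeling, conditioning, and clinical screening for
wearable charge-variation (electrostatic MEMS) sensor platforms.

Low-power MEMS charge-variation sensors can record ECG, EEG, EOG, and
surface EMG for days at near-zero added power, which makes two kinds of
overnight domestic screening practical: watching ECG/EEG parameters drift
in the run-up to a nocturnal hypoglycemia alarm, and flagging REM sleep
epochs from the simultaneous occurrence of heart-rate bursts, rapid eye
movements, and chin/masseter atonia. `biopot` implements that processing
stack as a tested Python package for signal-processing researchers and
device engineers: since no recordings from such devices are publicly
deposited, every stage is paired with a synthetic generator that carries
its construction ground truth, so the full pipeline is verifiable offline.

## What it computes

* **Acquisition model** — additive front-end noise (54 µV RMS), resampling
  to the output data rate (240 Hz), gain 78 LSB/mV, 12-bit quantization
  with saturation clipping, and the inverse LSB→mV mapping.
* **Conditioning** — zero-phase Butterworth presets with the platform's
  band edges (ECG 1–35 Hz, occipital alpha 8–13 Hz, frontal 1–3 Hz), a
  50 Hz notch, and the four-step sEMG envelope (3 Hz HP + notch →
  rectification → 10 Hz LP → normalization).
* **Features** — R peaks (energy-transform detection, 200 ms refractory);
  HR = 60000/RR; QT and QTc = QT/√RR(s); SDNN and RMSSD;
  LF:HF of the RR tachogram spectrum (LF 0.04–0.15 Hz / HF 0.15–0.40 Hz,
  4 Hz resampling, Welch); spectral moments Gₙ = ∫ fⁿP(f) df with centroid
  frequency CF = G₁/G₀ and rotational radius √(G₂/G₀); EMG activation
  bursts; per-epoch EOG activity.
* **Screening** — rolling-feature onset detection against the glucose alarm
  (baseline + k·SD sustained-departure rule, lead time in minutes), and
  epoch-wise REM screening by the three-way conjunction of HR-burst, eye-
  activity, and atonia flags on 30 s epochs.
* **Synthetic data** — seeded generators for ECG (sum-of-Gaussians P-QRS-T
  beats on an RR sequence), alpha spindles, blink/saccade EOG, gated sEMG,
  glucose decay profiles, hypnogram-driven multichannel nights, and the
  full hypoglycemia-night scenario.

See `docs/methods.md` for the model details, defaults, and limitations.

## Worked example

Screen a simulated 70-minute night whose hypnogram contains REM blocks of
17 and 15 minutes:

```python
import numpy as np
from biopot import simulate as sim, preprocess as pp, features as feat, screening as scr
from biopot.signals import ScenarioSpec

scn = ScenarioSpec.two_rem_night(seed=42)
night = sim.compose_night(scn)
n_ep = int(scn.duration_s // 30)

rr = feat.detect_r_peaks(pp.apply_filter(night["ecg"], pp.preset("ecg")))
hr_flags = scr.hr_burst_flags(rr, n_epochs=n_ep)
eog_flags = scr.eog_flags(pp.apply_filter(night["eog"], pp.preset("frontal")), n_epochs=n_ep)
atonia = scr.atonia_flags(pp.emg_envelope(night["emg"]), n_epochs=n_ep)

episodes = scr.rem_screen(hr_flags, eog_flags, atonia)
print(episodes.to_frame())
print(f"beats: {rr.n_beats}, SDNN {feat.sdnn(rr):.1f} ms, RMSSD {feat.rmssd(rr):.1f} ms")
```

prints

```
   start_s   end_s          label
0    600.0  1620.0  REM-candidate
1   2820.0  3720.0  REM-candidate
beats: 4378, SDNN 158.5 ms, RMSSD 33.1 ms
```

The screener recovers the two programmed REM blocks: minutes 10–27
(17 min) and 47–62 (15 min, detected here as 2820–3720 s = 15.0 min).
The whole-night SDNN is large (158 ms) because the NREM/REM stage
difference in mean RR dominates; within-stage windows are far smaller.

The same pipeline is available from the shell:

```
biopot make-fixtures --out fixtures --seed 0
biopot simulate --scenario fixtures/two_rem_night.yaml --seed 7 --out night_out
biopot screen-rem --night night_out/night.csv --out rem_out
biopot report device.csv gold.csv     # percent-discrepancy table
```

Every run writes a JSON manifest (outputs + sha256) and its resolved
configuration, and identical seeds reproduce outputs byte for byte.

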