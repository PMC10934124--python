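# Methods

`biopot` is a desk-scale software counterpart of a wearable biopotential
platform built on electrostatic charge-variation (QVAR-type) MEMS sensing.
Because no recordings from such a device are publicly deposited, the package
pairs every analysis stage with a synthetic generator whose ground truth is
carried in the trace metadata, so the whole chain — acquisition model,
conditioning, feature extraction, screening — is testable end to end.

## Acquisition model

A physical trace in millivolts is digitized by `simulate.apply_sensor`:

1. additive white Gaussian front-end noise (default 54 µV RMS, the
   shorted-input figure of the modeled sensor);
2. polyphase resampling to the output data rate (default 240 Hz,
   configurable 120–240 Hz);
3. gain of 78 LSB/mV, rounding to integer counts;
4. clipping to the signed 12-bit range [−2048, 2047] with a saturation flag.

The published gain and bit depth jointly imply a ±26.3 mV digitized span,
which is narrower than the published ±460 mV DC-coupled analog input range;
the gain staging between the two is not public. We therefore treat the gain
as the effective programmable-AFE gain, keep both numbers configurable, and
clip at the bit-depth range. `lsb_to_mv` inverts the gain; for a noiseless
in-range DC input the round-trip error is bounded by half an LSB
(0.5/78 ≈ 0.0064 mV), which a test asserts.

## Signal generators

All generators draw from one `numpy.random.Generator` seeded per call; a
fixed seed reproduces output byte for byte. Each returns its construction
ground truth in `meta`.

**ECG** (`gen_ecg`) — one beat template per RR interval, a sum of Gaussian
bumps for P, Q, R, S, T (amplitudes 0.12, −0.12, 1.0, −0.18, 0.30 mV
relative to a 1 mV R peak; widths 28, 9, 11, 9, 50 ms; P and Q/S centered
180 and 35/32 ms from R). The k-th R peak sits at the cumulative sum of the
first k intervals. The T-wave center is placed per beat so that the
constructed QT follows QT = 0.4·√RR(s) s (i.e. QTc = 400 ms by the
QT/√RR correction). The constructed Q onset is 3.05 σ before the Q center —
the point where a Gaussian's descent reaches 5 % of its steepest slope,
matching the delineator's onset convention — and the constructed T end is
2 σ past the T center, where the tangent through the steepest downslope of
a Gaussian crosses a zero baseline. Gaussian bumps are an idealization:
real QRS complexes are asymmetric and T waves skewed, so QT delineation on
real data is harder than these tests show.

**Occipital alpha EEG** (`gen_alpha_eeg`) — fusiform spindles: a sinusoid at
f₀ ∈ [8, 13] Hz under a raised-cosine envelope (default 1 s spindle, 1 s
gap, 30 µV), over pink (1/f) background noise. A 1 s spindle at 10 Hz
carries ten oscillation peaks. The spindle frequency may be piecewise
constant in time (used by the hypoglycemia scenario).

**Frontal EEG / EOG** (`gen_frontal_eeg`) — pink background plus stereotyped
transients: blinks as 0.2 mV monophasic bumps (300 ms), saccades as smaller
biphasic waves. Events closer than 0.5 s are rejected rather than overlapped.

**sEMG** (`gen_emg`) — Gaussian noise band-limited to 10–250 Hz (truncated
at 0.45·fs when the rate cannot carry the band), multiplied by a smoothed
on/off gate from the contraction schedule; contraction RMS equals `amp_mv`.

**Glucose** (`gen_glucose`) — a piecewise-linear decay sampled once per
minute. Analysis time t = 0 is the first crossing below the alarm threshold
(default 80 mg/dL); the crossing of the drift-onset level (default
100 mg/dL) is recorded alongside. The default profile holds the 120 mg/dL
target for 30 min, then declines at 20 mg/dL per 90 min to 70: it crosses
100 mg/dL 90 min before the alarm.

**Night scenarios** (`compose_night`) — a hypnogram of WAKE/NREM/REM blocks
drives stage-conditional statistics:

| stage | RR (ms)            | EMG tone (rel.) | eye events/min |
|-------|--------------------|-----------------|----------------|
| WAKE  | 850 ± 40           | 0.5             | 6              |
| NREM  | 1100 ± 30          | 0.2 (residual)  | 0.2            |
| REM   | 1000 baseline with bursts to a 750 ms floor | 0.005 (atonia) | 25 |

REM heart-rate bursts follow a 120 s cycle: a 5 s ramp down, a 65 s hold at
the 750 ms floor, a 5 s ramp up, then baseline. The hold exceeds two 30 s
scoring epochs so that at least one full epoch sits at the floor — the
80 bpm burst ceiling is then recovered exactly by the epoch-wise heart-rate
estimate, regardless of epoch-grid alignment. An NREM segment at mean RR
1100 ms reads below 55 bpm (the mean of 60000/RR exceeds 60000/mean(RR)
slightly, by Jensen's inequality, but stays ≈ 54.6 bpm at 30 ms jitter).

**Hypoglycemia night** (`gen_hg_night`) — ECG + alpha EEG + glucose over the
default ≈ 4.4 h profile. The RR sequence is 950 ms with deterministic LF
(0.1 Hz) and HF (0.25 Hz) modulation plus white jitter; when glucose falls
below the drift-onset level the LF amplitude steps 20 → 70 ms and the
jitter 15 → 40 ms, stepping up both rolling SDNN (≈ 27 → ≈ 65 ms) and
LF:HF (≈ 0.8 → ≈ 4). Fifteen minutes before the alarm the spindle
frequency steps 10 → 12 Hz, stepping the alpha-band centroid frequency.
The 2 Hz step is chosen so the detector's threshold lies at half the step,
centring the onset estimate on the injection time.

## Conditioning

Filters are 4th-order Butterworth (the 50 Hz notch is a second-order IIR,
Q = 30), applied forward-backward (zero phase) after one second of reflect
padding, so event times are not displaced and edges do not ring. Presets
carry the platform's printed band edges: ECG 1–35 Hz, occipital alpha
8–13 Hz, frontal 1–3 Hz, sEMG high-pass 3 Hz / envelope low-pass 10 Hz.
(The frontal 1–3 Hz channel is named `frontal`, not "beta", since the
conventional beta band is 13–30 Hz; the preset implements the printed
band.)

The sEMG envelope is the four-step chain in fixed order: 3 Hz high-pass
with 50 Hz notch → full-wave rectification → 10 Hz low-pass → peak
normalization to [0, 1]. Steps 2 and 3 deliberately do not commute
(low-passing a zero-mean 10–250 Hz carrier before rectification leaves
almost nothing); a regression test pins the order. For a sinusoidal carrier
of amplitude a the pre-normalization plateau is the full-wave-rectified
mean 2a/π. Normalization is per-record peak normalization; an all-zero
record is returned unchanged with a flag rather than divided by zero.

## Features

* **R peaks** — derivative → squaring → 150 ms moving-window integration →
  peak picking with a 200 ms refractory period and an adaptive threshold
  (fraction of the 99th-percentile energy), then snapping to the local
  maximum of the input. Flatline input yields an empty, flagged series.
* **RR gating** — intervals outside [300, 2000] ms are excluded before any
  variability statistic.
* **SDNN** — sample (n−1) standard deviation of RR in ms. **RMSSD** —
  RMS of successive differences. Fewer than 2 (3) intervals → NaN sentinel.
* **LF:HF** — tachogram linearly resampled at 4 Hz, Welch (Hann, 2 min
  segments, 50 % overlap), trapezoid band powers over the conventional
  LF 0.04–0.15 Hz and HF 0.15–0.40 Hz bands; all bands configurable.
* **QT/QTc** — Q onset by the 5 %-of-steepest-slope walk-back within 80 ms
  before R; T end by the tangent method on the T downslope; QTc = QT/√RR(s).
  Undelineatable beats are skipped, not guessed.
* **Spectral moments** — Welch (4 s, Hann, 50 %) restricted to a band;
  Gₙ = ∫ fⁿP(f) df by trapezoid; centroid frequency CF = G₁/G₀ and
  rotational radius √(G₂/G₀). Closed forms used as test oracles: a flat
  spectrum on (0, W) has CF = W/2 and radius W/√3; two equal lines at 8 and
  12 Hz give CF = 10 Hz and radius √104 ≈ 10.198 Hz.
* **EMG activations** — hysteresis on the normalized envelope (on at 0.2,
  off at 0.1 of the maximum), minimum burst duration 0.5 s.
* **EOG activity** — per-epoch RMS against k (default 3) times the 25th
  percentile of epoch RMS (the quiet-background level).

## Screening

**Pre-hypoglycemia onset.** Rolling features (default 5-min windows, 60 s
steps) are screened per metric: baseline mean/SD from the earliest quiet
segment (default first 30 min), onset at the first sustained departure
beyond k = 2 SD (two-sided). Two robustness choices matter:

* the SD is floored at 5 % of the baseline mean, so a numerically locked
  baseline (a synthetic centroid frequency with sub-millihertz scatter)
  does not flag sub-percent fluctuations;
* *persistence counts independent windows*: the required run length is the
  configured persistence (3) plus the window/step overlap factor minus one.
  With overlapping windows, three consecutive exceedances are one excursion
  seen three times, not sustained evidence; scaling by the overlap factor
  restores the intended meaning and reduces exactly to the plain
  three-window rule for non-overlapping windows.

The onset time is the midpoint of the first window of the run, and the
result reports pre- and post-onset means (the "trend line" convention) plus
the lead time to the glucose alarm crossing in minutes.

**REM screening.** On 30 s epochs (the sleep-scoring convention), an epoch
is a REM candidate iff three flags coincide: heart-rate bursts (epoch max
instantaneous HR ≥ 80 bpm, or epoch HR SD above 3× the night's median epoch
SD), eye activity (EOG RMS flag), and masseter atonia (epoch median
envelope < 0.05). Candidates are merged across gaps up to one epoch and
episodes shorter than 5 min are dropped — shorter than the ~15–17 min
episodes of interest, longer than single-epoch noise. The narrative source
of this rule is not algorithmic; the conjunction + merge + minimum-duration
formalization, with every threshold in config, is this package's contract.

**Agreement report.** `discrepancy_report` computes 100·|device − gold|/gold
per metric with a NaN sentinel for a zero reference, plus the maximum.

## Problem sizes and tolerances

Tests and the acceptance script run everything at desk scale, chosen as the
smallest sizes at which the estimators are stable: the hypoglycemia night is
the default ≈ 4.4 h scenario at 240 Hz; the REM night is 70 min (two REM
blocks of 17 and 15 min between NREM blocks); HR-regime segments are 10 min;
fixture records are tens of seconds. Stochastic recovery tolerances follow
the screening grids: ±2 analysis windows for onset leads, ±1 epoch for
episode durations, ±1 bpm for epoch heart rate.

## Known limitations

* Generators emulate the *statistical structure* the analyses assume, not
  real physiology: no electrode–skin impedance or motion artifacts, no
  mains interference unless added explicitly, stationary noise within a
  stage, idealized beat morphology. Passing recovery tests shows the
  pipeline is self-consistent, not that it is validated on patients.
* Sleep staging is deliberately coarse (WAKE/NREM/REM only, no N1–N3); the
  REM screener returns "REM-candidate" intervals, not a diagnosis.
* The onset detector assumes a quiet early-night baseline; it will not
  handle a drift already in progress at recording start.
* EDF export writes plain EDF (16-bit, 1 s records, integer sampling
  rates); EDF+ annotations are out of scope.
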