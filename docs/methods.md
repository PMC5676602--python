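# Methods

This note records the models implemented by `bansim`, the defaults that
matter, and what the tests do and do not establish.

## Latency model

A monitoring application is a DAG of tasks with data flows; only the
compute chain t2..t6 carries cost.  Acquisition (t1) and the sinks
(t7 visualization, t8 store, t9 alarm) default to zero compute cost: the
reference timing table prices only the five processing stages, and the
sinks are I/O-bound.  Costs are seconds **per user** on a reference device;
a device with speedup `s` executes the same task in `cost/s`.  Accelerators
are *absolute* per-task cost overrides, not multipliers — the published
laptop wavelet-stage figure (0.0026316 s) is a measured value with no
stated factor, so storing the absolute number reproduces the table without
inventing one.

For `n` monitored users, a stage on a per-user (worn) device contributes its
per-user cost once — every athlete's own device works in parallel — while a
stage on a shared staff device contributes `n × cost`, serialized.  This
rule is the module's central semantic; it exactly reproduces the published
multi-athlete totals (e.g., 11 × 0.02/3.93 = 0.0559796 s).  Totals keep full
floating precision internally and round to 7 decimals only for display;
the reproduction tolerance is 1e-6 s absolute, because the printed tables
themselves carry last-digit rounding differences.

Communication delay is excluded from totals by default (the reference tables
are compute-only); link feasibility is checked separately as
`n_users × 8 × rate_KB/s ≤ link capacity`, with link capacities taken from
the configuration as printed, even where the printed WLAN figures disagree
with the real standards' rates.

The real-time deadline derives from the maximum physiological heart rate:
`deadline = floor(100 × 60/max_hr)/100` — truncation, not rounding, so
220 beats/min gives exactly 0.27 s.

### Assignment search

Valid assignments pin acquisition to a worn (B-class) device, exclude
environmental sensors and non-computing wearables, and enforce monotone
outward flow: once a task runs on a shared device, no successor returns to
the BAN.  `enumerate_assignments` is exhaustive (guarded at 12 compute
tasks ≈ 500k+ candidate mappings for 3 devices); `best_assignment` minimizes
total latency with ties broken toward keeping more stages on the BAN
(processing raw bio-signals nearest the user), then lexicographically.
Exhaustiveness is what makes the enumerator usable as a brute-force oracle
in the tests.

## Reference ECG pipeline

The published case study names algorithm families but no parameters; the
implementations are standard desk-scale choices, all configuration-exposed:

| stage | method | default | why |
|---|---|---|---|
| t2 | zero-phase Butterworth band-pass, order 4 | 0.5–40 Hz | standard monitoring band |
| t3 | IIR notch (Q=30) + median-filter baseline subtraction | 50 Hz, 0.6 s kernel | powerline + wander removal |
| t4 | Hilbert-envelope peak picking, adaptive threshold mean + k·SD | k=1.5, 2 s window | envelope peaks at R for QRS-dominated signals |
| t4 | detector refractory | **0.2 s** | see below |
| t5 | periodized orthogonal Daubechies DWT, energies per subband | db4 (8-tap), 4 levels | orthogonality gives exact Parseval |
| t6 | heart-rate threshold band; optional RR-CV rule | [40, 200] beats/min | staff-alert band |

**Refractory choice.** The physiological minimum RR interval (0.27 s at
220 beats/min) is the *deadline* bound, and is kept as a named constant.
It is deliberately **not** the detector refractory: a detector that refuses
peaks closer than 0.27 s aliases any rhythm above ~222 beats/min to half
rate (every other beat suppressed), which would silently mask exactly the
extreme tachycardias the monitor exists to flag.  Detection uses the
field-standard 200 ms refractory instead; 0.27 s can still be passed
explicitly where the physiological bound is the point.

**Wavelets.** No discrete wavelet transform ships with the assumed
scientific stack, so a minimal periodized DWT is implemented here: circular
convolution + downsampling with orthonormal Daubechies filters, inputs
zero-padded to a multiple of 2^levels (zero padding adds no energy).  Each
level is an orthogonal map, so subband energies sum to the window energy to
machine precision — the property the feature tests assert — and single-level
perfect reconstruction is property-tested against random inputs.

**Streaming.** `process_stream` filters once, detects once, then assigns
each whole second the most recent beat's instantaneous heart rate
(60/RR of the latest beat ending at or before that second); seconds before
the first RR interval report `no_beat`.  Alarms fire on non-normal verdicts
only.  The SQLite store is rebuilt from scratch per run and the event log is
written with sorted keys, making both byte-deterministic for a fixed input
and configuration.

### Host calibration

`calibrate_cost_model` times each stage on a sample signal, takes the
**median** over repetitions (robust to scheduler jitter) and normalizes per
second of signal, yielding a cost model with the host as reference device.
Per-task cost tracks signal length only once array work dominates fixed
per-call overhead; filter design is therefore cached, and the scaling test
uses 60 s vs 120 s signals.

## Synthetic data

The generator emulates the acquisition side of a monitored session:
per-athlete ECG, 1 Hz telemetry packets (heart rate, GPS on a 105 × 68 m
pitch via a velocity-damped random walk capped at sprint speed, cumulative
distance, minutes played) and per-minute ambient readings.  Defaults: 11
athletes, 250 Hz sampling (desk-scale, above the analysis bands), 75
beats/min baseline, noise of 0.05 mV baseline wander + 0.02 mV powerline +
0.01 mV white noise; injected episodes default to 230 beats/min
(tachycardia), 35 (bradycardia) or beat removal (flatline).

ECG morphology is a fixed five-Gaussian template (P, Q, R, S, T) placed at
beat times integrated from a piecewise-constant HR profile, with non-R bump
offsets/widths compressed when the local RR is short.  The first beat is
placed at t = 0.3 s so the full template fits the record (a beat at t = 0
is half-truncated and its envelope peak shifts ~44 ms — a generator
artifact, not a detector property).  R times are therefore exact ground
truth, which is what the detection-quality gates score against.

What this generator does **not** emulate: physiological heart-rate
variability, pathology-specific morphologies, motion artifacts, electrode
noise or inter-lead differences (a single synthetic lead is produced).  A
green detection gate therefore establishes correctness of the pipeline
plumbing and threshold logic on idealized morphology — not clinical
detection performance.

## Numerical and degenerate-input choices

- Latency totals: full precision internally, 7-decimal display, 1e-6 s
  reproduction tolerance; deadline comparison is `total ≤ deadline`.
- Topological order and assignment enumeration are deterministic
  (lexicographic tie-breaks) so reruns are identical.
- Flatline input → zero detected peaks; empty segment lists and missing
  heart rates raise typed errors rather than guessing.
- All randomness flows through `numpy.random.default_rng` seeded from the
  session spec; distinct athletes derive distinct streams from the one seed.

## Known limitations

- The latency model is deterministic and compute-only: no queueing,
  preemption, pipelining across stages, energy/battery modeling or radio
  effects.  An optional volume/bandwidth transmission term exists in the
  flow model but is off by default for fidelity to the reference tables.
- Only static (design-time) partitioning is implemented; on-the-fly
  repartitioning is out of scope.
- One published 26-athlete configuration splits one stage across two devices
  in a way that is not recoverable from the stated costs; it is excluded
  from reproduction.
- The anomaly stage is a threshold band (plus optional RR-variability rule),
  not a clinical classifier.
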