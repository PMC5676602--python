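# Case-study fixture: measured per-task costs, device speedups, WLAN links
# and monitoring contexts for the sudden-death detection pipeline.
# Base costs are seconds per user on the reference smartwatch (b2); the
# laptop (m2) carries a DSP accelerator for the wavelet stage t5, expressed
# as an absolute measured cost.

acquisition_rate_kbps: 1.0

cost_model:
  reference_device: b2
  base_costs:
    t2: 0.0000228
    t3: 0.0001824
    t4: 0.0200000
    t5: 0.1800000
    t6: 0.0223440

devices:
  - device_id: b1        # chest strap: senses only, no computing capability
    device_class: B
    can_compute: false
  - device_id: b2        # smartwatch (ARM A7 @ 1.4 GHz) — reference device
    device_class: B
    speedup: 1.0
  - device_id: m1        # coach's tablet (Snapdragon 820 @ 2.15 GHz)
    device_class: M
    speedup: 3.93
  - device_id: m2        # staff laptop (i7-7660U @ 2.50 GHz) + DSP hardware
    device_class: M
    speedup: 4.56
    accelerators:
      t5: 0.0026316
  - device_id: e1        # environmental sensor (sends data only)
    device_class: E
  - device_id: e2        # thermometer (sends data only)
    device_class: E

links:
  - {technology: 802.11n,  data_rate: "600 Kbps", range_m: 30}
  - {technology: 802.11ac, data_rate: "1.3 Mbps", range_m: 30}
  - {technology: 802.11ad, data_rate: "7 Gbps",   range_m: 10}
  - {technology: 802.11ah, data_rate: "100 Kbps", range_m: 1000}

contexts:
  A: {n_users: 1,  deadline: 0.27}   # single athlete, training
  B: {n_users: 11, deadline: 0.27}   # one team in a training session
  C: {n_users: 26, deadline: 0.27}   # match: two teams + four referees

assignments:
  all_b2:   {t1: b2, t2: b2, t3: b2, t4: b2, t5: b2, t6: b2}
  all_m1:   {t1: b2, t2: m1, t3: m1, t4: m1, t5: m1, t6: m1}
  all_m2:   {t1: b2, t2: m2, t3: m2, t4: m2, t5: m2, t6: m2}
  # preprocessing on the BAN, analysis on the tablet
  fig3b:    {t1: b2, t2: b2, t3: b2, t4: m1, t5: m1, t6: m1}
  # everything but anomaly detection on each smartwatch
  fig3c:    {t1: b2, t2: b2, t3: b2, t4: b2, t5: b2, t6: m1}
  # split between tablet and DSP-accelerated laptop
  fig3d:    {t1: b2, t2: b2, t3: b2, t4: m1, t5: m2, t6: m2}
  # context-C variants: computing outsourced to the laptop
  fig3b_out: {t1: b2, t2: b2, t3: b2, t4: m2, t5: m2, t6: m2}
  fig3c_out: {t1: b2, t2: b2, t3: b2, t4: b2, t5: b2, t6: m2}

pipeline:
  low_cut: 0.5
  high_cut: 40.0
  notch_freq: 50.0
  refractory: 0.2
  wavelet: db4
  levels: 4
  hr_low: 40.0
  hr_high: 200.0
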