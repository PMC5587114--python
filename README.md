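# hcasim

A desk-scale digital twin of an RFID-baseplate home-cage monitoring system
for group-housed rats.

Continuous monitoring of activity and body temperature in rats normally
forces single housing, which changes the behaviour being measured. One
alternative instrumented the *home cage* instead: each rat carries a small
subcutaneous RFID transponder (ID + temperature), the cage sits on a
baseplate containing 12 transceiver coils polled sequentially, and an
infrared side-view camera records whole-cage video from which vertical
(rearing-like) activity is extracted. `hcasim` reimplements that whole
acquisition-and-validation pipeline as a simulator plus analytics library,
so the system's tracking rules, detection physics and validation
statistics can be exercised, calibrated and tested end-to-end without
animals or hardware:

* **cohort generator** (`hcasim.cohort`) — bounded correlated random walks
  with rest bouts, circadian modulation (12:12 photoperiod, dark:light
  activity ratio 1.4), posture events (rearing/climbing), implant-site tag
  poses, subcutaneous temperature (37.5 °C baseline, +0.5 °C dark phase)
  and husbandry perturbations (cage change, gavage, single housing);
* **baseplate reader** (`hcasim.baseplate`) — sequential polling (75 ms
  activation, 90 ms slot, 1080 ms cycle ⇒ 0.93 Hz per-tag ceiling),
  tag–coil coupling via the exact circular-loop field projected on the tag
  axis, a 60 ms charge-dwell requirement, strongest-tag collision rule and
  clamped/quantized temperature reads;
* **tracking** (`hcasim.tracking`) — flicker filtering (2-consecutive
  confirmation), gap interpolation with provenance flags, transition and
  distance binning, temperature binning;
* **video motion** (`hcasim.video`) — synthetic side-view rendering, frame
  differencing, vertical-activity episodes above an 8 cm line, and
  per-individual episode attribution from the RFID tracks;
* **statistics** (`hcasim.stats`) — ICC(1,k) and ICC(A,k), Bland–Altman
  limits of agreement, OLS, a single-random-intercept REML mixed model,
  negative-binomial counts regression, paired t-test, the implant-site
  scoring rubric and light/dark summaries.

## Core quantities

With one-way ANOVA mean squares BMS (between subjects) and WMS (within),
the average-measures intraclass correlation is

    ICC(1,k) = (BMS − WMS) / BMS

Bland–Altman agreement between paired measurements x, y uses d = x − y:

    bias = mean(d),   LoA = bias ± 1.96 · sd(d)

The mixed model `y = Xβ + u[rat] + ε`, `u ~ N(0, τ²)`, `ε ~ N(0, σ²)` is
estimated by REML with the variance ratio λ = τ²/σ² profiled out by 1-D
bounded optimization. Tag–coil signal strength is
`field_scale · gain · |B(r)·axis|` with `B` the exact field of a circular
current loop (complete elliptic integrals); a tag is read when this stays
above the calibrated threshold for ≥ 60 ms of a 75 ms activation and the
tag is the strongest candidate on that activation.

## Worked example

`examples/` contains one short narrative script per capability. For
instance `python examples/02_baseplate_reads.py` prints:

```
theoretical ceiling: 0.926 Hz per tag
pre-upgrade :  32982 reads over 4 h; per-tag rates 0.752, 0.782, 0.756 Hz
post-upgrade:  36953 reads over 4 h; per-tag rates 0.860, 0.865, 0.840 Hz
```

Three simulated ventral-midline rats read at ~0.75 Hz per tag — the
calibration point of the shipped coupling constants — and the "shielding
upgrade" (a coupling gain) moves them toward the 0.93 Hz ceiling; the
remaining gap is collision drop-out between cage mates. And
`python examples/05_agreement_stats.py` validates baseplate tracking
against the ground-truth path exactly the way the hardware was validated
against manual tracking:

```
paired 15-min distance bins: n=12, methods k=2
ICC(1,k) = 0.837   (BMS 170805, WMS 27868)
Bland-Altman bias -62 cm, LoA [-528, 404] cm
mean read rate 0.761 Hz
rubric scores: {'read_frequency': 5, 'tracking_icc': 4}
```

The negative bias is the truncation of centroid-snapped tracking; the ICC
near 0.84 says both routes rank active and quiet periods the same way.

A command-line pipeline wraps the same functions for shell use:

```
hcasim simulate --out session --seed 1 --duration 3600
hcasim reads    --out session --seed 1 --duration 3600
hcasim track    --out session --seed 1 --duration 3600
hcasim analyze  --out session --seed 1 --duration 3600
hcasim report   --out session
```

## Documentation

`docs/methods.md` describes the models, their assumptions, the calibrated
constants and the known limitations of the synthetic data.
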