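# Methods

This note documents the models behind `hcasim`, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Clock and cage conventions

Time zero is lights-on; the light phase occupies the first
`photoperiod_h[0]` hours of every 24 h day (default 12:12). The cage floor
is a 50 × 38 cm rectangle matching the baseplate; positions are in cm with
the origin at one plate corner and x along the 50 cm axis.

## Cohort generator

**Movement.** Each animal is a bounded correlated random walk on the cage
floor: while "active", steps occur as Bernoulli events per 0.1 s timestep
with rate `base_step_rate_hz` (0.9 steps/s) multiplied by the circadian
intensity — 1 in the light phase, `dark_light_activity_ratio` (1.4) in the
dark — and by any perturbation multiplier. Step length is |N(3, 1)| cm and
heading performs a random walk (σ = 0.6 rad per step). Walls reflect
(billiard fold), which preserves step lengths. Rest/active alternation is
a two-state semi-Markov process with exponential bouts (means 150 s rest /
60 s active, phase-independent by default). Because rest structure is
phase-independent and only the step *rate* is modulated, the expected
dark:light step-count ratio equals the configured ratio exactly; the test
suite verifies recovery within Monte-Carlo error.

**Postures.** Rearing and climbing are Poisson events with
phase-dependent rates (rearing 12/h light, 25/h dark; climbing 2/h, 5/h;
durations 2 s and 4 s). These rates are not published values; they are
configurable declarations chosen to give a realistic nocturnal rearing
pattern. Vertical events change the tag pose (and the rendered silhouette)
but do not suppress stepping, so they cannot bias the step-count ratio.

**Tag pose.** Each implant site preset provides a per-posture effective
tag height, a canonical axis (horizontal along the body, or vertical), and
a lateral offset (3 cm for flank sites). The axis is yawed by the heading
and wobbles in pitch with a slow AR(1) process (σ = 12°, τ = 2 s) — real
tags are never held at an exact orientation, and this wobble is what lets
a horizontally implanted tag couple to the strong vertical field directly
above a coil. The preset heights are **calibration constants** (see
below), not measured anatomy: in particular the two flank presets share an
anatomical region but differ in effective height because the effective
height absorbs orientation and posture detail the simulator does not
model explicitly.

**Temperature.** Two-level mean (37.5 °C light, +0.5 °C dark — the
alternative 0.25 °C light-phase deficit reported by the fitted regression
on the real data can be configured via `temp_dark_elevation_c`), plus a
stable per-animal offset N(0, 0.15 °C) and AR(1) noise (σ = 0.15 °C,
τ = 600 s). The dark elevation switches instantaneously at the phase
boundary; 15-min analysis bins align with that boundary, so binned phase
means are unbiased. The series never approaches the transponder's
33–43 °C recording range under default parameters, so clamping never
triggers spuriously.

**Perturbations** transform the generator *schedule* before sampling:
cage change multiplies the step rate ×3 for 45 min (configurable within
the reported 30–60 min), gavage ×2.5 for 10 min, and single housing
subtracts 0.5 °C for its duration (default 16 h). Outside its window an
event is the identity on the schedule. They are not applied to
already-sampled paths, because inserting steps into a sampled path would
displace every later position — the schedule-level definition is the one
that keeps "unchanged outside the window" exactly true.

## Baseplate reader

**Schedule.** 12 antennae in a 3 × 4 grid are polled in a row-major
serpentine order, 75 ms activation inside a 90 ms slot; the 15 ms settle
gap reconciles the printed 75 ms × 12 activations with the 1080 ms total
cycle. The per-tag ceiling is one read per cycle = 0.926 Hz (printed as
0.93 Hz).

**Coupling.** Signal strength is
`field_scale · gain · |B(r) · axis|` where `B` is the exact magnetostatic
field of a horizontal circular loop (radius 5 cm) evaluated via complete
elliptic integrals. A point-dipole approximation was tried first and
rejected: its horizontal-axis coupling `3hd/|r|⁵` peaks near `h = d/2`
(≈3 cm at the 12.5 cm coil pitch), making read rates nearly
height-insensitive over the anatomically relevant 2–7 cm — the observed
strong advantage of low implant sites is then unreachable. The loop field
restores the physics that matters: near the plate the field concentrates
around the winding and decays steeply with height. It also reproduces the
qualitative orientation pattern: a vertical tag couples best directly
above a coil, a horizontal tag best between adjacent coils.

**Detection.** A per-activation multiplicative lognormal noise term
(σ = 0.4) models interference and unresolved pose detail; a tag is
readable when its (noisy) coupling stays above `read_threshold`
continuously for at least `min_dwell_ms` = 60 ms (the transponder charge
time), discretized as `run_samples × dt ≥ min_dwell − dt/2` (a
half-sample guard, exact at the 10 ms sweep resolution used for
verification; readstream simulation samples each activation at 5
sub-points, i.e. 15 ms). Among readable tags only the strongest
(time-averaged coupling) is reported on an activation, and each tag is
reported at most once per cycle, on its strongest antenna — so a tag may
appear on adjacent antennae across cycles, and a weaker cage mate near
the same coil drops out, both emergent rather than scripted.

**Temperature reads** add truncated-uniform ±0.5 °C error, clamp to the
33.0–43.0 °C recording range (clamped values are flagged and excluded
from binned means, so drop-out statistics stay independent of
temperature) and quantize to 0.1 °C. Because the uniform error spans
exactly ten quanta, quantization introduces no bias.

**Calibration.** `field_scale` is fixed at 1; `read_threshold` (0.05),
`coupling_noise_sd` (0.4), `shielding_gain` (2.6) and the per-site
walking heights (ventral 2.0, flank-vertical 3.3, flank-horizontal 6.0,
interscapular 7.0 cm) were fitted once by the coarse grid search in
`hcasim.calibrate` so that 24 h simulated 3-rat cages reproduce the
reference per-site read rates (0.74 Hz ventral midline pre-upgrade, with
the other sites ~0.10/0.30/0.44 Hz lower, strictly ordered). The fitted
constants ship in `hcasim/data/calibration_v1.json` and are the
`CouplingModel` defaults. With three co-housed tags the shielding gain
raises the ventral rate by ~0.10 Hz; a single-tag cage reaches ~0.89 Hz
post-upgrade. The residual gap to the reported in vivo upgrade effect
(+0.14 Hz) is the collision floor of the strongest-tag rule under
independent (non-avoiding) animal positions.

## Tracking

Antenna assignments live on the scan-cycle grid. A change of antenna is
accepted only when confirmed by the immediately following read on the
same new antenna (2-consecutive rule; idempotent, removes pure A/B
flicker, passes genuine moves with one cycle latency; a majority-of-3
variant sits behind a config switch). Positions snap to antenna
centroids; read gaps ≤ 5 s are filled by linear interpolation and flagged
`interpolated`; longer gaps stay `missing`. Every sample carries a
provenance flag (`read`/`filtered`/`interpolated`/`missing`) and the raw
assignment is retained, so the raw stream is recoverable. Transitions are
counted on filtered labels (raw transitions overcount stationary animals)
and distance sums centroid-to-centroid segments. Consequences, both
verified by tests: baseplate distance systematically *underestimates* the
true path (truncation), and residual false transitions from boundary
flicker are phase-independent, which **dilutes the measured dark:light
contrast** (≈1.17 measured vs 1.4 configured in a default week). For that
reason parameter-recovery analyses use the idealized nearest-antenna
track (`tracks_from_truth`) when the question is about the generator, and
the full noisy chain when the question is about the measurement system —
mirroring the fact that the real system's baseplate-derived contrast also
differed from its video-derived contrast.

## Video motion

The renderer is orthographic (side view, depth ignored): a static
background with a tunnel fixture, one filled ellipse per rat (16 × 6 cm
walking, narrower and 11–13 cm tall when reared, with a deterministic
triangular height sway of ±2 cm so that a reared rat is visible to a
*motion* detector on every frame), optional additive Gaussian pixel noise
(σ = 1 intensity unit on an 8-bit scale — small enough that a differenced
pixel essentially never crosses the threshold by chance). Synthetic
resolution is 320 × 180 at 25 fps; the analytics are
resolution-independent given the cm-per-pixel calibration.

Detection: a frame is *vertical* when any differenced pixel above the
8 cm line (image row from the camera calibration) exceeds the intensity
threshold (default 10); quiet gaps shorter than `min_frames` (3 ≈ 120 ms)
are bridged and only runs of ≥ `min_frames` vertical frames become
episodes. Neither threshold is a published value; both are declared
defaults. Episodes are attributed to the animal whose track x-position is
nearest the motion centroid at mid-episode; exact ties or missing track
positions leave the episode unassigned. On noise-free fixtures with a
known rearing schedule, episode recall/precision and frame accuracy are
exact (100%), because the expected frame labels can be derived from the
schedule by episode arithmetic (the rise is visible on the first reared
frame, the fall one frame after the last).

## Statistics

* **ICC(1,k)** `(BMS − WMS)/BMS` from the one-way ANOVA decomposition;
  zero total variance is reported as undefined. The label "average
  absolute agreement" mixes two naming systems, so the two-way
  **ICC(A,k)** `(MSR − MSE)/(MSR + (MSC − MSE)/n)` is provided as an
  option; both are cross-checked against an independent implementation in
  the tests.
* **Bland–Altman**: bias ± 1.96 sample SD of paired differences.
* **OLS** with treatment coding (reference = first level alphabetically;
  the original coding is unstated); rank-deficient designs raise an error
  naming the first aliased term.
* **Random-intercept mixed model**: REML, with λ = τ²/σ² profiled out by
  bounded scalar optimization on log λ and a GLS inner solve; the λ = 0
  boundary is checked explicitly so τ̂² ≥ 0. REML (rather than ML) was
  chosen; the original choice is unstated. One grouping factor suffices
  for every model used here; a single-group input falls back to OLS with
  a warning flag. The model printed as ending "+1" alongside text calling
  the rat a random factor is implemented with a rat random intercept.
* **Negative binomial** (NB2, log link) for over-dispersed transition
  counts, via maximum likelihood.
* **Paired t**: identical inputs have zero-variance differences and raise
  an undefined-statistic error rather than returning t = 0.
* **Rubric** bands are implemented as half-open `[lower, upper)`
  intervals, so a boundary value belongs to the band it opens (the
  printed strict inequalities leave boundaries undefined); the mapping is
  total and monotone.
* **Light/dark summaries** report per-animal and cage-level phase means,
  dark−light differences and dark:light ratios; a zero light-phase mean
  yields an undefined ratio, reported as such.

Wald SEs quantify estimation error given the data; in parameter-recovery
experiments the dominant error is the generator's own Monte-Carlo
variation (e.g. the realized weekly temperature deficit fluctuates by
~0.04 °C per animal-day), so recovery checks compare against empirical
Monte-Carlo SEMs computed from per-animal(-day) replicates.

## Problem sizes

Default test and acceptance runs use: 24 h sessions for read-rate
calibration (one per implant site), two 7-day 3-rat cages for circadian
recovery and truncation, 60 s video fixtures, and 200-replicate
small-panel simulations for estimator coverage. These sizes keep the full
suite fast while leaving Monte-Carlo error well below the decision bands.

## Known limitations

* No social behaviour (huddling, play fighting) or body-exclusion between
  animals; independent positions overstate tag-collision drop-out
  slightly (see the calibration note on the upgrade gain).
* No electromagnetic interactions between coils, no RF protocol
  modelling; the loop field is a single-turn approximation.
* The renderer is orthographic with no perspective, occlusion by the food
  hopper, tails, or illumination artifacts — the real system's known
  vertical-activity confounds are deliberately absent, so video accuracy
  on synthetic fixtures is an upper bound, not a field estimate.
* Passing recovery tests show the *pipeline* is self-consistent under the
  generator's assumptions; they do not validate the generator against
  real rats.
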