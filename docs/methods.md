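# Methods

## Problem and scope

`usvmap` analyses three-chamber sociability sessions in which a single test
rat explores a square arena containing two perforated stimulus containers
while an overhead microphone records ultrasonic vocalizations (USVs) and an
overhead camera records position. The package takes *detector output* (call
onset/offset and principal frequency) and *tracker output* (time-stamped
positions) as given; detecting calls from audio and tracking from video are
out of scope. Its job is everything downstream: valence classification of
calls, spatial localization of each call on the trajectory, near/distant
zonal aggregation, freezing detection, composite track/call maps, and the
group statistics, including the companion two-bottle sucrose preference
analysis.

## Coordinate and time conventions

Coordinates are centimetres with the origin at the arena's lower-left
corner, y up; times are seconds from session start. The default apparatus is
a 60 × 60 cm arena split by two partition walls into two chambers and a
12 cm central corridor, with one 15 × 20 cm container per chamber placed in
diagonally opposite corners (stimulus 1 upper-left), 2 cm off the walls.
Sessions default to 600 s at 25 Hz. The corridor width and container
placement are package choices: they are not measurable from the apparatus
description alone, so both are configurable in the arena YAML.

## Call classification

A call is **aversive** if its principal frequency lies in [19, 33] kHz *and*
its duration in [0.5, 5] s; **pro-social** if frequency lies in [40, 60] kHz
and duration in (0, 1] s; otherwise **other**. All interval bounds are
closed except the pro-social duration floor at 0; the published band
descriptions do not give open/closed notation, and the closed reading is the
least surprising, so it is pinned by tests. Calls between 33 and 40 kHz or
above 60 kHz fall in *other*, which is reported separately and excluded from
aversive/pro-social statistics. Only the detector's single principal
frequency per call is used — within-call frequency modulation is ignored.
Temporally overlapping calls are classified independently, never merged;
`overlap_fraction` reports how often intervals intersect (positive-length
intersection; calls touching only at an endpoint do not count) so users can
judge whether that independence assumption is reasonable for their data.

## Localization and zoning

Each call is placed at the trajectory position linearly interpolated at its
*onset* time plus a configurable audio/video `sync_offset` (default 0; clock
alignment hardware varies). Onsets outside the track span are kept with
status `off_track_dropped` rather than erased, so counts always reconcile.

The **near zone** is the union of the two container footprints expanded by
`near_buffer` (default 10 cm, roughly snout-reach) under the Euclidean
metric — i.e. every point within 10 cm of a container rectangle, boundary
inclusive. Everything else in the arena is **distant**. With the default
geometry the near zone covers ≈ 47 % of the floor area. Because the buffer
is a judgment call, every zonal result should be reported alongside the
buffer used; the pipeline writes it into the resolved run config.

An important caveat reproduced deliberately: the microphone hears *all*
animals, including the caged stimulus rats, yet every call is attributed to
the test animal's position. This mirrors the single-microphone recording
workflow the package targets and is a known limitation of that workflow, not
of the implementation.

## Locomotor metrics

Path length is the sum of straight segments between samples. Occupancy
weights each sample by half its interval to each neighbour (midpoint rule),
so compartment times and zone times each sum exactly to the track span;
out-of-arena samples (tracking glitches) are clamped to the boundary and
logged rather than dropped, preserving that conservation.

**Freezing** is immobility: centroid speed (central differences, then a
moving average over `smoothing_window` = 0.2 s) below `speed_threshold` =
2 cm/s for at least `min_duration` = 1 s. Commercial and free trackers use
the same construction with undocumented constants, so all three parameters
are explicit, configurable, and pinned by tests. Raising the threshold can
only increase total freezing time (tested monotonicity).

## Statistics

* **Kruskal–Wallis** (between-strain), midrank ties, H referred to
  chi-square with k−1 df; degenerate all-equal input returns H = 0, p = 1.
* **Wilcoxon matched-pairs signed-rank** (within-animal contrasts, e.g. near
  vs distant). Zero differences are dropped (Wilcoxon's original
  convention — the alternative "Pratt" handling is deliberately not the
  default). Exact null distribution for n ≤ 25 without ties, else normal
  approximation with tie correction.
* **Spearman** rank correlation: Pearson on midranks, t-approximation
  p-value; zero rank variance is flagged degenerate.
* **Mixed (split-plot) ANOVA** for the sucrose test: strain between, the
  four day/night × water/sucrose measurements within. Implemented as the
  explicit sum-of-squares decomposition (strain tested against
  subjects-within-strain; measurement and interaction against the
  within-subject residual), observation-weighted means for unbalanced
  groups; rats missing any cell are excluded with a warning. Sphericity is
  not corrected (uncorrected df are the reporting convention the package
  follows); tests cross-check the decomposition against an independent
  mixed-ANOVA implementation.
* All tests two-tailed, α = 0.05, no multiple-testing correction by default
  (a Holm helper is provided but off, matching common practice in this
  assay's literature).

The first three tests are thin, contract-enforcing wrappers over
`scipy.stats`; their calibration (type-I error within [0.04, 0.06] at
n = 12/group under seeded null simulations) and agreement with brute-force
oracles (full 2ⁿ sign-pattern enumeration, hand rank formula) are asserted
in the acceptance suite. Note the Wilcoxon exact test is discrete: at n = 12
its achievable size at nominal 0.05 is ≈ 0.042, which is why the calibration
band reaches down to 0.04.

Sucrose preference is sucrose/(sucrose+water) per rat per phase, flagged
undefined when total intake is zero.

## Synthetic-data generator

The generator exists so every stage is testable without recordings. It
emulates the *statistical structure* the analysis assumes, nothing more:

* **Movement**: a reflected correlated random walk on a 1/frame-rate grid.
  The heading mixes the previous heading (weight `step_persistence` = 0.7)
  with isotropic Gaussian noise and a drift of weight `zone_attraction`
  toward (+) or away from (−) the nearest container centre; per-frame speeds
  are gamma-distributed (shape 4) around `step_speed_mean`. Because the
  drift bias integrates over ~15 000 frames, small weights produce strong
  preferences: the presets use ±0.03, giving the sociable profile ≈ 74 % and
  the avoidant profile ≈ 23 % near-zone time with realistic between-animal
  spread. Freezing bouts interleave as an alternating exponential renewal
  process (`freeze_rate` episodes/min, mean duration `freeze_dur_mean`) and
  zero the speed. This is the simplest model able to produce the occupancy
  and zonal contrasts the analysis measures — it is not a model of rat
  locomotion.
* **Calls**: per-frame Poisson thinning. The instantaneous rate per category
  is `base_rate` (the distant-zone rate, calls/min) times
  `near_distant_ratio` when the animal is in the near zone and times
  `freezing_rate_multiplier` during freezing bouts. Durations are log-normal
  clipped into the category's band limits and frequencies uniform in the
  band, so the classifier recovers the generating label by construction;
  during freezing the aversive duration median is additionally scaled by
  `freeze_duration_scale`, which (with the rate multiplier) induces the
  positive freezing/aversive-duration coupling across sessions.
* **Presets**: `wistar_like` (sociable; pro-social 4/min near-biased 2:1,
  aversive 0.5/min) and `km_like` (avoidant; aversive 3/min distant-biased
  3:1 with freezing multiplier 3 and duration scale 1.5; pro-social 1/min).
  Rates were chosen once to give tens of calls per 10-min session — typical
  detector yields — and a clearly resolvable strain contrast at n = 12/group.
* **Sucrose**: volume = strain×phase×fluid cell mean + rat offset
  (SD 3 mL) + residual (SD 8 mL), truncated at 0. The default cell means are
  the published group means of the reference cohort (control: 2.1/2.1/8.1/
  32.1 mL; model strain: 2.5/1.4/20.1/36.4 mL for day-water/night-water/
  day-sucrose/night-sucrose); the noise SDs were set from that table's SEMs
  at n = 10–20 *before* measuring power, and kept.

Everything is a pure function of config + seed (child seeds spawned in fixed
order), so cohorts are bit-reproducible.

What passing tests on synthetic data do **not** show: the generator has no
multi-animal interaction, no caller identity (see the localization caveat),
no call-subtype structure within bands, no circadian structure beyond the
day/night cell means, and its movement statistics are only loosely
rodent-like. Parameter-recovery results demonstrate that the *pipeline*
measures what was emitted, not that real recordings satisfy the emission
model. One visible consequence: with the avoidant preset's high emission
rates, ~10–15 % of simulated calls overlap in time, higher than the 0–3 %
typical of real single-arena recordings; `overlap_fraction` makes this
auditable.

## Composite maps

Tracks are drawn at 25 % opacity and superimposed; pins mark status-ok calls
at their onset positions (blue aversive, red pro-social, gray other).
Because container sides are alternated between animals, each session is
mirrored horizontally/vertically (never rotated — the arena is square and
mirroring preserves wall identity) so its stimulus-1 container lands in the
upper-left quadrant before overlay. Mirroring is an isometry; tests assert
path length is unchanged and that the pin count equals the number of
localized calls (renderer object counts, not pixels). PNG and SVG output are
deterministic (fixed SVG hash salt, no timestamps).

## Numerical and degenerate-input choices

* Sample times must be strictly increasing; duplicate timestamps are dropped
  and counted in the load report.
* Call rows with `t_end ≤ t_start` are rejected with a warning; a call table
  whose median frequency is < 1 is refused outright (kHz/MHz confusion)
  rather than silently misclassified.
* Occupancy conservation is asserted to 1e-6 s; the ANOVA decomposition
  identity to 1e-8; CSV round-trips to 1e-9 (shortest-repr floats).
* Degenerate statistics (all-equal groups, all-zero differences, zero rank
  variance, zero error SS) return flagged results with p = 1 instead of
  raising, so batch pipelines keep running.
* The walk's reflection step is followed by a clip to the arena; a reflected
  point can only re-exit for steps longer than the arena side, which the
  speed distribution makes vanishingly rare.

## Problem sizes used in tests

The acceptance suite uses 10 000 null replicates for test calibration, 200
replicate 12 + 12 cohorts for effect-direction recovery, 200 sessions for
the coupling sign, 60–100 sessions for rate-ratio recovery, and 500
replicates for sucrose power — sizes at which the Monte-Carlo error is small
relative to every asserted margin. The acceptance script reports the same
quantities at the same or slightly smaller sizes.

## Known limitations

* Freezing constants are package defaults, not the (unpublished) values of
  any particular tracker; absolute freezing numbers are comparable only
  within a fixed parameter set.
* The near-zone buffer is a convention; zonal contrasts should be checked
  for robustness across buffer values.
* Caller identity is unresolved by design (single microphone).
* The RM-ANOVA reports uncorrected df by default; with m = 4 highly unequal
  cell variances the uncorrected within-subject p-values are
  anticonservative. A Greenhouse–Geisser corrected p is available
  (`gg=True`) but is not the headline output.
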