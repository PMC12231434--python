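# usvmap

Spatially-resolved analysis of rat ultrasonic vocalizations (USVs) in
three-chamber sociability tests.

Rodents broadcast affect ultrasonically: long, narrow-band "22-kHz" calls
(19–33 kHz, 0.5–5 s) signal a negative state, while short "50-kHz" calls
(40–60 kHz, ≤ 1 s) accompany approach and play. In a three-chamber test a
rat chooses between two containers — one holding a stranger conspecific —
and *where* it calls is as informative as *how much*: a sociability deficit
shows up as aversive calls emitted away from the social stimulus, coupled to
freezing. `usvmap` turns raw detector and tracker exports into exactly that
picture.

**Pipeline:** call tables (onset, offset, principal frequency) and trajectory
tables (t, x, y) → band classification (aversive / pro-social / other) →
localization of each call at its onset position on the track → near/distant
zonal aggregation (near = container footprint + 10 cm buffer) → freezing
detection (smoothed centroid speed < 2 cm/s for ≥ 1 s) → group statistics →
composite 25 %-alpha track maps with valence-colored call pins.

**Statistics:** Kruskal–Wallis between strains, Wilcoxon matched-pairs for
within-animal zone contrasts, Spearman correlation for freezing–call
coupling, and a two-way mixed ANOVA (strain × repeated measurement) with
per-rat preference ratios for the companion two-bottle sucrose test.

A seeded synthetic-data generator (correlated random walk with
container-directed drift, Markov freezing bouts, zone- and state-dependent
Poisson call emission, and a strain × phase × fluid consumption model) makes
every stage testable without recordings. See `docs/methods.md` for the
models, parameters, and their limits.

## Worked example

Simulate a 12 + 12 cohort of contrasting phenotypes and run the full
pipeline:

```
usvmap all --n-per-strain 12 --seed 7 --out demo
```

or equivalently in Python:

```python
import usvmap as u
out = u.run_pipeline(u.RunConfig(out_dir="demo", simulate=True,
                                 n_per_strain=12, seed=7))
```

`demo/` then contains the simulated inputs, `session_summaries.csv`,
`localized_calls.csv`, `stats.csv`, the sucrose tables, per-strain maps, and
the resolved config. Selected rows of `stats.csv` from this exact run:

```
                    test           metric                       scope statistic_name  statistic   df  p_value
          kruskal_wallis freezing_total_s between:km_like|wistar_like              H  17.287516 1/22 0.000032
          kruskal_wallis     dur_aversive between:km_like|wistar_like              H  17.280000 1/22 0.000032
wilcoxon_near_vs_distant     dur_aversive                     km_like              W   0.000000   12 0.000488
```

Reading: the avoidant cohort froze more and accumulated more aversive call
duration than the sociable cohort (Kruskal–Wallis H ≈ 17.3, p ≈ 3 × 10⁻⁵ at
n = 12 + 12), and within the avoidant strain aversive call duration was
concentrated in the distant zone (Wilcoxon W = 0, p < 0.001 across 12
animals). The per-strain means behind these tests (from
`session_summaries.csv`) show the spatial asymmetry directly: avoidant
animals spent 113 s of 600 s near the containers and emitted 40.8 s of
aversive calling in the distant zone vs 3.7 s near; sociable animals spent
408 s near and emitted almost no aversive calls anywhere.

The sucrose ANOVA on the simulated two-bottle data (`sucrose_anova.csv`)
gives strain F(1, 28) = 9.4 (p = 0.005) and a strain × measurement
interaction F(3, 84) = 4.6 (p = 0.005): the model strain's excess intake is
specific to daytime sucrose, not a general consumption shift.

To analyze real exports instead, list them in a sessions CSV and run
`usvmap analyze sessions.csv --sucrose sucrose.csv --out results`; column
dialects, arena geometry, band edges, the near buffer and freezing constants
are all overridable (`usvmap analyze --help`).

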