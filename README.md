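# waggledance

Tools for studying the spatial organisation of the honey-bee dance floor:
a simulator for the *waggle drift* motion of dancing bees, a processing
chain that turns marker-based trajectory detections into dances and
dance-following events, and the spatial/circular statistics that describe
how dances advertising different food sources separate on the comb.

## Background

A forager advertising a food source performs repeated *waggle phases* —
straight oscillating runs whose body angle encodes the direction to the
source — separated by return loops.  The return loop does not bring her
back exactly to the previous start point: successive waggle-phase start
points are displaced, on average, *forward along the waggle direction*.
Modelling each dance as a random walk with per-step displacement

    forward  ~ N(mu_f, sigma_f)   along the waggle direction alpha,
    sideways ~ N(0,   sigma_s)    orthogonal to it,

(defaults `mu_f = 0.80834 mm`, `sigma_f = 7.30946 mm`,
`sigma_s = 8.15597 mm`, with out-of-comb proposals rejected and redrawn)
reproduces a striking property of real dance floors: waggle phases end up
displaced from the dance-floor centre *in the direction they point*, so
dances advertising opposite directions drift apart and partition the dance
floor into subregions.  The package quantifies this with the alignment
statistic

    score = unit(p - c) . (cos alpha, sin alpha),

the dot product between a phase's unit offset from the overall median
phase location `c` and its waggle direction, tested with a one-sided sign
test.

Downstream, the package implements the full event-detection chain used on
real tracking data: per-bee tag-rotation correction, single-frame gap
interpolation, ego-motion features, single-linkage clustering of waggle
phases into dances (3 cm / 5 s) with a deterministic RANSAC angle
consensus (60% inliers), dance-event extraction from behaviour-classifier
probabilities (>= 4 s, gaps <= 3 s), attendee/follower detection (within
14 mm, facing the dancer, >= 1 s), dance-to-feeder assignment (feeder
visit within the preceding 5 min), and the group-separation, target-map
and choice-situation statistics.  A seeded synthetic-scene generator with
full ground truth makes every stage testable end to end.

## Worked example

Simulate 2,000 dances of 20 waggle phases with the default drift
parameters and summarise the alignment statistic:

```sh
waggledance simulate-drift --seed 1 --out drift_phases.csv
```

```json
{
 "center_mm": [79.37134062568359, 160.51618803340324],
 "n_phases": 40000,
 "n_at_center": 0,
 "median_alignment": 0.27106002512714955,
 "n_positive": 23735,
 "n_nonzero": 40000,
 "sign_test_p": 2.5080170983091685e-307,
 "mean_forward_mm": 0.7366008861689994
}
```

Reading the output: of 40,000 simulated phases, 23,735 (59.3%) lie on the
side of the dance-floor centre that their waggle direction points to
(alignment score > 0), the median score is 0.27 for this seed (seed-to-seed
spread is about ±0.02, long-run mean ≈ 0.29), and the one-sided sign test
rejects a symmetric null overwhelmingly.  The mean forward drift recovered
from consecutive phase pairs is 0.74 mm — slightly below the input
`mu_f = 0.81 mm` because comb-boundary rejection truncates outward steps.

The same thing in Python, plus the quiver-field view of the drift pattern:

```python
from waggledance import MotionModelParams, simulate_dances, alignment_report
from waggledance.stats import binned_orientation_field
from waggledance.plotting import plot_orientation_field

phases = simulate_dances(MotionModelParams(), seed=1)
print(alignment_report(phases))
plot_orientation_field(binned_orientation_field(phases))
```

A full synthetic-scene pipeline run (generate, rotation-correct, cluster,
detect events, analyse) with every intermediate written to disk:

```sh
waggledance run --seed 5 --out runs/demo
```

## Layout

| module | contents |
| --- | --- |
| `waggledance.drift` | drift motion model, projected-drift measurement |
| `waggledance.scene` | synthetic hive scenes with ground truth |
| `waggledance.trajectory` | tag-rotation correction, interpolation, ego-motion features |
| `waggledance.clustering` | waggle-phase chaining, RANSAC angle consensus |
| `waggledance.events` | dance events, attendees/followers, feeder assignment |
| `waggledance.stats` | alignment scores, sign test, orientation fields, Mood's test, distances |
| `waggledance.pipeline` / `waggledance.cli` | orchestration, config validation, `waggledance` CLI |

See `docs/methods.md` for the model details, parameter meanings, and
design decisions.
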