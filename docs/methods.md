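# Methods

## The drift motion model

Each dance starts at a location drawn from an isotropic normal
distribution around `start_mean` (default (80, 160) mm on a 400 × 240 mm
comb, near where real dance floors form next to the hive entrance) with
standard deviation `start_spread` (20 mm), and keeps one waggle direction
`alpha ~ U(0, 2*pi)` for its whole duration.  Every waggle phase is one
update step: the position advances by `forward` along
`(cos alpha, sin alpha)` and by `sideways` along `(-sin alpha, cos alpha)`
with `forward ~ N(0.80834, 7.30946)` mm and `sideways ~ N(0, 8.15597)` mm.
A proposal landing outside the comb is discarded and both offsets redrawn
until the position is inside (a configurable cap, default 10,000 redraws,
turns a pathological noise-free configuration into an error instead of a
hang).  The position *after* each step is recorded as a phase location;
the initial start point is not itself a phase, so 20 phases mean 20
update steps.

**Scales are standard deviations.**  The offset distributions are written
with a `sigma2` notation in the source material, yet the drift measured
from annotated dances is reported as `0.81 ± 7.3 mm` (mean ± std), which
identifies 7.3 as a standard deviation.  We validated both readings
against the published simulation outputs: treating the printed scales as
standard deviations reproduces the positive-score count (≈23,900/40,000
simulated vs 23,695 published) and the median alignment within its
seed-to-seed spread; treating them as variances misses both.  The
variance reading remains available behind
`MotionModelParams(scales_are_variances=True)`.

### The alignment statistic

For phase location `p` and the dance-floor centre `c` (component-wise
median of all phase locations), the score is
`unit(p - c) · (cos alpha, sin alpha)`; phases exactly at `c` have no
defined offset direction and are excluded but counted.  Significance is a
one-sided exact sign test (upper-tail binomial at p = 1/2, zeros
excluded).  Two finite-sample caveats, both visible in the tests:

* scores within one dance are strongly correlated (shared direction and
  trajectory), so the median's effective sample size is the number of
  dances, not phases — the per-run spread of the median is ≈0.02 at 2,000
  dances;
* because `c` is estimated from the same data, the statistic carries a
  small negative bias under the no-drift null (≈ −0.02 at the default
  geometry), far from the ≈ +0.29 drift signal.

The projected-drift measurement inverts the model: for consecutive phases
within one dance, `forward = dp · (cos a, sin a)` and
`sideways = dp · (-sin a, cos a)` with `a` the earlier phase's direction.
At the default geometry the recovered mean forward drift (≈0.75–0.79 mm)
sits slightly below the input 0.81 mm because boundary rejection truncates
outward steps; on a large comb the estimator recovers all three
parameters within sampling error.

## The synthetic scene generator

Scenes emulate the statistical structure the pipeline assumes, not hive
physics:

* **Dancers** alternate 1.5 s waggle runs and 2.5 s returns (a 4 s cycle,
  8 phases per dance by default → 32 s dances, comfortably above the 4 s
  event threshold).  Phase start points follow the drift process above.
  Dances for a feeder share that feeder's direction (two feeders: up vs
  down, i.e. toward vs away from the sun) ± 0.1 rad, and start near a
  feeder-specific dance-floor anchor (the shared anchor displaced 12 mm
  along the feeder direction, emulating the observed separation of feeder
  groups which at full scale emerges from drift accumulated over many
  dances).  Dances are scheduled in disjoint time slots by default so
  that spatiotemporal clustering is unambiguous;
  `overlapping_dances=True` schedules them independently, which is what
  choice situations require.
* **Followers** attach to a dancer for a planted interval: 4–10 mm away
  at a fixed bearing, facing her exactly.  A configurable fraction are
  *attendees* — positioned identically but never emitting the "follow"
  behaviour class.  After an interval the bee dashes away at 15 mm/s for
  4 s (so the 14 mm attendance window closes cleanly) and resumes walking.
  With `follows_per_follower > 1`, later follows pick the nearest
  concurrently running dance from the bee's current position — the
  distance-based choice behaviour observed in real followers.
* **Idle bees** perform a bounded correlated random walk (heading noise
  0.35 rad/frame, speed |N(3, 1.5)| mm/s, reflection 5 mm inside the
  walls), oriented along their heading — which is what makes the
  rotation-correction estimator work, since walking bees move forward.
* **Observation model**: per-bee tag misalignment ~ N(0,
  `tag_offset_spread`) added to every reported orientation; optional
  Gaussian position noise; i.i.d. per-frame detection dropout; detection
  confidence ~ N(0.9, 0.05) clipped to [0, 1].  Class probabilities are
  the one-hot ground-truth labels plus i.i.d. N(0, `class_prob_noise`)
  per class, clipped at 1e-6 and renormalised — `noise=0` reproduces the
  labels exactly, and the label-flip rate grows smoothly with noise.
  Every dance is preceded by one feeder visit 60–280 s before its start.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: antennation and physical crowding, identity
switches and decoding errors, the waggle detector's false positives,
dancers adjusting direction for the sun's movement, and realistic comb
occupancy (dozens of bees rather than thousands).  Recovery rates on
scenes are upper bounds for real recordings.

## Event-detection conventions

* Median smoothing of class probabilities uses a centred kernel of 5 with
  shrinking windows at the edges; argmax ties break toward
  other < follow < dance.
* Dance events: dance-labeled runs merged across gaps **≤ 3 s**, kept at
  ≥ 4 s; follow candidates merged across gaps **< 3 s**, kept at ≥ 1 s
  (the two gap rules are deliberately one inclusive and one strict,
  matching the published wording).
* The facing rule (orientation · direction-to-dancer ≥ 0) is evaluated
  with a 1e-12 epsilon so the inclusive boundary survives rounding.
* Follower vs attendee is a majority vote of the bee's own labels over
  the candidate interval.
* Feeder assignment looks back 300 s from the dance start, excludes the
  start instant, and returns a `"dropped"` sentinel when the dancer
  visited two or more distinct feeders in the window.
* Times are seconds; frame index = round(time × frame rate); events are
  reported on the frame grid (start = first frame / rate, end = (last
  frame + 1) / rate).

## Clustering conventions

Chaining uses phase *start points* and single linkage: phases join a
dance when connected by pairs within both 30 mm and 5 s; groups under 3
phases are discarded.  The angle consensus enumerates every phase's angle
as a hypothesis (groups are small, so the exhaustive variant replaces
random sampling and is seed-free); inliers lie within 0.52 rad (30°, a
package choice — the tolerance is not specified in the source analysis
and is exposed as a parameter); ties between equally sized inlier sets go
to the smaller circular spread, then the earlier phase.  The consensus is
the circular mean of the inliers; a best fraction under 60% discards the
whole group, otherwise only the outlier phases are dropped.

## Statistics conventions

* Circular mean = atan2 of mean sine and cosine; circular std =
  sqrt(−2 ln R̄); angles wrapped to (−pi, pi].
* Mood's median test dichotomises at the pooled median as above/not-above
  (ties below), 1-df Pearson chi-square without continuity correction;
  degenerate tables give chi2 = 0, p = 1.
* Percentiles (feature clipping, 5th/95th) interpolate linearly between
  order statistics; a constant feature's std is floored at 1e-8 with a
  warning.
* Spatial grids are 10 mm, half-open `[k·10, (k+1)·10)`, origin at the
  comb's lower-left; direction bins for the median-location profile are
  half-open 5° bins on [0°, 360°).
* The dance-floor area fraction ranks cells by count and takes the
  minimal prefix reaching 95% coverage (greedy = optimal for this
  objective); low-activity days are dropped when not strictly above the
  median daily count.
* Group-distance time courses use 1.96 × SEM bands (normal
  approximation); bins with fewer than two events are omitted.
* Choice situations: candidates are dance events *running at the instant
  the next follow starts*, by dancers distinct from the follower and from
  the initial dance's dancer; a situation requires ≥ 2 distinct dancers
  covering both feeders with the followed dance among them.  Distances
  are measured to each candidate dancer's detection nearest in time.

## Problem sizes

Tests and the acceptance script run at desk scale: drift simulations use
the published 2,000 × 20 configuration (a run takes well under a second);
scene-based checks use 5–35 bees for 5–10 simulated minutes at 6 Hz,
which is enough for every recovery statistic to resolve at its stated
tolerance.  Real-data magnitudes that depend on the recorded colony
(total phase counts, absolute area percentages, real follower distances)
are outside what synthetic scenes can or should reproduce.
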