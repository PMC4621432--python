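# Methods

This note documents the models implemented in `quadfly`, the choices made
where the underlying assay description leaves the design open, and what
the synthetic-data generator does and does not capture about real
recordings.

## Arena geometry and quadrant assignment

The arena is a 19.5 cm × 19.5 cm square (0.7 cm deep in the physical
apparatus) whose walkable region is a star-shaped Teflon insert between
glass plates.  The exact insert outline is not load-bearing for any
statistic — everything reduces to the sign pattern of a position relative
to the two axes through the center — so the default mask is the bounding
square with the four corners notched off (isosceles right triangles with
legs of 0.25 × side).  The mask polygon is configurable for labs with a
different insert.

Quadrants are named `Q1..Q4` counterclockwise from the (+,+) sector at
rotation 0.  The naming is a package convention; which quadrant carries
odor is an experiment-configuration fact.  Positions exactly on a quadrant
axis (within 1e−12 cm) or outside the mask are labelled `NONE` and
excluded from all quadrant counts: for continuous positions this is a
measure-zero set, and excluding it avoids biased tie-breaking.

**Rotation.**  `rotate_arena(arena, 90)` models the 90° arena rotation of
the post-stimulus protocol.  Recorded coordinates follow the plate, so
rotation acts as a relabelling: a fixed point's label advances cyclically
(Q1 → Q2 → Q3 → Q4 per +90°), and material deposited while a quadrant was
labelled `L` carries the label `remap_quadrant(L, rotation)` afterwards.
`post_stimulus_analysis` applies that remap so the post-rotation
Attraction Index is computed against the deposits' new label, which is
exactly what dissociates deposited-pheromone attraction from residual
signal in the fixed odor-delivery plumbing.

## Index statistics

`AI = (O − C_avg)/(O + C_avg)` and `OPI = (E_o − E_avg)/(E_o + E_avg)` as
defined in the README.  Additional semantics that are part of the tested
contract:

- All flies' samples are pooled; "number of tracked positional data
  points" is read literally.  A per-fly averaged variant exists behind
  `attraction_index(..., per_fly=True)` but is not the default.
- Analysis windows are half-open `[t0, t1)`; post-stimulus windows start
  at the first frame after the clean-air switch.
- A zero denominator (no samples/eggs in any counted region) raises
  `UndefinedStatisticError` rather than returning 0; in sliding-window
  time courses such windows are kept, flagged, with `AI = NaN`.
- `compare_groups` uses Student's equal-variance t-test for two groups
  (a flag selects Welch's) and one-way ANOVA for more; the sampling unit
  is the trial (one replicate arena run per value), and p-values are
  reported raw with no multiplicity correction.

## Tracking

Flies are dark blobs on a bright infrared background.  Detection
thresholds dark pixels (fixed threshold, Otsu-initialized per frame when
unset), labels 8-connected components, filters them to a plausible fly
area, and reports darkness-weighted centroids.

Linking is greedy nearest-neighbour within a gate distance (default
derived from a 3 cm/s maximum walking speed: `3 × px_per_cm / frame_rate`
pixels per frame).  The identity rule is deliberately conservative: a
merge is declared when a detection's area exceeds 1.8 × the running median
single-fly area, or when one detection is the only gated candidate of two
or more active tracks; either cue suffices.  All tracks gated to a merged
blob are terminated, the merged blob is kept for bookkeeping but
contributes no position to any fly track (the identity of the flies inside
it is unknown), and fresh track ids open when the blobs separate.  Track
ids increase in order of creation and never reappear.  Global assignment
(Hungarian) was considered and rejected: at the assay's densities greedy
mutual-nearest-neighbour is equivalent in practice and easier to reason
about.

Detection parameters of the original (external) tracker are unpublished;
the defaults here are declared choices validated on rendered synthetic
frames, where linked tracks recover ground truth with sub-pixel error.

## Synthetic data generator

The generator emulates the study conditions of the live assay: 40–50
flies (default 45, 1:1 sex ratio) in the 19.5 cm arena at 30 frames/s; a
protocol of `pre` / `stimulus` / `clean_air` phases (5-min food-odor
stimulation in the standard run); 23-hr egg-laying recordings at
1 frame/5 s; 1000-ms odor pulses for spike trains.

**Motion law.**  Discrete-time correlated random walk.  Per step the agent
draws a perturbation from a von Mises distribution whose mean points
toward the local attractant and whose concentration is `β·s` (`β` =
`bias_strength`, `s` ∈ [0,1] the normalized local stimulus strength); the
new heading is the direction of `persistence·u(heading) +
(1−persistence)·u(perturbation)`.  At `β·s = 0` the von Mises is the
uniform circular distribution and the walk is isotropic, so β = 0 gives
AI = 0 in expectation and measured attraction is attributable to the bias
alone; using the concentration (rather than a deterministic pull) keeps
the dose response graded in β.  Step lengths are gamma-distributed
(shape 4) with mean `step_speed_mean/frame_rate`; the default speed of
1.5 cm/s matches starved, locomotor-activated flies.  Default persistence
is 0.7.

Stimulus strength: during an odor phase the plume fills its quadrant
uniformly, so agents outside the quadrant get `s = 1` toward the quadrant
centroid and agents inside get no directional cue (`s = 0`) — this is
what keeps odor-quadrant occupancy below 100% and graded in β.  During
clean-air phases `s = g/(g + g₀)` where `g` is the magnitude of the local
sensed pheromone gradient and `g₀` (`pheromone_gradient_scale`, default
0.1 units/cm) the half-saturation scale.

Boundary handling is specular reflection off the mask polygon (the
default mask is convex, which makes reflection exact); for a non-convex
custom mask the step is rejected and the heading reversed.  Both keep the
speed distribution intact.

**Pheromone field.**  A grid of deposited mass over the arena at the
pixel resolution.  Per step of length `dt` each cell decays by
`exp(−k·T·dt)` (`k` = `evaporation_rate`, `T` = `temperature_factor`) and
gains `d·dt` per male agent in the cell; deposition is male-only and
active only while a food-odor stimulus phase is on and the cell lies in
the odor quadrant.  No quantitative deposition or evaporation rates are
published for this system; the defaults — `k = 1/900 s⁻¹` (15-min mass
e-fold) and `d = 1` unit·s⁻¹ per male — were chosen once so that the
simulated post-stimulus attraction decays over tens of minutes, matching
the qualitative time course of the live assay, and are not fitted to any
data.  `temperature_factor > 1` models a heated arena (the deposit is
heat-labile); a large factor abolishes the post-stimulus response.

Deposits land in single grid cells (the trail a walking fly leaves is
~1 mm wide), but what a detector fly senses is the airborne volatile
radiating from the deposit.  Agents therefore sense the deposit grid
smoothed by a Gaussian plume of `plume_sigma_cm` (default 1.5 cm), and
follow its gradient (central differences on a bilinear interpolation).
The deposition/evaporation dynamics themselves operate on the raw grid
and retain the closed-form first-order decay of total mass.

**Eggs, spikes, EAG.**  Egg totals are Poisson with multinomial region
assignment proportional to configured weights and uniform position within
a region — the weights are analytic ground truth, so the measured OPI must
converge to `(w−1)/(w+1)` for weights `(w,1,1)`.  Spike trains are
inhomogeneous Poisson: baseline rate `r0` except rate `r1` in the window
`[onset+latency, onset+latency+duration)` (default 1000-ms pulse, 500-ms
latency), making the expected windowed response `(r1−r0) × 1 s`.  EAG
traces are an alpha-function deflection (rescaled so the sampled peak
equals the requested amplitude exactly) plus Gaussian noise.

**Randomness.**  Each simulation consumes one `numpy` generator seeded
from the config, drawn in a fixed agent order, so identical config + seed
reproduce every output bitwise.  (Per-agent substreams were considered but
are incompatible with vectorized state-dependent von Mises draws; bitwise
reproducibility under agent *reordering* is therefore not guaranteed.)

## What passing tests do and do not show

The generator produces bimodal, noise-free frames, circular flies, exact
first-order pheromone kinetics and memoryless Poisson spiking.  Passing
the pipeline's tests therefore demonstrates correctness of the geometry,
linking rule, index arithmetic and window semantics — not robustness to
real-video nuisances (uneven illumination, reflections at the glass,
grooming postures, spike-sorting errors), nor realism of the behavioral
dynamics beyond the qualitative phenomena it was built to express
(odor attraction graded in bias, male-deposited post-stimulus aggregation
that decays under clean air and vanishes with heating or female-only
depositors).

## Problem sizes used in the automated checks

The shipped test and acceptance runs use desk-scale versions of the study
conditions, chosen as the smallest sizes at which the statistical checks
are well-powered: bias-recovery sweeps use 15 flies at 10 frames/s for
2 min (20 replicate seeds per β); tracker ground-truth recovery uses 20
rendered videos of 30 s at 30 frames/s with 4–10 well-separated flies;
post-stimulus protocol checks use 10 depositors + 10 detectors with a
1-min stimulation and 15-min clean-air phase at 10 frames/s; Monte-Carlo
spike checks use 1000 trials; OPI convergence uses ~10,000 eggs.  The
sampling-arithmetic checks run the recording modes at full duration
(60 s at 30 frames/s; 23 hr at 1 frame/5 s).

## Known limitations

- No identity maintenance through occlusion — by design, mirroring the
  assay's rule; long-horizon per-fly statistics are not available.
- No airflow or plume physics; odor is a quadrant-shaped step function
  and the deposited volatile a Gaussian halo.
- Egg positions are drawn from region weights, not from a pheromone
  field, so egg statistics have analytic ground truth but no spatial
  microstructure within a region.
- Spike sorting (e.g. separating large- and small-amplitude neurons in
  one sensillum) is out of scope; the SSR module consumes spike times.
- The 3-well plate geometry is a nominal 34 × 85 mm layout with disc
  wells; only per-well counts enter the OPI.
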