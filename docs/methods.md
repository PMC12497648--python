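# Methods

## The problem

Grid cells in the medial entorhinal cortex fire on a triangular lattice
during open-field foraging. Cells of one module share lattice orientation
and spacing and differ only in spatial phase, so the module's joint state
is a point on a two-dimensional torus: two phases (v0, v1) along two of the
lattice axes. torusnav implements the analysis chain that (i) identifies
grid cells and fits the module's lattice geometry, (ii) decodes (v0, v1)
from population spiking with a recurrent network, (iii) converts decoded
phase changes back into Cartesian movement, and (iv) uses the decoded
representation to ask in which reference frame the module is anchored — a
fixed room landmark (the bridge of a homing task) or a movable object (a
lever) — and whether the module's orientation drift predicts the animal's
homing error.

## Grid rate model

Each cell's firing rate at position x is

    rate(x) = ReLU((cos(a0 - o0) + cos(a1 - o1) + cos(a2 - o2) + 1.5) / 4.5) * pr

with a_i = (x . u_i) / p_i * 2 pi, u_i the unit vector along axis direction
theta_i, p_i the axis period (cm), o_i the phase offset, and pr the peak
rate (Hz). For a perfect lattice theta_i = theta + {0, 60, 120} degrees and
p_i = p. Note that p is the period of the positional projection on an axis;
the lattice constant (distance between neighboring firing fields, and
between inner autocorrelation peaks) is 2 p / sqrt(3) ~ 1.155 p, and the
autocorrelation peaks lie 30 degrees away from the axis directions. The
initialization and fitting code inverts these relations explicitly.

Fitting proceeds in two stages with full-batch Adam on the mean squared
error between the model rate and the cell's instantaneous rate (tracking
timestamps, 100-ms Gaussian smoothing): stage 1 constrains perfect 60-degree
periodicity and equal periods; stage 2 releases all six axis parameters,
initialized from stage 1. Defaults: learning rate 0.01, up to 2,000
iterations per stage, early stop when the relative loss change stays below
1e-6 for 10 iterations. Module geometry is the per-parameter median of
(theta0, theta1, p0, p1) across at least five co-recorded grid cells, after
aligning each cell's axes to the first cell modulo the 60-degree lattice
symmetry.

## Torus transform and movement reconstruction

v_i = (x . u_i) / p_i * 2 pi, wrapped to [0, 2 pi); deltas are wrapped to
(-pi, pi]. A wrapped delta pair maps back to a unique Cartesian step by
solving the 2x2 linear system u_i . m = dv_i p_i / (2 pi), valid while
per-sample steps stay below half a period (at 20-ms bins a mouse moves
well under 1 cm, far from the p/2 = 15 cm ambiguity bound). The decoded
movement path is the cumulative sum of these steps anchored at the real
starting position. The decoded directional error is the signed angle
between decoded and real step vectors; its mean vector length (MVL) is the
directional precision and its circular mean the module rotation (per trial:
the decoded trial drift). Evaluation masks: running speed > 10 cm/s and
positions more than 5 cm from the wall.

## Decoder

A two-layer LSTM with 256 hidden features maps the last 20 bins (20 ms
each, rates smoothed with a 20-ms Gaussian) of population rates to
(cos v0, sin v0, cos v1, sin v1); angles are recovered by atan2 after
smoothing the four outputs with a 100-ms Gaussian. Training: one epoch,
batch 64, learning rate 0.001, Adam, MSE, chronological 80/20 split of the
first foraging trial. The network, backpropagation through time and Adam
are implemented directly on numpy float32 arrays; the backward pass is
verified against numerical gradients in float64. Inputs are fed raw in Hz
(a z-scoring switch exists; on synthetic sessions raw inputs converged to a
lower one-epoch loss than z-scored ones). Given a fixed seed, training and
decoding are bit-stable on one platform.

## Anchoring

The inferred torus position of an object is psi = wrap(v + T(R(c) (object -
mouse))), where T is the Cartesian-to-torus delta transform and c the
applicable rotation correction. Anchoring strength is the mean of the two
concentration parameters of a bivariate von Mises fit to the psi pairs.
The fit uses two independent circular marginals: circular means plus the
standard three-regime mean-resultant-length inversion for kappa, capped at
1e3 for degenerate samples. The full sine-model likelihood is deliberately
not used — only k0 and k1 are consumed downstream, the correlation term is
unidentified from these outputs, and the moment inversion is deterministic.
The shuffle null translates each trial's decoded path rigidly by a uniform
torus offset (1,000 repetitions) and refits; strengths above the 95th
percentile count as significant anchoring. Phase timecourses truncate each
behavioral phase to its first 3 s (configurable to the last 3 s) and pool
thirds across trials.

## Behavioral segmentation

A trial's journey is segmented by lever contact: the search runs from door
opening until the animal is within 10 cm of the lever box outline (the box
is an 11.6 x 8.2 cm rectangle; orientation configurable), the at-lever
interval is the contiguous in-zone block, and homing runs from leaving the
zone until the animal is within 3 cm of the arena edge. Trials with the
lever outline closer than 10 cm to the border are flagged invalid. The
error at the periphery is the angle between the center-to-crossing and
center-to-bridge vectors (chance level pi/2 for uniform crossings); the
heading error compares the circular median homing heading with the bearing
from the lever-departure point to the bridge.

## Synthetic sessions

The generator emulates the study's two situations with one shared ground
truth.

Foraging: a stochastic path on a 50-cm-diameter arena (80-cm for the task),
heading a random walk with diffusion 1.0 rad/sqrt(s) (heading persistence of
a running mouse, roughly 60 deg/s RMS), speed an Ornstein-Uhlenbeck process
around 15 cm/s, reflection at the wall; 15 min covers >80% of 3-cm bins.

Task trials: start at the bridge (0, -R), biased random search to a lever
placed uniformly within 0.75 R and at least 10 cm from the wall, a 2.5-s
orbit at the lever (press at its middle), then a near-straight homing leg.
Light labels follow the task protocol: seven light trials, then alternating
dark/light.

Module and spiking: co-modular cells share a 60-degree lattice (default
spacing p = 30 cm, a typical dorsal module; peak rate 20 Hz, mid-range for
grid cells; offsets uniform on the torus, with a dispersion knob to cluster
them). Spike counts are Poisson per 5-ms bin on the rate evaluated at the
*internal* position, optionally modulated by head direction
(1 + g cos(hd - pref)).

Internal state: orientation drift is a Wiener process per cm traveled
(default 0.3 deg/sqrt(cm)), so the internal position integrates R(drift)
times the true velocity — drift grows with path length, the simplest
generator with that property; the true generative process behind observed
drift is unknown and this is a stand-in. Reanchoring, when enabled, is an
instantaneous translation of the internal position at the first lever
contact of each trial such that the internally estimated lever position
lands on a fixed stored torus phase; orientation is preserved (pure phase
translation). An optional contact rotation adds a rotational component, off
by default, used to verify that the translation-only analysis detects its
absence. Homing directions can be coupled to the current drift
(heading = bearing + gain * drift + noise), which the drift-homing
correlation must recover.

What the generator does not emulate: theta rhythmicity and refractory
structure in spike trains (cluster-quality statistics are exercised on
constructed trains instead), conjunctive head-direction-by-grid cells,
multi-module interactions, tracking noise and dropped frames, and lever
perception in the light. Passing tests therefore demonstrate correctness of
the analysis chain under the stated model, not robustness to every
idiosyncrasy of real recordings.

## Numerical choices and conventions

- Angles: positions in [0, 2 pi), deltas in (-pi, pi], everywhere.
- Maps: 3-cm bins, 5-cm Gaussian smoothing of spike-count and occupancy
  maps separately, kernel renormalized over valid bins; rate defined only
  where occupancy > 0.
- Autocorrelation: Pearson r per displacement over overlapping valid bins
  (FFT-based), displacements with fewer than 20 overlapping bins invalid.
- Field detection: components of ac > 0.1; the central component's extent
  is capped at the first minimum of the radial profile (merging guard); the
  outermost 2 bins of the valid region are excluded (correlations there are
  computed from marginal overlaps and run high regardless of structure);
  peak locations are value-weighted component centroids. Fewer than six
  fields makes the grid score undefined, which is distinct from a low score.
- Grid score: mean(r60, r120) - mean(r30, r90, r150) on the annulus. The
  difference form is the default (`form="ratio"` exists); the ratio is
  unstable when the denominator crosses zero and cannot support the shuffle
  percentile rule.
- Shuffles: circular time-shifts with a minimum 20-s shift; classification
  at the 95th percentile of 500 shuffles; decoding precision null at the
  95th of 1,000; drift-homing significance at the 97.5th of a seeded
  trial-permutation null (the chance-distribution generator is not
  prescribed; permutation is the assumption-free choice).
- Cluster QC: refractory ratio from the 0-25 ms autocorrelogram (0.5-ms
  bins, zero-lag self-pairs excluded), spike-count criterion on 0-30 ms,
  both windows kept as stated; isolation distance = max(largest own
  Mahalanobis distance, Nth-nearest other-cluster distance), N = cluster
  size, covariance from the cluster itself.
- Speed: central differences, 100-ms Gaussian smoothing by default.
- Distance-matched drift: the matched search segment is the final stretch
  of the search path whose length equals the at-lever path length
  (configurable choice; the earliest-stretch alternative gave
  indistinguishable medians on simulations).

## Known limitations

- The decoder's directional precision on synthetic sessions depends on the
  smoothness of the simulated trajectory; heavily jittered paths lower the
  ceiling for any decoder because 20-ms movement directions decorrelate
  faster than the 100-ms output smoothing.
- The bivariate von Mises fit ignores circular-circular correlation between
  the two torus coordinates.
- `init_from_autocorr` requires six detectable autocorrelation fields and
  near-60-degree axis spacing; strongly sheared lattices must be
  initialized manually.
- The grid-score annulus heuristics (threshold 0.1, centroid peaks, edge
  guard) are tuned for 50-80-cm arenas with 25-45-cm lattice constants;
  very small maps may need a different binning.
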