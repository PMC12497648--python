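# torusnav

Grid-cell module decoding on the torus: classify grid cells, fit the
module's lattice geometry, decode the animal's position on the module torus
from population spiking, reconstruct movement from the decoded phases, and
quantify in which reference frame the module is anchored.

## Who this is for

Systems neuroscientists analyzing medial entorhinal cortex recordings from
freely moving rodents — in particular experiments where a grid module may
*reanchor* to a movable object (here: the lever of an automated homing
task) instead of the room, and where the module's orientation drift during
path integration is compared with the animal's homing behavior. A
synthetic-session generator with full ground truth (internal position,
orientation drift, reanchoring events, drift-coupled homing directions)
makes every stage testable without any recordings.

## The model

Cells of a grid module share lattice axes theta_i and periods p_i and
differ in phase. Each cell's rate is the rectified three-cosine model

    rate(x) = ReLU((cos(a0-o0) + cos(a1-o1) + cos(a2-o2) + 1.5) / 4.5) * pr,
    a_i = (x . u_i) / p_i * 2*pi,

fitted per cell in two stages (perfect 60-degree lattice, then free axes)
with Adam on an MSE loss. The module's state is the phase pair

    v_i = (x . u_i) / p_i * 2*pi  (mod 2*pi),   i = 0, 1,

a point on a torus. A two-layer LSTM (256 hidden units) decodes
(cos v0, sin v0, cos v1, sin v1) from the last 400 ms of population rates;
wrapped phase deltas map back to Cartesian movement by solving
u_i . m = dv_i p_i / (2*pi). The signed angle between decoded and real
movement vectors gives the *directional precision* (mean vector length) and
the *module rotation / trial drift* (circular mean). Anchoring of the
decoded representation to an object is the mean concentration (k0 + k1)/2
of a bivariate von Mises fit to the object's inferred torus positions,
tested against a shuffle that rigidly translates each trial's decoded path.

See `docs/methods.md` for the full account of assumptions, parameters and
numerical conventions.

## Worked example

```python
import numpy as np
import torusnav as tn

# a 15-min foraging session: 8 co-modular grid cells, 30-cm spacing
traj = tn.simulate_foraging_trajectory(duration=900, seed=1)
cells = tn.make_module(n_cells=8, seed=2)
spikes, gt = tn.simulate_module_spikes(traj, cells, seed=3)

# shuffle-based grid classification of one cell
thr, is_grid, score, _ = tn.classify_grid(traj, spikes[1], n_shuffle=500, seed=4)
print(f"grid score {score:.2f} vs shuffle threshold {thr:.2f} -> grid cell: {is_grid}")

# per-cell two-stage model fit, then median module geometry
models = []
for st in spikes:
    rm = tn.rate_map(traj, st)
    init = tn.init_from_autocorr(rm)
    _, rate = tn.instantaneous_rate(st, traj.t[0], traj.t[-1],
                                    bin_size=traj.dt, smooth_sd=0.1)
    n = min(rate.size, traj.t.size)
    model, _ = tn.fit_cell(traj.xy()[:n], rate[:n], init)
    models.append(model)
geom = tn.module_geometry(models)
print(f"module geometry: theta0 = {np.rad2deg(geom.theta0):.1f} deg, "
      f"p0 = {geom.p0:.1f} cm   (ground truth: 0.0 deg, 30.0 cm)")

# movement reconstruction from the (here: ground-truth) torus path
v = tn.to_torus(traj.xy(), geom)
tp = tn.TorusPath(traj.t, v[:, 0], v[:, 1])
vec, recon = tn.decoded_movement(tp, geom, traj.xy()[0])
err = tn.directional_errors(vec, np.diff(traj.xy(), axis=0))
print(f"true torus path reconstruction: directional precision {err.precision:.3f}, "
      f"rotation {np.rad2deg(err.rotation):.2f} deg")
```

Output:

```
grid score 1.21 vs shuffle threshold 0.78 -> grid cell: True
module geometry: theta0 = 0.3 deg, p0 = 30.3 cm   (ground truth: 0.0 deg, 30.0 cm)
true torus path reconstruction: directional precision 1.000, rotation -0.00 deg
```

The classified cell's score (1.21) clearly exceeds its own shuffle
threshold (0.78); the fitted module geometry recovers the generator's
lattice to a fraction of a degree and millimeter-scale period error; and
reconstructing movement from the true torus path reproduces the real
trajectory exactly (precision 1, no rotation), confirming the phase
transforms are mutually inverse. Training the LSTM decoder on such a
session (`tn.train_decoder`) yields held-out directional precisions around
0.8 with 15 cells.

A thin CLI mirrors the common entry points:

```bash
torusnav simulate --scenario autopi --seed 1 --n-trials 20 --out session/
torusnav validate-session session/
torusnav qc session/
torusnav classify session/
torusnav fit-module session/
```

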