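"""Synthetic recording sessions with ground-truth internal state.

This module emulates the two recording situations of the study so that every
analysis stage can be exercised without real data:

* random foraging on a circular arena (50-cm diameter by default) with a
  smooth stochastic trajectory (Ornstein-Uhlenbeck heading and speed,
  reflection at the wall);
* the automated path-integration (AutoPI) homing task on an 80-cm-diameter
  arena with the bridge at the -y edge: per trial, the animal leaves the
  bridge, searches for a randomly placed lever, dwells circling the lever,
  and homes back to the periphery.

Spiking is generated from a co-modular population of grid cells obeying a
rectified three-cosine grid rate model (shared axis orientations and periods,
per-cell phase offsets, peak rate ``pr``):

    rate(x, y) = ReLU((cos(a0-o0) + cos(a1-o1) + cos(a2-o2) + 1.5) / 4.5) * pr

with a_i = d_i / p_i * 2*pi and d_i the position projected on axis i. Spikes
are drawn as an inhomogeneous Poisson process on small time bins.

Two ground-truth internal-state features can be injected:

* orientation drift: the module's internal heading estimate performs a Wiener
  random walk per cm of path traveled (``drift_rate_deg_per_cm``), so the
  internal position integrates a rotated copy of the true velocity;
* reanchoring: at the first lever contact of each trial, the internal
  position is translated (orientation preserved) so that the lever maps to a
  fixed stored torus phase — a pure phase translation of the grid pattern.

The emitted :class:`SimGroundTruth` exposes exactly what the downstream
analyses are supposed to recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import wrap_delta, wrap_pos
from .session_model import SpikeTrain, Trajectory, TrialEvents
from .torus import (ModuleGeometry, cartesian_to_torus_delta, to_torus,
                    torus_delta_to_cartesian)

__all__ = [
    "GridModel",
    "SimGroundTruth",
    "grid_rate",
    "make_module",
    "module_geometry_of",
    "simulate_foraging_trajectory",
    "simulate_autopi_trials",
    "simulate_module_spikes",
    "FORAGING_RADIUS",
    "TASK_RADIUS",
]

# Arena geometry of the study: 50-cm-diameter foraging arena, 80-cm-diameter
# task arena with the bridge at the -y edge.
FORAGING_RADIUS = 25.0
TASK_RADIUS = 40.0


# ---------------------------------------------------------------------------
# Grid rate model
# ---------------------------------------------------------------------------

@dataclass
class GridModel:
    """Parameters of one grid cell: axis directions (rad), periods (cm),
    phase offsets (rad) and peak rate (Hz)."""

    theta: np.ndarray
    p: np.ndarray
    o: np.ndarray
    pr: float

    def __post_init__(self):
        self.theta = wrap_pos(np.asarray(self.theta, dtype=float))
        self.p = np.asarray(self.p, dtype=float)
        self.o = wrap_pos(np.asarray(self.o, dtype=float))
        if self.theta.shape != (3,) or self.p.shape != (3,) or self.o.shape != (3,):
            raise ValueError("theta, p, o must each have 3 components")
        if np.any(self.p <= 0):
            raise ValueError("periods must be positive")
        if self.pr < 0:
            raise ValueError("peak rate must be nonnegative")


def grid_rate(xy, model: GridModel):
    """Firing rate (Hz) of the grid model at Cartesian position(s) xy (cm)."""
    xy = np.asarray(xy, dtype=float)
    single = xy.ndim == 1
    xy = np.atleast_2d(xy)
    if not np.all(np.isfinite(xy)):
        raise ValueError("positions must be finite")
    u = np.column_stack([np.cos(model.theta), np.sin(model.theta)])  # (3, 2)
    d = xy @ u.T                                   # (n, 3)
    a = d / model.p * 2 * np.pi
    g = (np.cos(a - model.o).sum(axis=1) + 1.5) / 4.5 * model.pr
    r = np.maximum(g, 0.0)
    return float(r[0]) if single else r


def make_module(n_cells: int, spacing: float = 30.0, orientation: float = 0.0,
                peak_rate: float = 20.0, dispersion: float = 1.0,
                seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
                ) -> list[GridModel]:
    """A co-modular population: shared 60-degree lattice, per-cell offsets.

    Offsets are drawn uniformly on the torus; ``dispersion`` in (0, 1] shrinks
    the covered fraction of the torus (cells clustered in phase decode worse).
    The third offset is o1 - o0, consistent with the lattice constraint
    u2 = u1 - u0 for equal periods.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = orientation + np.array([0.0, np.pi / 3, 2 * np.pi / 3])
    p = np.full(3, float(spacing))
    cells = []
    for _ in range(n_cells):
        phi = rng.uniform(0, 2 * np.pi * dispersion, size=2)
        o = np.array([phi[0], phi[1], phi[1] - phi[0]])
        cells.append(GridModel(theta.copy(), p.copy(), o, peak_rate))
    return cells


def module_geometry_of(cells: Sequence[GridModel]) -> ModuleGeometry:
    """Geometry (first two axes) shared by a simulated module."""
    c = cells[0]
    return ModuleGeometry(c.theta[0], c.theta[1], c.p[0], c.p[1])


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class SimGroundTruth:
    """Internal state emitted by the generator (what analyses must recover)."""

    t: Optional[np.ndarray] = None
    internal_xy: Optional[np.ndarray] = None       # (n, 2) cm
    drift: Optional[np.ndarray] = None             # (n,) rad
    reanchor_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    homing_direction: Optional[np.ndarray] = None  # (n_trials,) rad
    lever_phase: Optional[np.ndarray] = None       # stored torus phase (2,)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _reflect(pos, vel, radius):
    """Reflect a position/velocity pair at the circular wall."""
    r = np.hypot(*pos)
    if r <= radius:
        return pos, vel
    n = pos / r
    pos = n * (2 * radius - r)
    vel = vel - 2 * np.dot(vel, n) * n
    return pos, vel


def simulate_foraging_trajectory(duration: float,
                                 arena_radius: float = FORAGING_RADIUS,
                                 dt: float = 0.02,
                                 mean_speed: float = 15.0,
                                 speed_sd: float = 6.0,
                                 speed_tau: float = 1.0,
                                 turn_sd: float = 1.0,
                                 seed: Optional[int] = None) -> Trajectory:
    """Smooth stochastic foraging path on a circular arena.

    Heading is a random walk (sd ``turn_sd`` rad/sqrt(s)); speed follows an
    Ornstein-Uhlenbeck process around ``mean_speed`` (cm/s), floored at 0.
    The path reflects at the wall. Deterministic given ``seed``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if arena_radius <= 0:
        raise ValueError("arena radius must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    hd = np.empty(n)
    pos = np.array([0.0, -arena_radius / 2])
    heading = rng.uniform(0, 2 * np.pi)
    speed = mean_speed
    sq = np.sqrt(dt)
    dW_h = rng.normal(0, turn_sd * sq, size=n)
    dW_s = rng.normal(0, speed_sd * np.sqrt(2 * dt / speed_tau), size=n)
    for k in range(n):
        x[k], y[k] = pos
        hd[k] = heading
        heading = heading + dW_h[k]
        speed = speed + (mean_speed - speed) * dt / speed_tau + dW_s[k]
        speed = max(speed, 0.0)
        vel = speed * np.array([np.cos(heading), np.sin(heading)])
        pos, vel = _reflect(pos + vel * dt, vel, arena_radius)
        heading = np.arctan2(vel[1], vel[0])
    return Trajectory(t, x, y, hd=wrap_pos(hd))


# ---------------------------------------------------------------------------
# AutoPI task
# ---------------------------------------------------------------------------

@dataclass
class AutoPIParams:
    """Study conditions of the simulated homing task."""

    arena_radius: float = TASK_RADIUS
    dt: float = 0.02
    speed: float = 18.0                 # cm/s, locomotion speed during trials
    search_turn_sd: float = 2.0         # rad/sqrt(s), search tortuosity
    search_bias: float = 1.2            # 1/s pull toward the lever
    dwell_duration: float = 2.5         # s circling at the lever
    dwell_radius: float = 6.0           # cm orbit radius at the lever
    drift_rate_deg_per_cm: float = 0.3  # Wiener sd of orientation drift
    coupling_gain: float = 0.0          # homing error = gain * drift + noise
    homing_noise_sd: float = 0.15       # rad
    n_light_start: int = 7              # consecutive light trials at start
    inter_trial_gap: float = 1.0        # s parked at the bridge
    lever_min_wall: float = 10.0        # cm, min lever distance from wall
    lever_max_frac: float = 0.75        # lever within this fraction of R


def simulate_autopi_trials(n_trials: int,
                           params: Optional[AutoPIParams] = None,
                           seed: Optional[int] = None
                           ) -> tuple[Trajectory, TrialEvents, SimGroundTruth]:
    """Simulate an AutoPI session: trajectory, trial events and ground truth.

    Each trial starts at the bridge (0, -R), performs a biased random search
    to a random lever position (within ``lever_max_frac * R`` of the center
    and at least ``lever_min_wall`` cm from the wall), circles the lever for
    ``dwell_duration`` s (lever press at the middle of the dwell), then homes.
    The homing heading equals the bearing to the bridge plus
    ``coupling_gain * drift`` at lever departure plus Gaussian noise. Light
    labels: ``n_light_start`` light trials, then alternating dark/light.

    Orientation drift is a Wiener process per cm of path traveled and is
    shared with :func:`simulate_module_spikes` through the returned ground
    truth, keeping behaviour and spiking consistent.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    p = params or AutoPIParams()
    rng = np.random.default_rng(seed)
    R = p.arena_radius
    dt = p.dt
    bridge = np.array([0.0, -R])
    start = np.array([0.0, -(R - 2.0)])
    sigma_drift = np.deg2rad(p.drift_rate_deg_per_cm)

    ts, xs, ys = [], [], []
    drifts = []
    rows = []
    homing_dirs = np.empty(n_trials)
    t_now = 0.0
    drift = 0.0
    sq = np.sqrt(dt)

    def advance(pos, heading, target_heading_fn, stop_fn, bias, turn_sd,
                max_time=120.0):
        nonlocal t_now, drift
        k = 0
        kmax = int(max_time / dt)
        while k < kmax:
            ts.append(t_now)
            xs.append(pos[0])
            ys.append(pos[1])
            drifts.append(drift)
            if stop_fn(pos):
                break
            tgt = target_heading_fn(pos)
            heading = heading + bias * wrap_delta(tgt - heading) * dt \
                + rng.normal(0, turn_sd * sq)
            vel = p.speed * np.array([np.cos(heading), np.sin(heading)])
            newpos, vel = _reflect(pos + vel * dt, vel, R - 0.5)
            heading = np.arctan2(vel[1], vel[0])
            step = np.hypot(*(newpos - pos))
            drift = drift + rng.normal(0, sigma_drift * np.sqrt(max(step, 1e-12)))
            pos = newpos
            t_now += dt
            k += 1
        return pos, heading

    for tr in range(n_trials):
        t_open = t_now
        # lever position: within lever_max_frac * R, >= lever_min_wall from wall
        while True:
            lever = rng.uniform(-R, R, size=2)
            r = np.hypot(*lever)
            if r <= min(p.lever_max_frac * R, R - p.lever_min_wall):
                break
        pos = start.copy()
        heading = np.pi / 2

        # --- search: biased random walk toward the lever
        wander = rng.uniform(0, 2 * np.pi)

        def search_target(q, lever=lever, wander=wander):
            b = np.arctan2(lever[1] - q[1], lever[0] - q[0])
            return b

        pos, heading = advance(
            pos, heading, search_target,
            stop_fn=lambda q: np.hypot(*(q - lever)) < 8.0,
            bias=p.search_bias, turn_sd=p.search_turn_sd)

        # --- at lever: orbit the lever
        t_contact = t_now
        n_dwell = int(p.dwell_duration / dt)
        phi0 = np.arctan2(pos[1] - lever[1], pos[0] - lever[0])
        omega = rng.choice([-1.0, 1.0]) * p.speed / p.dwell_radius * 0.6
        for k in range(n_dwell):
            phi = phi0 + omega * k * dt
            q = lever + p.dwell_radius * np.array([np.cos(phi), np.sin(phi)])
            ts.append(t_now)
            xs.append(q[0])
            ys.append(q[1])
            step = p.dwell_radius * abs(omega) * dt
            drift = drift + rng.normal(0, sigma_drift * np.sqrt(step))
            drifts.append(drift)
            t_now += dt
        pos = np.array([xs[-1], ys[-1]])
        t_press = t_contact + p.dwell_duration / 2

        # --- homing: straight-ish run whose direction errs with the drift
        bearing = np.arctan2(bridge[1] - pos[1], bridge[0] - pos[0])
        err = p.coupling_gain * drift + rng.normal(0, p.homing_noise_sd)
        homing_heading = bearing + err
        homing_dirs[tr] = homing_heading
        pos, heading = advance(
            pos, homing_heading,
            target_heading_fn=lambda q, h=homing_heading: h,
            stop_fn=lambda q: np.hypot(*q) >= R - 2.0,
            bias=0.8, turn_sd=0.3)

        # --- park at the bridge between trials
        n_gap = int(p.inter_trial_gap / dt)
        for k in range(n_gap):
            ts.append(t_now)
            xs.append(start[0])
            ys.append(start[1])
            drifts.append(drift)
            t_now += dt
        t_close = t_now

        light = "light" if (tr < p.n_light_start or
                            (tr - p.n_light_start) % 2 == 1) else "dark"
        rows.append(dict(trial_id=tr, light=light, t_door_open=t_open,
                         t_door_close=t_close, t_lever_press=t_press,
                         lever_x=lever[0], lever_y=lever[1],
                         bridge_x=bridge[0], bridge_y=bridge[1],
                         arena_rotation=float(rng.choice(np.arange(8)) *
                                              np.pi / 4)))

    traj = Trajectory(np.asarray(ts), np.asarray(xs), np.asarray(ys))
    trials = TrialEvents(pd.DataFrame(rows))
    gt = SimGroundTruth(t=traj.t, drift=np.asarray(drifts),
                        homing_direction=homing_dirs)
    return traj, trials, gt


# ---------------------------------------------------------------------------
# Spiking
# ---------------------------------------------------------------------------

def internal_trajectory(traj: Trajectory,
                        drift: Optional[np.ndarray] = None,
                        drift_rate_deg_per_cm: float = 0.0,
                        trials: Optional[TrialEvents] = None,
                        reanchor_at_lever: bool = False,
                        lever_phase: Optional[np.ndarray] = None,
                        geom: Optional[ModuleGeometry] = None,
                        contact_rotation: float = 0.0,
                        rng: Optional[np.random.Generator] = None
                        ) -> SimGroundTruth:
    """Integrate the module's internal position along a real trajectory.

    The internal position integrates R(drift) . velocity. If
    ``reanchor_at_lever`` is set, at the first lever contact of each trial
    (first sample within 10 cm of the lever after door open) the internal
    position is translated so that the internally estimated lever position
    maps to a fixed stored torus phase (``lever_phase``; taken from the first
    contact when not supplied). Orientation (drift) is preserved across the
    reset — a pure phase translation. A nonzero ``contact_rotation`` adds
    that angle to the orientation drift at each contact (a rotational
    reanchoring component, off by default).
    """
    n = traj.t.size
    xy = traj.xy()
    vel = np.diff(xy, axis=0)
    if drift is None:
        if rng is None:
            rng = np.random.default_rng()
        sigma = np.deg2rad(drift_rate_deg_per_cm)
        steps = np.hypot(vel[:, 0], vel[:, 1])
        incr = rng.normal(0, 1, size=n - 1) * sigma * np.sqrt(steps)
        drift = np.concatenate([[0.0], np.cumsum(incr)])
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (n,):
        raise ValueError("drift must match trajectory length")

    contacts = []
    if reanchor_at_lever and trials is not None:
        for row in trials:
            m = (traj.t >= row.t_door_open) & (traj.t < row.t_door_close)
            idx = np.flatnonzero(m)
            if idx.size == 0:
                continue
            d = np.hypot(xy[idx, 0] - row.lever_x, xy[idx, 1] - row.lever_y)
            hit = np.flatnonzero(d < 10.0)
            if hit.size:
                contacts.append((int(idx[hit[0]]),
                                 np.array([row.lever_x, row.lever_y])))
        if geom is None:
            raise ValueError("reanchoring requires module geometry")
    contact_map = dict(contacts)

    if contact_rotation != 0.0 and contact_map:
        drift = drift.copy()
        for k in sorted(contact_map):
            drift[k:] += contact_rotation
    internal = np.empty((n, 2))
    internal[0] = xy[0]
    stored = None if lever_phase is None else np.asarray(lever_phase, float)
    reanchor_times = []
    c, s = np.cos(drift), np.sin(drift)
    for k in range(n - 1):
        if k in contact_map:
            lever = contact_map[k]
            rel = lever - xy[k]
            rot = np.array([[c[k], -s[k]], [s[k], c[k]]])
            lever_est = internal[k] + rot @ rel
            psi = to_torus(lever_est, geom)
            if stored is None:
                stored = psi.copy()
            else:
                dv = wrap_delta(stored - psi)
                internal[k] = internal[k] + torus_delta_to_cartesian(dv, geom)
                reanchor_times.append(traj.t[k])
        internal[k + 1, 0] = internal[k, 0] + c[k] * vel[k, 0] - s[k] * vel[k, 1]
        internal[k + 1, 1] = internal[k, 1] + s[k] * vel[k, 0] + c[k] * vel[k, 1]

    return SimGroundTruth(t=traj.t, internal_xy=internal, drift=drift,
                          reanchor_times=np.asarray(reanchor_times),
                          lever_phase=stored)


def simulate_module_spikes(traj: Trajectory,
                           cells: Sequence[GridModel],
                           drift_rate_deg_per_cm: float = 0.0,
                           reanchor_at_lever: bool = False,
                           trials: Optional[TrialEvents] = None,
                           hd_gain: float = 0.0,
                           hd_pref: float = 0.0,
                           dt: float = 0.005,
                           seed: Optional[int] = None,
                           ground_truth: Optional[SimGroundTruth] = None,
                           lever_phase: Optional[np.ndarray] = None
                           ) -> tuple[list[SpikeTrain], SimGroundTruth]:
    """Inhomogeneous-Poisson spike trains for a co-modular population.

    Rates are evaluated from :func:`grid_rate` on the *internal* position
    (see :func:`internal_trajectory`), optionally modulated by head direction
    as ``rate * (1 + hd_gain * cos(hd - hd_pref))``. Spike counts per ``dt``
    bin are Poisson; spike times are jittered uniformly within bins.

    If ``ground_truth`` (with a drift series) is given — e.g. from
    :func:`simulate_autopi_trials` — that drift is used, keeping spiking
    consistent with the behavioural coupling.
    """
    if dt > traj.dt + 1e-12:
        raise ValueError("spike dt must not exceed the tracking step")
    rng = np.random.default_rng(seed)
    geom = module_geometry_of(cells)
    drift = None if ground_truth is None else ground_truth.drift
    gt = internal_trajectory(traj, drift=drift,
                             drift_rate_deg_per_cm=drift_rate_deg_per_cm,
                             trials=trials, reanchor_at_lever=reanchor_at_lever,
                             lever_phase=lever_phase, geom=geom, rng=rng)
    if ground_truth is not None:
        gt.homing_direction = ground_truth.homing_direction

    # upsample internal position (and hd) to the spike bin grid
    tb = np.arange(traj.t[0], traj.t[-1], dt) + dt / 2
    ix = np.interp(tb, traj.t, gt.internal_xy[:, 0])
    iy = np.interp(tb, traj.t, gt.internal_xy[:, 1])
    pos = np.column_stack([ix, iy])
    if hd_gain != 0.0:
        if traj.hd is not None:
            hd = np.interp(tb, traj.t, np.unwrap(traj.hd))
        else:
            vx = np.gradient(traj.x, traj.t)
            vy = np.gradient(traj.y, traj.t)
            hd = np.interp(tb, traj.t, np.unwrap(np.arctan2(vy, vx)))
        hd_factor = 1.0 + hd_gain * np.cos(hd - hd_pref)
    else:
        hd_factor = 1.0

    trains = []
    for i, cell in enumerate(cells):
        lam = grid_rate(pos, cell) * hd_factor * dt
        counts = rng.poisson(lam)
        hot = np.flatnonzero(counts)
        times = np.repeat(tb[hot] - dt / 2, counts[hot]) \
            + rng.uniform(0, dt, size=int(counts[hot].sum()))
        trains.append(SpikeTrain(f"cell{i:03d}", np.sort(times)))
    return trains, gt
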