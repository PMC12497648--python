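"""Trial segmentation and behavioral error measures.

A homing-task journey is segmented into search (journey start to first
lever contact), at-lever (contact until the animal leaves the lever zone)
and homing (leaving the lever until the arena periphery, within 3 cm of the
edge). Contact means being within 10 cm of the lever box outline (the box
is an 11.6 x 8.2 cm rectangle around its tracked center). Trials whose
lever sits closer than 10 cm to the arena border are flagged invalid.

Homing performance: the error at the periphery is the angle between the
center-to-periphery-crossing and center-to-bridge vectors; the heading error
compares the median homing heading with the direction from the lever
departure point to the bridge.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._utils import circ_mean_resultant, wrap_delta
from .ratemaps import RateMap, rate_map
from .session_model import SpikeTrain, Trajectory, TrialEvents

__all__ = [
    "TrialSegments",
    "LEVER_BOX",
    "segment_trial",
    "homing_errors",
    "lever_direction_tuning",
    "lever_frame_stability",
]

LEVER_BOX = (11.6, 8.2)  # cm, printed lever-box footprint


def _dist_to_box(xy: np.ndarray, center, angle: float = 0.0,
                 box=LEVER_BOX) -> np.ndarray:
    """Distance from points to the outline of the lever box rectangle."""
    xy = np.atleast_2d(np.asarray(xy, float)) - np.asarray(center, float)
    c, s = np.cos(-angle), np.sin(-angle)
    local = xy @ np.array([[c, -s], [s, c]]).T
    hx, hy = box[0] / 2, box[1] / 2
    dx = np.abs(local[:, 0]) - hx
    dy = np.abs(local[:, 1]) - hy
    outside = np.hypot(np.maximum(dx, 0), np.maximum(dy, 0))
    inside = np.minimum(np.maximum(dx, dy), 0)
    return outside + inside


@dataclass
class TrialSegments:
    trial_id: int
    search: Optional[tuple[float, float]]
    at_lever: Optional[tuple[float, float]]
    homing: Optional[tuple[float, float]]
    periphery_xy: Optional[np.ndarray]
    lever_xy: np.ndarray
    valid: bool
    homing_open_ended: bool = False


def segment_trial(traj: Trajectory, trial, arena_radius: float,
                  contact_dist: float = 10.0, periphery_dist: float = 3.0,
                  lever_angle: float = 0.0) -> TrialSegments:
    """Segment one trial into search / at-lever / homing intervals.

    ``trial`` is a row of the :class:`TrialEvents` table. The search runs
    from door opening to the first sample within ``contact_dist`` cm of the
    lever box outline; the at-lever interval is the contiguous in-zone block
    from contact; homing runs from leaving the zone to the first sample
    within ``periphery_dist`` cm of the arena edge (open-ended if the
    periphery is never reached). A trial whose lever outline is closer than
    10 cm to the border is invalid.
    """
    lever = np.array([trial.lever_x, trial.lever_y])
    m = (traj.t >= trial.t_door_open) & (traj.t < trial.t_door_close)
    idx = np.flatnonzero(m)
    if idx.size == 0:
        raise ValueError("trial has no arena samples")
    xy = traj.xy()[idx]
    t = traj.t[idx]
    half_diag = 0.5 * np.hypot(*LEVER_BOX)
    valid = (arena_radius - np.hypot(*lever) - half_diag) >= 10.0

    d = _dist_to_box(xy, lever, lever_angle)
    in_zone = d < contact_dist
    hits = np.flatnonzero(in_zone)
    if hits.size == 0:
        return TrialSegments(int(trial.trial_id), (t[0], t[-1]), None, None,
                             None, lever, bool(valid))
    contact = hits[0]
    leave = contact
    while leave + 1 < t.size and in_zone[leave + 1]:
        leave += 1
    search = (t[0], t[contact])
    at_lever = (t[contact], t[leave])

    r = np.hypot(xy[:, 0], xy[:, 1])
    after = np.flatnonzero((np.arange(t.size) > leave) &
                           (r >= arena_radius - periphery_dist))
    if after.size:
        homing = (t[leave], t[after[0]])
        periphery = xy[after[0]]
        open_ended = False
    else:
        homing = (t[leave], t[-1])
        periphery = None
        open_ended = True
    return TrialSegments(int(trial.trial_id), search, at_lever, homing,
                         periphery, lever, bool(valid), open_ended)


def _circular_median(angles: np.ndarray) -> float:
    """Angle among the samples minimizing the summed circular distance."""
    angles = np.asarray(angles, float)
    d = np.abs(wrap_delta(angles[:, None] - angles[None, :])).sum(axis=1)
    return float(angles[np.argmin(d)])


def homing_errors(seg: TrialSegments, traj: Trajectory, bridge_xy,
                  arena_center=(0.0, 0.0)):
    """Homing errors of one trial: (error_at_periphery, heading_error), rad.

    error_at_periphery: unsigned angle in [0, pi] between the vectors from
    the arena center to the periphery crossing and to the bridge. The
    heading error is the circular distance between the median heading during
    homing and the bearing from the lever-departure point to the bridge.
    Undefined (raises) without a periphery crossing.
    """
    if seg.homing is None or seg.periphery_xy is None:
        raise ValueError("no periphery crossing: homing errors undefined")
    bridge = np.asarray(bridge_xy, float)
    center = np.asarray(arena_center, float)
    a = seg.periphery_xy - center
    b = bridge - center
    err_p = abs(wrap_delta(np.arctan2(a[1], a[0]) - np.arctan2(b[1], b[0])))

    m = (traj.t >= seg.homing[0]) & (traj.t <= seg.homing[1])
    xy = traj.xy()[m]
    if xy.shape[0] < 2:
        raise ValueError("homing segment too short")
    steps = np.diff(xy, axis=0)
    moving = np.hypot(steps[:, 0], steps[:, 1]) > 1e-9
    headings = np.arctan2(steps[moving, 1], steps[moving, 0])
    med = _circular_median(headings)
    depart = xy[0]
    bearing = np.arctan2(bridge[1] - depart[1], bridge[0] - depart[0])
    return float(err_p), float(abs(wrap_delta(med - bearing)))


def lever_direction_tuning(spikes: SpikeTrain, traj: Trajectory,
                           trials: TrialEvents, radius: float = 18.0,
                           bin_deg: float = 10.0, n_shuffle: int = 100,
                           min_shift: float = 20.0,
                           seed: Optional[int] = None):
    """Firing rate vs direction of the animal around the lever, with MVL.

    The direction is that of the vector from the lever center to the mouse;
    only samples within ``radius`` cm of the lever are used, pooled across
    trials. The MVL weights each bin's unit vector by its firing rate. The
    chance MVL is the median over ``n_shuffle`` circular time-shifts of the
    position data relative to the spikes. Returns
    (bin_centers_rad, rate_hist, mvl, chance_mvl).
    """
    edges = np.deg2rad(np.arange(-180, 180 + bin_deg / 2, bin_deg))
    dt = traj.dt
    t0, T = traj.t[0], traj.duration

    def hist_for(shift: float):
        occ = np.zeros(edges.size - 1)
        cnt = np.zeros(edges.size - 1)
        sh_t = np.mod(traj.t - t0 + shift, T) + t0
        order = np.argsort(sh_t)
        xs, ys, ts = traj.x[order], traj.y[order], sh_t[order]
        for row in trials:
            m = (ts >= row.t_door_open) & (ts < row.t_door_close)
            dx = xs[m] - row.lever_x
            dy = ys[m] - row.lever_y
            near = np.hypot(dx, dy) <= radius
            occ += np.histogram(np.arctan2(dy[near], dx[near]), bins=edges)[0] * dt
            st = spikes.times[(spikes.times >= row.t_door_open) &
                              (spikes.times < row.t_door_close)]
            if st.size:
                px = np.interp(st, ts, xs) - row.lever_x
                py = np.interp(st, ts, ys) - row.lever_y
                nn = np.hypot(px, py) <= radius
                cnt += np.histogram(np.arctan2(py[nn], px[nn]), bins=edges)[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occ > 0, cnt / occ, np.nan)
        return rate, occ

    rate, occ = hist_for(0.0)
    if occ.sum() < 1.0:
        raise ValueError("less than 1 s of occupancy in the lever zone")
    centers = 0.5 * (edges[:-1] + edges[1:])

    def mvl_of(r):
        w = np.nan_to_num(r)
        tot = w.sum()
        if tot <= 0:
            return np.nan
        z = (w * np.exp(1j * centers)).sum() / tot
        return float(np.abs(z))

    mvl = mvl_of(rate)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    for i in range(n_shuffle):
        s = rng.uniform(min_shift, T - min_shift)
        null[i] = mvl_of(hist_for(s)[0])
    return centers, rate, mvl, float(np.nanmedian(null))


def lever_frame_stability(spikes: SpikeTrain, traj: Trajectory,
                          trials: TrialEvents, frame: str = "lever",
                          light: Optional[str] = None, bin_size: float = 1.0,
                          radius: float = 18.0, smooth_sd: float = 3.0,
                          min_trials: int = 6, min_overlap: int = 20,
                          seed: Optional[int] = None) -> float:
    """Split-half map stability in the lever or room reference frame.

    Trials (optionally restricted to one light condition) are split randomly
    into two equal groups; a firing-rate map is built per group from the
    samples within ``radius`` cm of the lever — positions relative to the
    lever (``frame='lever'``) or absolute positions over the identical time
    intervals (``frame='room'``) — and the Pearson r over jointly valid bins
    is returned.
    """
    if frame not in ("lever", "room"):
        raise ValueError("frame must be 'lever' or 'room'")
    rows = [row for row in trials
            if light is None or row.light == light]
    if len(rows) < min_trials:
        raise ValueError(f"need at least {min_trials} trials")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    halves = (order[: len(rows) // 2], order[len(rows) // 2:])

    dt = traj.dt
    half = np.ceil(radius / bin_size) * bin_size
    edges = np.arange(-half, half + bin_size / 2, bin_size)
    if frame == "room":
        lim = float(np.hypot(traj.x, traj.y).max()) + bin_size
        lim = np.ceil(lim / bin_size) * bin_size
        edges = np.arange(-lim, lim + bin_size / 2, bin_size)

    def build(sel):
        occ = np.zeros((edges.size - 1, edges.size - 1))
        cnt = np.zeros_like(occ)
        for k in sel:
            row = rows[k]
            m = (traj.t >= row.t_door_open) & (traj.t < row.t_door_close)
            dx = traj.x[m] - row.lever_x
            dy = traj.y[m] - row.lever_y
            near = np.hypot(dx, dy) <= radius
            if frame == "lever":
                px, py = dx[near], dy[near]
            else:
                px, py = traj.x[m][near], traj.y[m][near]
            occ += np.histogram2d(px, py, bins=[edges, edges])[0] * dt
            st = spikes.times[(spikes.times >= row.t_door_open) &
                              (spikes.times < row.t_door_close)]
            if st.size:
                pos = traj.position_at(st)
                sdx = pos[:, 0] - row.lever_x
                sdy = pos[:, 1] - row.lever_y
                nn = np.hypot(sdx, sdy) <= radius
                if frame == "lever":
                    qx, qy = sdx[nn], sdy[nn]
                else:
                    qx, qy = pos[nn, 0], pos[nn, 1]
                cnt += np.histogram2d(qx, qy, bins=[edges, edges])[0]
        from ._utils import masked_smooth2d
        valid = occ > 0
        s_occ = masked_smooth2d(occ, valid, smooth_sd / bin_size)
        s_cnt = masked_smooth2d(cnt, valid, smooth_sd / bin_size)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = s_cnt / s_occ
        rate[~valid] = np.nan
        return rate

    m1 = build(halves[0])
    m2 = build(halves[1])
    joint = np.isfinite(m1) & np.isfinite(m2)
    if joint.sum() < min_overlap:
        raise ValueError("insufficient jointly valid bins")
    return float(np.corrcoef(m1[joint], m2[joint])[0, 1])
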