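"""Trial segmentation, homing errors, lever-centered single-cell measures."""
import numpy as np
import pandas as pd
import pytest

import torusnav as tn
from torusnav.behavior import _dist_to_box
from torusnav.session_model import SpikeTrain, TrialEvents


def _manual_trial(lever=(0.0, 10.0), R=40.0, dt=0.02):
    """Straight in, orbit, straight out; known contact/leave geometry."""
    lever = np.array(lever)
    start = np.array([0.0, -(R - 2)])
    # inbound leg
    n1 = 200
    frac = np.linspace(0, 1, n1)
    inbound = start + frac[:, None] * (lever - start)
    # orbit at 5 cm for 2 s
    n2 = 100
    ang = np.linspace(0, 2 * np.pi, n2)
    orbit = lever + 5 * np.column_stack([np.cos(ang), np.sin(ang)])
    # outbound toward bridge
    n3 = 200
    out = orbit[-1] + np.linspace(0, 1, n3)[:, None] * \
        (np.array([0.0, -(R - 1)]) - orbit[-1])
    xy = np.vstack([inbound, orbit, out])
    t = np.arange(xy.shape[0]) * dt
    traj = tn.Trajectory(t, xy[:, 0], xy[:, 1])
    row = pd.Series(dict(trial_id=0, light="dark", t_door_open=0.0,
                         t_door_close=t[-1] + dt, t_lever_press=t[n1 + n2 // 2],
                         lever_x=lever[0], lever_y=lever[1],
                         bridge_x=0.0, bridge_y=-R, arena_rotation=0.0))
    return traj, row, R


class TestSegmentation:
    def test_boundaries_match_constructed_geometry(self):
        traj, row, R = _manual_trial()
        seg = tn.segment_trial(traj, row, arena_radius=R)
        assert seg.valid
        # contact when within 10 cm of the box outline on the inbound leg
        d = _dist_to_box(traj.xy(), (row.lever_x, row.lever_y))
        first_in = traj.t[np.flatnonzero(d < 10)[0]]
        assert seg.search[1] == pytest.approx(first_in)
        assert seg.at_lever[0] == seg.search[1]
        assert seg.homing[1] <= traj.t[-1]
        assert seg.periphery_xy is not None
        assert np.hypot(*seg.periphery_xy) >= R - 3 - 1e-9

    def test_lever_too_close_to_wall_invalid(self):
        traj, row, R = _manual_trial(lever=(0.0, 26.0))
        seg = tn.segment_trial(traj, row, arena_radius=R)
        assert not seg.valid

    def test_periphery_never_reached_open_ended(self):
        traj, row, R = _manual_trial()
        m = traj.t <= traj.t[320]  # truncate before homing completes
        short = tn.Trajectory(traj.t[m], traj.x[m], traj.y[m])
        row = row.copy()
        row.t_door_close = short.t[-1] + 0.02
        seg = tn.segment_trial(short, row, arena_radius=R)
        assert seg.homing_open_ended
        with pytest.raises(ValueError):
            tn.homing_errors(seg, short, (0, -R))


class TestHomingErrors:
    def test_crossing_at_bridge_zero_error(self):
        traj, row, R = _manual_trial()
        seg = tn.segment_trial(traj, row, arena_radius=R)
        err_p, err_h = tn.homing_errors(seg, traj, (0.0, -R))
        assert err_p < 0.1
        assert err_h < 0.2

    def test_diametrically_opposite_crossing(self):
        # homing path goes to +y instead of the bridge at -y
        R = 40.0
        n = 300
        xy = np.column_stack([np.zeros(n), np.linspace(10, R - 1, n)])
        t = np.arange(n) * 0.02
        traj = tn.Trajectory(t, xy[:, 0], xy[:, 1])
        from torusnav.behavior import TrialSegments
        seg = TrialSegments(0, (0, 0), (0, 0), (0.0, t[-1]),
                            xy[np.flatnonzero(np.hypot(*xy.T) >= R - 3)[0]],
                            np.array([0.0, 5.0]), True)
        err_p, _ = tn.homing_errors(seg, traj, (0.0, -R))
        assert err_p == pytest.approx(np.pi, abs=0.05)


class TestLeverDirectionTuning:
    def test_concentrated_and_uniform_mvl(self, foraging_traj):
        # synthetic trials table centered on the foraging arena
        rows = [dict(trial_id=i, light="dark", t_door_open=180.0 * i,
                     t_door_close=180.0 * (i + 1), t_lever_press=np.nan,
                     lever_x=0.0, lever_y=0.0, bridge_x=0, bridge_y=-25,
                     arena_rotation=0.0) for i in range(5)]
        trials = TrialEvents(pd.DataFrame(rows))
        # cell firing only when mouse is east of the lever
        xy = foraging_traj.xy()
        east = (np.arctan2(xy[:, 1], xy[:, 0]) < 0.3) & \
               (np.arctan2(xy[:, 1], xy[:, 0]) > -0.3) & \
               (np.hypot(*xy.T) < 18)
        times = foraging_traj.t[east]
        st = SpikeTrain("e", times[::3])
        centers, hist, mvl, chance = tn.lever_direction_tuning(
            st, foraging_traj, trials, n_shuffle=20, seed=1)
        assert mvl > 0.8
        assert mvl > chance
        # uniform cell
        rng = np.random.default_rng(2)
        uni = SpikeTrain("u", np.sort(rng.uniform(0, 900, 4000)))
        _, _, mvl_u, _ = tn.lever_direction_tuning(uni, foraging_traj, trials,
                                                   n_shuffle=5, seed=3)
        assert mvl_u < 0.15


class TestLeverFrameStability:
    def test_lever_frame_beats_room_frame_for_lever_locked_cell(self):
        # lever moves across trials; cell fires at a fixed offset from it
        rng = np.random.default_rng(4)
        dt = 0.02
        rows, xs, ys, ts = [], [], [], []
        spike_times = []
        t0 = 0.0
        for i in range(10):
            lever = rng.uniform(-15, 15, 2)
            n = 1500
            ang = rng.uniform(0, 2 * np.pi, n).cumsum() * 0  # noqa - placeholder
            walk = lever + rng.normal(0, 6, (n, 2)).cumsum(axis=0) * 0.05
            walk = lever + np.clip(walk - lever, -16, 16)
            tt = t0 + np.arange(n) * dt
            xs.append(walk[:, 0]); ys.append(walk[:, 1]); ts.append(tt)
            field = lever + np.array([5.0, 0.0])
            d = np.hypot(*(walk - field).T)
            lam = 30 * np.exp(-d ** 2 / (2 * 3 ** 2)) * dt
            spk = tt[rng.poisson(lam) > 0]
            spike_times.append(spk)
            rows.append(dict(trial_id=i, light="dark", t_door_open=tt[0],
                             t_door_close=tt[-1] + dt, t_lever_press=np.nan,
                             lever_x=lever[0], lever_y=lever[1],
                             bridge_x=0, bridge_y=-25, arena_rotation=0.0))
            t0 = tt[-1] + dt
        traj = tn.Trajectory(np.concatenate(ts), np.concatenate(xs),
                             np.concatenate(ys))
        st = SpikeTrain("lv", np.concatenate(spike_times))
        trials = TrialEvents(pd.DataFrame(rows))
        r_lever = tn.lever_frame_stability(st, traj, trials, frame="lever",
                                           seed=5)
        r_room = tn.lever_frame_stability(st, traj, trials, frame="room",
                                          seed=5)
        assert r_lever > r_room
        assert r_lever > 0.5

    def test_min_trials_enforced(self, foraging_traj):
        rows = [dict(trial_id=0, light="dark", t_door_open=0.0,
                     t_door_close=10.0, t_lever_press=np.nan, lever_x=0,
                     lever_y=0, bridge_x=0, bridge_y=-25, arena_rotation=0.0)]
        with pytest.raises(ValueError):
            tn.lever_frame_stability(SpikeTrain("x", [1.0]), foraging_traj,
                                     TrialEvents(pd.DataFrame(rows)))
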