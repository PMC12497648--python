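"""Movement reconstruction, directional errors, shuffle nulls, drift measures."""
import numpy as np
import pytest

import torusnav as tn
from torusnav._utils import wrap_delta
from torusnav.pathrecon import lever_vs_matched_drift


def _torus_path_of(traj, geom, n=None):
    xy = traj.xy() if n is None else traj.xy()[:n]
    v = tn.to_torus(xy, geom)
    t = traj.t if n is None else traj.t[:n]
    return tn.TorusPath(t, v[:, 0], v[:, 1], source="true")


class TestDecodedMovement:
    def test_ground_truth_passthrough_overlays_real_path(self, foraging_traj,
                                                         geom):
        tp = _torus_path_of(foraging_traj, geom)
        _, recon = tn.decoded_movement(tp, geom, foraging_traj.xy()[0])
        err = np.hypot(*(recon - foraging_traj.xy()).T)
        assert err.max() < 1e-6

    def test_zero_deltas_stationary(self, geom):
        tp = tn.TorusPath(np.arange(10), np.full(10, 1.0), np.full(10, 2.0))
        vec, recon = tn.decoded_movement(tp, geom, (3.0, 4.0))
        assert np.allclose(vec, 0)
        assert np.allclose(recon, [3.0, 4.0])

    def test_geometry_rotation_equivariance(self, foraging_traj):
        phi = 0.4
        g1 = tn.ModuleGeometry(0.0, np.pi / 3, 30, 30)
        g2 = tn.ModuleGeometry(phi, phi + np.pi / 3, 30, 30)
        tp = _torus_path_of(foraging_traj, g1, n=500)
        vec1, _ = tn.decoded_movement(tp, g1, (0, 0))
        vec2, _ = tn.decoded_movement(tp, g2, (0, 0))
        c, s = np.cos(phi), np.sin(phi)
        R = np.array([[c, -s], [s, c]])
        assert np.allclose(vec2, vec1 @ R.T, atol=1e-9)


class TestDirectionalErrors:
    def test_perfect_decoding(self):
        rng = np.random.default_rng(0)
        vec = rng.normal(0, 1, (500, 2))
        es = tn.directional_errors(vec, vec)
        assert es.precision == pytest.approx(1.0)
        assert es.rotation == pytest.approx(0.0, abs=1e-12)

    def test_constant_rotation_detected(self):
        rng = np.random.default_rng(1)
        vec = rng.normal(0, 1, (500, 2))
        rot = tn.apply_rotation(vec, np.deg2rad(30))
        es = tn.directional_errors(rot, vec)
        assert es.precision == pytest.approx(1.0)
        assert np.rad2deg(es.rotation) == pytest.approx(30.0)

    def test_random_decoding_near_zero_precision(self):
        rng = np.random.default_rng(2)
        n = 5000
        real = rng.normal(0, 1, (n, 2))
        dec = rng.normal(0, 1, (n, 2))
        es = tn.directional_errors(dec, real)
        assert es.precision < 2 / np.sqrt(n) * 3

    def test_precision_invariant_rotation_shifts(self):
        rng = np.random.default_rng(3)
        real = rng.normal(0, 1, (800, 2))
        dec = tn.apply_rotation(real, 0.1) + rng.normal(0, 0.2, (800, 2))
        base = tn.directional_errors(dec, real)
        shifted = tn.directional_errors(tn.apply_rotation(dec, 0.5), real)
        assert shifted.precision == pytest.approx(base.precision, abs=1e-9)
        assert wrap_delta(shifted.rotation - base.rotation) == pytest.approx(
            0.5, abs=1e-9)

    def test_empty_mask_undefined(self):
        with pytest.raises(ValueError):
            tn.directional_errors(np.ones((5, 2)), np.ones((5, 2)),
                                  np.zeros(5, bool))


class TestShuffleNull:
    def test_null_below_true_precision_and_deterministic(self, foraging_traj,
                                                         geom):
        tp = _torus_path_of(foraging_traj, geom)
        vec, _ = tn.decoded_movement(tp, geom, foraging_traj.xy()[0])
        real = np.diff(foraging_traj.xy(), axis=0)
        mask = np.hypot(*real.T) / foraging_traj.dt > 10
        es = tn.directional_errors(vec, real, mask)
        null, p95 = tn.shuffle_precision_null(vec, real, mask,
                                              foraging_traj.dt, n=200, seed=4)
        null2, _ = tn.shuffle_precision_null(vec, real, mask,
                                             foraging_traj.dt, n=200, seed=4)
        assert np.array_equal(null, null2)
        assert p95 < es.precision
        assert null.mean() < 0.1


class TestRotationCorrection:
    def test_session_correction_zeroes_residual(self):
        rng = np.random.default_rng(5)
        real = rng.normal(0, 1, (600, 2))
        dec = tn.apply_rotation(real, np.deg2rad(20))
        es = tn.directional_errors(dec, real)
        corr = tn.rotation_correction({"light": es})["light"]
        fixed = tn.directional_errors(tn.apply_rotation(dec, -corr), real)
        assert abs(fixed.rotation) < 1e-9
        assert np.rad2deg(corr) == pytest.approx(20.0, abs=1e-9)

    def test_small_condition_skipped(self):
        rng = np.random.default_rng(6)
        real = rng.normal(0, 1, (20, 2))
        es = tn.directional_errors(real, real)
        out = tn.rotation_correction({"dark": es}, min_samples=50)
        assert np.isnan(out["dark"])


class TestCumulativeError:
    def test_perfect_decoding_zero_error(self):
        t = np.arange(0, 10, 0.02)
        path = np.column_stack([np.cos(t), np.sin(t)]) * 10
        trials = [dict(t=t, recon=path, real=path, t_event=5.0)]
        grid = np.linspace(-3, 3, 31)
        _, err, cnt = tn.cumulative_decoding_error(trials, grid)
        assert np.allclose(err[cnt > 0], 0)

    def test_trials_without_event_skipped(self):
        t = np.arange(0, 5, 0.02)
        path = np.column_stack([t, t])
        trials = [dict(t=t, recon=path, real=path, t_event=None)]
        _, err, cnt = tn.cumulative_decoding_error(trials, np.linspace(-1, 1, 5))
        assert np.all(cnt == 0)


class TestLeverVsMatchedDrift:
    def test_identical_segments_give_zero(self):
        err = np.full(50, 0.4)
        lens = np.linspace(0, 100, 50)
        trials = [dict(search_err=err, search_len=lens, lever_err=err,
                       lever_len=30.0)]
        diffs = lever_vs_matched_drift(trials)
        assert diffs.shape == (1,)
        assert diffs[0] == pytest.approx(0.0, abs=1e-12)

    def test_injected_rotation_recovered(self):
        rng = np.random.default_rng(7)
        trials = []
        for _ in range(40):
            n = 200
            search = rng.normal(0.1, 0.05, n)
            lens = np.cumsum(rng.uniform(0.5, 1.5, n))
            lever = rng.normal(0.1 + np.deg2rad(10), 0.05, 80)
            trials.append(dict(search_err=search, search_len=lens,
                               lever_err=lever, lever_len=lens[-1] / 3))
        med = np.median(lever_vs_matched_drift(trials))
        assert np.rad2deg(med) == pytest.approx(10.0, abs=2.0)

    def test_short_search_skipped(self):
        trials = [dict(search_err=np.ones(5), search_len=np.arange(5.0),
                       lever_err=np.ones(5), lever_len=100.0)]
        assert lever_vs_matched_drift(trials).size == 0
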