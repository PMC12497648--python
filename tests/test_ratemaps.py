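"""Rate maps, autocorrelation, grid score, information score, similarity."""
import numpy as np
import pytest

import torusnav as tn
from torusnav.ratemaps import RateMap, grid_score
from torusnav.session_model import SpikeTrain


def _ideal_map(model, radius=40.0, bin_size=3.0):
    """Noiseless rate map evaluated directly from the grid model."""
    half = np.ceil(radius / bin_size) * bin_size
    edges = np.arange(-half, half + bin_size / 2, bin_size)
    c = 0.5 * (edges[:-1] + edges[1:])
    gx, gy = np.meshgrid(c, c, indexing="ij")
    inside = np.hypot(gx, gy) <= radius
    rate = tn.grid_rate(np.column_stack([gx.ravel(), gy.ravel()]),
                        model).reshape(gx.shape)
    rate[~inside] = np.nan
    occ = np.where(inside, 1.0, 0.0)
    return RateMap(edges, edges, rate, occ, inside)


class TestRateMap:
    def test_zero_spikes_zero_map(self, foraging_traj):
        rm = tn.rate_map(foraging_traj, SpikeTrain("e", []))
        assert np.nanmax(rm.rate) == 0.0

    def test_single_spike_unsmoothed(self):
        t = np.arange(200) * 0.02
        traj = tn.Trajectory(t, np.zeros(200), np.zeros(200))
        rm = tn.rate_map(traj, SpikeTrain("c", [1.0]), smooth_sd=0,
                         arena_radius=3.0)
        occ = rm.occupancy.sum()
        k = np.unravel_index(np.nanargmax(rm.rate), rm.rate.shape)
        assert rm.rate[k] == pytest.approx(1.0 / occ)

    def test_homogeneous_poisson_mean_rate(self, foraging_traj):
        rng = np.random.default_rng(2)
        lam = 5.0
        n = rng.poisson(lam * foraging_traj.duration)
        st = SpikeTrain("p", np.sort(rng.uniform(0, foraging_traj.duration, n)))
        rm = tn.rate_map(foraging_traj, st)
        occ_p = rm.occupancy[rm.valid] / rm.occupancy[rm.valid].sum()
        mean_rate = np.nansum(rm.rate[rm.valid] * occ_p)
        se = np.sqrt(lam / foraging_traj.duration)
        assert abs(mean_rate - lam) < 3 * se

    def test_occupancy_conservation(self, foraging_traj):
        rm = tn.rate_map(foraging_traj, SpikeTrain("e", []))
        assert rm.occupancy.sum() == pytest.approx(
            foraging_traj.duration, abs=2 * foraging_traj.dt)


class TestAutocorrelation:
    def test_center_is_one(self, module_session):
        traj, spikes, _, _ = module_session
        ac = tn.spatial_autocorrelation(tn.rate_map(traj, spikes[0]))
        ci, cj = np.array(ac.shape) // 2
        assert ac[ci, cj] == pytest.approx(1.0, abs=1e-9)

    def test_secondary_peaks_at_grid_period(self):
        m = tn.GridModel([0, np.pi / 3, 2 * np.pi / 3], [40.0] * 3,
                         [0.0] * 3, 10.0)
        ac = tn.spatial_autocorrelation(_ideal_map(m))
        gm = tn.grid_metrics(ac)
        # six inner peaks sit at the lattice constant 2 p / sqrt(3)
        ci, cj = np.array(ac.shape) // 2
        yy, xx = np.indices(ac.shape)
        rr = np.hypot(yy - ci, xx - cj) * 3.0
        ring = gm.annulus & np.isfinite(ac)
        peak_r = rr[ring][np.argmax(ac[ring])]
        assert abs(peak_r - 2 * 40 / np.sqrt(3)) < 4

    def test_white_noise_low_offcenter_correlation(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1, (25, 25))
        ac = tn.spatial_autocorrelation(noise)
        n = np.round(np.abs(np.fft.fft2(np.ones((25, 25))))).astype(int)
        ci, cj = np.array(ac.shape) // 2
        big_overlap = np.zeros_like(ac, bool)
        big_overlap[ci - 5:ci + 6, cj - 5:cj + 6] = True
        big_overlap[ci, cj] = False
        assert np.nanmax(np.abs(ac[big_overlap])) < 0.2


class TestGridMetrics:
    def test_ideal_grid_score_high_with_hexagonal_periodicity(self):
        m = tn.GridModel([0, np.pi / 3, 2 * np.pi / 3], [40.0] * 3,
                         [0.2, 0.9, 0.7], 10.0)
        ac = tn.spatial_autocorrelation(_ideal_map(m))
        gm = tn.grid_metrics(ac)
        assert gm.score > 0.8
        # periodicity peaks at 0, 60, 120 degrees
        for target in (0, 60, 120):
            k = np.argmin(np.abs(gm.periodicity_angles - target))
            window = np.abs(gm.periodicity_angles - target) <= 10
            assert np.nanmax(gm.periodicity[window]) > 0.7
        k30 = np.argmin(np.abs(gm.periodicity_angles - 30))
        assert gm.periodicity[k30] < 0.3

    def test_rotational_invariance_of_score(self):
        m = tn.GridModel([0.3, 0.3 + np.pi / 3, 0.3 + 2 * np.pi / 3],
                         [40.0] * 3, [0.0] * 3, 10.0)
        m2 = tn.GridModel(m.theta + np.pi / 3, m.p, m.o, m.pr)
        s1 = tn.grid_metrics(tn.spatial_autocorrelation(_ideal_map(m))).score
        s2 = tn.grid_metrics(tn.spatial_autocorrelation(_ideal_map(m2))).score
        assert abs(s1 - s2) < 0.05

    def test_radial_bump_undefined_or_zero(self):
        edges = np.arange(-39, 40, 3.0)
        c = 0.5 * (edges[:-1] + edges[1:])
        gx, gy = np.meshgrid(c, c, indexing="ij")
        bump = np.exp(-(np.hypot(gx, gy) ** 2) / (2 * 15 ** 2))
        ac = tn.spatial_autocorrelation(bump)
        with pytest.raises(ValueError):
            tn.grid_metrics(ac)  # no six fields: undefined, not low


class TestClassifyGrid:
    def test_simulated_grid_cell_classified(self, big_arena_traj):
        cells = tn.make_module(1, spacing=40, peak_rate=10, seed=41)
        spikes, _ = tn.simulate_module_spikes(big_arena_traj, cells, seed=42)
        thr, is_grid, obs, _ = tn.classify_grid(big_arena_traj, spikes[0],
                                                n_shuffle=200, seed=43)
        assert is_grid and obs > thr

    def test_low_rate_low_period_module_classified(self, big_arena_traj):
        # classification holds down to modest peak rates
        cells = tn.make_module(1, spacing=40, peak_rate=8, seed=44)
        spikes, _ = tn.simulate_module_spikes(big_arena_traj, cells, seed=45)
        _, is_grid, _, _ = tn.classify_grid(big_arena_traj, spikes[0],
                                            n_shuffle=200, seed=46)
        assert is_grid

    def test_min_shift_precondition(self, foraging_traj):
        short = foraging_traj.slice(0, 30)
        with pytest.raises(ValueError):
            tn.classify_grid(short, SpikeTrain("c", [1.0]), min_shift=20)


class TestInformationScore:
    def test_uniform_rate_zero_bits(self):
        assert tn.information_score([3.0, 3.0, 3.0],
                                    [0.2, 0.3, 0.5]) == pytest.approx(0.0)

    def test_two_bin_case_one_bit(self):
        assert tn.information_score([2.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            lam = rng.uniform(0, 10, 8)
            p = rng.dirichlet(np.ones(8))
            if (p * lam).sum() > 0:
                assert tn.information_score(lam, p) >= -1e-12

    def test_zero_mean_rate_undefined(self):
        with pytest.raises(ValueError):
            tn.information_score([0.0, 0.0], [0.5, 0.5])


class TestMapSimilarity:
    def test_self_similarity(self, module_session):
        traj, spikes, _, _ = module_session
        rm = tn.rate_map(traj, spikes[0])
        assert tn.map_similarity(rm, rm) == pytest.approx(1.0)

    def test_negation_about_mean(self, module_session):
        traj, spikes, _, _ = module_session
        rm = tn.rate_map(traj, spikes[0])
        neg = RateMap(rm.x_edges, rm.y_edges,
                      2 * np.nanmean(rm.rate) - rm.rate, rm.occupancy,
                      rm.valid)
        assert tn.map_similarity(rm, neg) == pytest.approx(-1.0)

    def test_binning_mismatch(self, module_session):
        traj, spikes, _, _ = module_session
        rm = tn.rate_map(traj, spikes[0])
        rm2 = tn.rate_map(traj, spikes[0], bin_size=5.0)
        with pytest.raises(ValueError):
            tn.map_similarity(rm, rm2)
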