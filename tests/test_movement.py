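"""Tests for Brownian bridges and space-time utilization distributions."""

import itertools

import numpy as np
import pytest

from seascapes import movement as mv


def brownian_detections(n, dt, sigma_m2, sigma_loc, seed, individual="bm"):
    """Observed Brownian motion: truth + iid location noise on every fix."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(sigma_m2 * dt), size=(n, 2))
    truth = np.cumsum(steps, axis=0)
    obs = truth + rng.normal(0.0, sigma_loc, size=(n, 2))
    t = np.arange(n, dtype=float) * dt
    return mv.DetectionSeries(individual, t, obs[:, 0], obs[:, 1])


class TestMotionVariance:
    def test_stationary_detections_give_zero(self):
        t = np.arange(10, dtype=float) * 600
        det = mv.DetectionSeries("a", t, np.zeros(10), np.zeros(10))
        assert mv.estimate_motion_variance(det, 300.0) < 1e-3

    def test_recovers_known_variance(self):
        # small location error so the bridge signal dominates
        estimates = [
            mv.estimate_motion_variance(
                brownian_detections(500, 600.0, 0.5, 10.0, seed), sigma_loc=10.0
            )
            for seed in range(5)
        ]
        assert abs(np.mean(estimates) - 0.5) / 0.5 < 0.25

    def test_translation_invariance(self):
        det = brownian_detections(100, 300.0, 0.2, 10.0, 3)
        shifted = mv.DetectionSeries("a", det.timestamps, det.x + 1e5, det.y - 2e4)
        a = mv.estimate_motion_variance(det, 10.0)
        b = mv.estimate_motion_variance(shifted, 10.0)
        assert a == pytest.approx(b, rel=1e-6)

    def test_too_few_detections_rejected(self):
        det = mv.DetectionSeries("a", np.array([0.0, 60.0]), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            mv.estimate_motion_variance(det, 300.0)


class TestBridgeDensity:
    params = mv.BridgeParams(sigma_loc=50.0, sigma_m2=0.5, max_gap=1e6)

    def test_endpoint_limit(self):
        mean, var = mv.bridge_moments([100, 200], [500, 800], 0, 600, 0.0, self.params)
        assert np.allclose(mean, [100, 200])
        assert var == pytest.approx(50.0**2)

    def test_midpoint_of_coincident_endpoints(self):
        mean, var = mv.bridge_moments([70, -30], [70, -30], 0, 600, 0.5, self.params)
        assert np.allclose(mean, [70, -30])

    def test_reversed_times_rejected(self):
        with pytest.raises(ValueError):
            mv.bridge_moments([0, 0], [1, 1], 10, 5, 0.5, self.params)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.75])
    def test_closed_form_matches_conditioned_random_walk(self, alpha):
        """Monte Carlo oracle: discrete random walk conditioned via the
        exact Gaussian bridge construction, plus endpoint location error."""
        rng = np.random.default_rng(int(alpha * 100))
        n_mc = 100_000
        T = 1200.0
        s2, sloc = 0.4, 30.0
        za_true = np.zeros((n_mc, 2))
        # simulate unconditional BM to time alpha*T and T, then condition by
        # sampling the bridge directly from its defining decomposition:
        #   W(aT) | W(T)=d  ~  N(a d, a(1-a) T s2)
        d = rng.normal(0, np.sqrt(s2 * T), size=(n_mc, 2))  # true displacement
        mid = alpha * d + rng.normal(0, np.sqrt(alpha * (1 - alpha) * T * s2), size=(n_mc, 2))
        # observed endpoints carry location error; the recorded start/end are
        # truth + noise, so truth = recorded - noise enters the mean
        ea = rng.normal(0, sloc, size=(n_mc, 2))
        eb = rng.normal(0, sloc, size=(n_mc, 2))
        za_obs = ea  # recorded start at origin + error
        zb_obs = d + eb
        # position relative to the *recorded* endpoints
        rel = mid - ((1 - alpha) * za_obs + alpha * zb_obs)
        params = mv.BridgeParams(sigma_loc=sloc, sigma_m2=s2, max_gap=1e9)
        _, var = mv.bridge_moments([0, 0], [0, 0], 0, T, alpha, params)
        mc_var = rel.var(axis=0).mean()
        # variance of the sample variance ~ 2 var^2 / n per axis
        sigma_mc = var * np.sqrt(2.0 / (2 * n_mc))
        assert abs(rel.mean()) < 4 * np.sqrt(var / (2 * n_mc))
        assert abs(mc_var - var) < 3 * sigma_mc

    def test_discretized_mass_sums_to_one(self):
        grid = mv.VoxelGrid(x0=-2000, y0=-2000, nx=40, ny=40, cell=100.0)
        dens = mv.bridge_density([0, 0], [100, 50], 0, 600, 0.5, self.params, grid)
        assert dens.sum() == pytest.approx(1.0, abs=1e-6)


class TestSpaceTimeUD:
    def test_two_detections_span_three_time_bins(self):
        grid = mv.VoxelGrid(x0=-1000, y0=-1000, nx=20, ny=20)
        det = mv.DetectionSeries("a", np.array([0.0, 1800.0]), np.array([0.0, 100.0]), np.zeros(2))
        params = mv.BridgeParams(sigma_loc=100.0, sigma_m2=0.01, max_gap=7200)
        vol = mv.spacetime_ud(det, grid, params)
        occupied = np.flatnonzero(vol.values.sum(axis=(0, 1)) > 0)
        assert list(occupied) == [0, 1, 2]
        assert vol.total_mass == pytest.approx(1.0, abs=1e-9)

    def test_single_receiver_concentrates_mass(self):
        grid = mv.VoxelGrid(x0=-3000, y0=-3000, nx=60, ny=60)
        n = 500
        t = np.arange(n) * 600.0
        det = mv.DetectionSeries("a", t, np.zeros(n), np.zeros(n))
        params = mv.BridgeParams(sigma_loc=300.0, sigma_m2=0.0, max_gap=7200)
        vol = mv.spacetime_ud(det, grid, params)
        planar = mv.planar_ud(vol)
        xc, yc = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
        within = np.hypot(xc, yc) <= 2 * 300.0
        assert planar.values[within].sum() > 0.95

    def test_time_marginal_proportional_to_occupancy(self):
        """Bookkeeping oracle on a 3-detection toy: per-bin mass follows
        the time each bridge spends in the bin."""
        grid = mv.VoxelGrid(x0=-5000, y0=-5000, nx=100, ny=100, tbin_minutes=10)
        t = np.array([0.0, 900.0, 1200.0])  # spans bins 0,1 (600+300) and bin 2 (0..300 of pair 2)
        det = mv.DetectionSeries("a", t, np.zeros(3), np.zeros(3))
        params = mv.BridgeParams(sigma_loc=100.0, sigma_m2=0.0, max_gap=7200)
        vol = mv.spacetime_ud(det, grid, params)
        marginal = vol.values.sum(axis=(0, 1))
        expected = np.zeros(grid.n_tbins)
        expected[0] = 600.0  # bridge 1 occupies all of bin 0
        expected[1] = 600.0  # bridge 1 (300 s) + bridge 2 (300 s)
        assert np.allclose(marginal[:3], (expected / expected.sum())[:3], atol=1e-6)

    def test_no_eligible_pairs_rejected(self):
        grid = mv.VoxelGrid(x0=-1000, y0=-1000, nx=20, ny=20)
        det = mv.DetectionSeries("a", np.array([0.0, 1e6]), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError, match="no eligible"):
            mv.spacetime_ud(det, grid, mv.BridgeParams(max_gap=3600))

    def test_24h_shift_invariance(self):
        grid = mv.VoxelGrid(x0=-2000, y0=-2000, nx=40, ny=40)
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 86400 * 3, size=50))
        x = rng.normal(0, 500, size=50)
        y = rng.normal(0, 500, size=50)
        params = mv.BridgeParams(sigma_loc=200.0, sigma_m2=0.05, max_gap=12 * 3600)
        a = mv.spacetime_ud(mv.DetectionSeries("a", t, x, y), grid, params)
        b = mv.spacetime_ud(mv.DetectionSeries("a", t + 86400.0, x, y), grid, params)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_wider_location_error_never_shrinks_spread(self):
        grid = mv.VoxelGrid(x0=-4000, y0=-4000, nx=80, ny=80)
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(0, 86400, size=40))
        x = rng.normal(0, 300, size=40)
        y = rng.normal(0, 300, size=40)
        det = mv.DetectionSeries("a", t, x, y)

        def iqr(vol):
            p = mv.planar_ud(vol).values.sum(axis=1)
            cum = np.cumsum(p)
            lo = np.searchsorted(cum, 0.25)
            hi = np.searchsorted(cum, 0.75)
            return hi - lo

        narrow = mv.spacetime_ud(det, grid, mv.BridgeParams(150.0, 0.01, 12 * 3600))
        wide = mv.spacetime_ud(det, grid, mv.BridgeParams(300.0, 0.01, 12 * 3600))
        assert iqr(wide) >= iqr(narrow)

    def test_per_slice_normalization_option(self):
        grid = mv.VoxelGrid(x0=-1000, y0=-1000, nx=20, ny=20)
        det = mv.DetectionSeries(
            "a", np.array([0.0, 600.0, 3000.0]), np.array([0.0, 100.0, 0.0]), np.zeros(3)
        )
        params = mv.BridgeParams(sigma_loc=100.0, sigma_m2=0.01, max_gap=7200)
        vol = mv.spacetime_ud(det, grid, params, per_slice_norm=True)
        slice_mass = vol.values.sum(axis=(0, 1))
        occupied = slice_mass > 0
        assert np.allclose(slice_mass[occupied], slice_mass[occupied][0], rtol=1e-9)
        assert vol.total_mass == pytest.approx(1.0, abs=1e-9)


class TestPlanarAndContour:
    def test_projection_preserves_single_voxel_mass(self):
        grid = mv.VoxelGrid(x0=0, y0=0, nx=4, ny=4, tbin_minutes=360)
        values = np.zeros((4, 4, 4))
        values[2, 1, 3] = 1.0
        planar = mv.planar_ud(mv.SpaceTimeUD(grid, values))
        assert planar.values[2, 1] == pytest.approx(1.0)
        assert planar.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_projection_stays_uniform(self):
        grid = mv.VoxelGrid(x0=0, y0=0, nx=3, ny=3, tbin_minutes=480)
        values = np.full((3, 3, 3), 1.0 / 27)
        planar = mv.planar_ud(mv.SpaceTimeUD(grid, values))
        assert np.allclose(planar.values, 1.0 / 9)

    def test_single_cell_contour(self):
        grid = mv.VoxelGrid(x0=0, y0=0, nx=3, ny=3)
        v = np.zeros((3, 3))
        v[1, 1] = 1.0
        mask = mv.ud_contour(mv.PlanarUD(grid, v), 0.5)
        assert mask.sum() == 1 and mask[1, 1]

    def test_uniform_four_cells_level_half(self):
        grid = mv.VoxelGrid(x0=0, y0=0, nx=2, ny=2)
        mask = mv.ud_contour(mv.PlanarUD(grid, np.full((2, 2), 0.25)), 0.5)
        assert mask.sum() == 2

    def test_greedy_equals_exhaustive_minimum(self, rng):
        """On 20 random cells, the greedy set has minimal cardinality at
        every level (checked against subset enumeration)."""
        weights = rng.dirichlet(np.ones(20))
        grid = mv.VoxelGrid(x0=0, y0=0, nx=4, ny=5)
        planar = mv.PlanarUD(grid, weights.reshape(4, 5))
        order = np.sort(weights)[::-1]
        for level in (0.2, 0.5, 0.8, 0.95):
            greedy = mv.ud_contour(planar, level).sum()
            # minimal cardinality: take largest cells first
            minimal = int(np.searchsorted(np.cumsum(order), level - 1e-12)) + 1
            assert greedy == minimal

    def test_bad_level_rejected(self):
        grid = mv.VoxelGrid(x0=0, y0=0, nx=2, ny=2)
        with pytest.raises(ValueError):
            mv.ud_contour(mv.PlanarUD(grid, np.full((2, 2), 0.25)), 1.5)


class TestNetCDFRoundTrip:
    def test_volume_round_trip(self, tmp_path):
        from seascapes.io import read_spacetime_ud

        grid = mv.VoxelGrid(x0=-500, y0=-500, nx=10, ny=10, tbin_minutes=60)
        rng = np.random.default_rng(2)
        values = rng.random((10, 10, 24))
        values /= values.sum()
        vol = mv.SpaceTimeUD(grid, values)
        path = tmp_path / "ud.nc"
        vol.to_netcdf(path)
        back = read_spacetime_ud(path)
        assert back.grid == grid
        assert np.allclose(back.values, values)
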