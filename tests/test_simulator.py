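"""Synthetic coincidence generator, phantoms, and fan-sum efficiencies."""

import numpy as np
import pytest
from scipy import stats

import petalign as pa
from petalign.simulator import hotrod_layout, sample_emission_points
from petalign.tof import TOFModel


@pytest.fixture(scope="module")
def tof():
    return TOFModel(250.0, range_mm=45.0)


class TestVoxelizePhantom:
    def test_point_source_at_voxel_center_single_hot_voxel(self):
        spec = pa.PhantomSpec.point_sources([[0.25, 0.25, 0.25]], 0.01)
        g = pa.voxelize_phantom(spec, spacing=0.5, padding=1.0)
        nz = np.nonzero(g.values)
        assert len(nz[0]) == 1
        assert g.total_mass == pytest.approx(1.0, rel=1e-9)

    def test_point_source_centroid_preserved(self):
        c = np.array([0.137, -0.291, 0.412])
        spec = pa.PhantomSpec.point_sources([c], 0.01)
        g = pa.voxelize_phantom(spec, spacing=0.5, padding=1.0)
        xs, ys, zs = g.voxel_centers()
        w = g.values
        centroid = np.array([
            (w.sum(axis=(1, 2)) * xs).sum(),
            (w.sum(axis=(0, 2)) * ys).sum(),
            (w.sum(axis=(0, 1)) * zs).sum(),
        ]) / w.sum()
        assert np.max(np.abs(centroid - c)) < 1e-9

    def test_straight_tube_volume_matches_cylinder(self):
        # oblique straight "tube" through collinear control points
        p0 = np.array([-6.0, -4.5, -3.0])
        p1 = np.array([6.0, 4.5, 3.0])
        pts = np.linspace(p0, p1, 10)
        spec = pa.PhantomSpec.bspline_tube(pts, diameter=1.0)
        g = pa.voxelize_phantom(spec, spacing=0.125, padding=0.5)
        length = np.linalg.norm(p1 - p0)
        want = np.pi * 0.5**2 * length
        # coverage-fraction rasterization: volume = sum(fractions) * h^3,
        # where the fraction is value / (full-coverage value)
        cover_vol = (g.values * 0.125**3).sum() / g.values.max()
        assert cover_vol == pytest.approx(want, rel=0.05)

    def test_total_mass_proportional_to_activity(self):
        spec = pa.PhantomSpec.point_sources(
            [[0, 0, 0], [3, 0, 0]], 0.01, activities=[2.0, 5.0]
        )
        g = pa.voxelize_phantom(spec, 0.5, 1.0)
        assert g.total_mass == pytest.approx(7.0, rel=1e-9)

    def test_empty_phantom_raises(self):
        with pytest.raises(ValueError):
            pa.PhantomSpec.point_sources([[0, 0, 0]], 0.1, activities=[0.0])


class TestSampleEmissionPoints:
    def test_tube_points_near_curve(self, rng):
        pts = np.array([[0, 0, -5.0], [1.0, 2.0, 0.0], [0, 0, 5.0]])
        spec = pa.PhantomSpec.bspline_tube(pts, diameter=0.25)
        samples = sample_emission_points(spec, 2000, rng)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(spec.curve_points()).query(samples)
        assert np.max(d) <= 0.125 + 0.02

    def test_shell_radii_in_band(self, rng):
        spec = pa.PhantomSpec.cylindrical_shell(10.0, 2.0, 20.0)
        s = sample_emission_points(spec, 5000, rng)
        r = np.hypot(s[:, 0], s[:, 1])
        assert np.all((r >= 9.0 - 1e-9) & (r <= 11.0 + 1e-9))
        assert np.all(np.abs(s[:, 2]) <= 10.0)

    def test_grid_sampling_matches_density(self, rng):
        vals = np.zeros((12, 12, 4))
        vals[3, 3, :] = 1.0
        vals[8, 8, :] = 3.0
        g = pa.VoxelGrid(np.zeros(3), np.ones(3), vals)
        s = sample_emission_points(g, 8000, rng)
        near_hot = np.hypot(s[:, 0] - 8.5, s[:, 1] - 8.5) < 2.0
        frac = near_hot.mean()
        assert frac == pytest.approx(0.75, abs=0.04)


class TestSimulateEvents:
    def test_zero_events_empty(self, small_scanner, tof, rng):
        bp, lut = small_scanner
        spec = pa.PhantomSpec.point_sources([[0, 0, 0]], 0.1)
        ev = pa.simulate_events(bp, lut, spec, None, None, tof, 0, rng)
        assert len(ev) == 0

    def test_seed_determinism(self, small_scanner, tof):
        bp, lut = small_scanner
        spec = pa.PhantomSpec.point_sources([[0, 0, 0]], 0.1)
        a = pa.simulate_events(bp, lut, spec, None, None, tof, 2000,
                               np.random.default_rng(42))
        b = pa.simulate_events(bp, lut, spec, None, None, tof, 2000,
                               np.random.default_rng(42))
        for col in ("d1", "cr1", "d2", "cr2", "t"):
            assert np.array_equal(getattr(a, col), getattr(b, col))

    def test_centered_source_uniform_across_blocks(self, small_scanner, tof):
        bp, lut = small_scanner
        spec = pa.PhantomSpec.point_sources([[0, 0, 0]], 0.1)
        ev = pa.simulate_events(bp, lut, spec, None, None, tof, 40000,
                                np.random.default_rng(3))
        singles = np.bincount(np.concatenate([ev.d1, ev.d2]), minlength=16)
        # azimuthal symmetry: blocks within a ring should be multinomially
        # uniform; compare against 4 sigma Poisson bands
        for ring in (singles[:8], singles[8:]):
            mu = ring.mean()
            assert np.all(np.abs(ring - mu) < 4 * np.sqrt(mu))

    def test_tof_histogram_matches_kernel_mass(self, small_scanner):
        bp, lut = small_scanner
        tof = TOFModel(250.0, range_mm=45.0)
        spec = pa.PhantomSpec.point_sources([[0, 0, 0]], 0.01)
        # entry-face mode (mu_crystal=0): for a centred source both entry
        # paths are equal by symmetry, so the measured offset is pure
        # Gaussian timing blur
        ev = pa.simulate_events(bp, lut, spec, None, None, tof, 100000,
                                np.random.default_rng(9), mu_crystal=0.0)
        counts = np.bincount(ev.t, minlength=tof.n_bins)
        # emissions at the centre: signed offset ~ N(0, sigma) (plus a
        # sub-mm crystal-depth correction), binned
        edges = (np.arange(tof.n_bins + 1) - tof.n_bins / 2) * tof.bin_width
        probs = np.diff(stats.norm.cdf(edges, scale=tof.kernel_sigma))
        probs /= probs.sum()
        chi2 = ((counts - len(ev) * probs) ** 2 / (len(ev) * probs)).sum()
        p = stats.chi2.sf(chi2, df=tof.n_bins - 1)
        assert p > 0.001

    def test_halving_efficiencies_quarters_acceptance(self, small_scanner, tof):
        bp, lut = small_scanner
        spec = pa.PhantomSpec.point_sources([[0, 0, 0]], 0.1)
        full = pa.EfficiencyTable.uniform(bp.n_detectors, lut.n_crystals)
        # efficiency thinning is relative to the max entry: to probe absolute
        # acceptance, give one crystal full efficiency and the rest 0.5
        half = pa.EfficiencyTable(np.full((bp.n_detectors, lut.n_crystals), 0.5))
        half.eff[0, 0] = 1.0
        n_trials = 60000
        # count accepted events among a fixed number of trials
        def accepted(eff):
            return len(pa.simulate_events(bp, lut, spec, None, eff, tof, 10**9,
                                          np.random.default_rng(5), n_trials,
                                          strict=False))
        n_full = accepted(full)
        n_half = accepted(half)
        ratio = n_half / n_full
        se = ratio * np.sqrt(1 / n_half + 1 / n_full)
        assert abs(ratio - 0.25) < 4 * se + 0.01


class TestSelfConsistency:
    def test_event_counts_match_expected_rates_chi2(self):
        """Central oracle: simulated per-bin counts vs the forward model.

        Two opposing blocks far apart (so solid-angle factors, which the
        line-integral rate model deliberately omits, are nearly constant
        across crystal pairs), a smooth central blob sampled exactly from
        its trilinear density, and a global chi-square over all bins with
        expected count >= 5 (remainder pooled).
        """
        from petalign import _kernels
        from scipy.ndimage import gaussian_filter

        bp = pa.make_cylindrical_blueprint(2, 1, 50.0, (16.0, 10.0, 16.0))
        lut = pa.CrystalLUT.regular((16.0, 10.0, 16.0), (4, 1, 4))
        tof = TOFModel(250.0, range_mm=60.0)
        n = 36
        vals = np.zeros((n, n, n))
        vals[n // 2, n // 2, n // 2] = 1.0
        vals = gaussian_filter(vals, 6.0)
        grid = pa.VoxelGrid(np.full(3, -n * 0.5 / 2), np.full(3, 0.5), vals)
        ev = pa.simulate_events(bp, lut, grid, None, None, tof, 30000,
                                np.random.default_rng(42), max_trials=200_000_000)
        hist = pa.histogram_events(ev, bp.n_detectors, lut.n_crystals, tof)

        ncr = lut.n_crystals
        c1, c2, t = np.meshgrid(np.arange(ncr), np.arange(ncr),
                                np.arange(tof.n_bins), indexing="ij")
        nb = c1.size
        eff = pa.EfficiencyTable.uniform(2, ncr)
        rates = np.zeros(nb)
        jr = np.random.default_rng(7)
        ns = 32
        _kernels.batch_expected_and_grad(
            np.zeros(nb, np.int64), c1.ravel().astype(np.int64),
            np.ones(nb, np.int64), c2.ravel().astype(np.int64),
            t.ravel().astype(np.int64),
            bp.positions.copy(), bp.basis.copy(), np.zeros((2, 3, 3, 3)),
            lut.centers, lut.half_extents, eff.eff,
            jr.uniform(-1, 1, (nb, ns, 3)), jr.uniform(-1, 1, (nb, ns, 3)),
            grid.values, grid.origin, grid.spacing,
            grid.values, grid.origin, grid.spacing,
            False, np.zeros((1, 1, 1)), np.zeros(3), np.ones(3),
            tof.bin_centers, tof.kernel_sigma, tof.bin_width, tof.no_tof,
            1024, 1024, False, rates, np.zeros((nb, 12)))
        obs = np.zeros(nb)
        code = (hist.cr1 * ncr + hist.cr2) * tof.n_bins + hist.t
        np.add.at(obs, code, hist.counts)
        exp = rates / rates.sum() * obs.sum()
        big = exp >= 5
        chi2 = ((obs[big] - exp[big]) ** 2 / exp[big]).sum()
        chi2 += (obs[~big].sum() - exp[~big].sum()) ** 2 / exp[~big].sum()
        p = stats.chi2.sf(chi2, int(big.sum()))
        assert p > 0.001


class TestFanAcceptance:
    def test_nine_partners_for_middle_ring(self):
        bp = pa.make_cylindrical_blueprint(8, 3, 75.0)
        acc = pa.make_fan_acceptance(bp, n_opposing=3, include_axial_neighbors=True)
        middle = 8  # first block of the middle ring
        partners = np.nonzero(acc.matrix[middle])[0]
        assert len(partners) >= 9  # 3 opposed x 3 rings, plus symmetrized adds

    def test_single_ring_single_opposing(self):
        bp = pa.make_cylindrical_blueprint(8, 1, 40.0, (24.0, 10.0, 24.0))
        acc = pa.make_fan_acceptance(bp, 1, include_axial_neighbors=False)
        assert np.array_equal(np.nonzero(acc.matrix[0])[0], [4])

    def test_symmetry(self):
        bp = pa.make_cylindrical_blueprint(6, 2, 40.0, (24.0, 10.0, 24.0))
        acc = pa.make_fan_acceptance(bp, 2)
        assert np.array_equal(acc.matrix, acc.matrix.T)
        for d1 in range(12):
            for d2 in range(12):
                assert acc(d1, d2) == acc(d2, d1)


class TestFanSumEfficiencies:
    def test_two_crystals_mutual_events(self, tof):
        ev = [pa.ListModeEvent(pa.CrystalID(0, 3), pa.CrystalID(4, 9), 2)] * 7
        h = pa.histogram_events(ev, 8, 16, tof)
        eff = pa.fan_sum_efficiencies(h)
        assert eff.eff[0, 3] == 7
        assert eff.eff[4, 9] == 7
        assert eff.eff.sum() == 14

    def test_empty_histogram_raises(self, tof):
        h = pa.histogram_events([], 8, 16, tof)
        with pytest.raises(ValueError):
            pa.fan_sum_efficiencies(h)

    def test_recovers_two_to_one_efficiency_ratio(self, small_scanner, tof):
        bp, lut = small_scanner
        spec = pa.PhantomSpec.cylindrical_shell(14.0, 2.0, 30.0)
        eff_true = pa.EfficiencyTable(np.ones((bp.n_detectors, lut.n_crystals)))
        # halve every crystal of block 2: otherwise symmetric scanner
        eff_true.eff[2, :] = 0.5
        ev = pa.simulate_events(bp, lut, spec, None, eff_true, tof, 60000,
                                np.random.default_rng(8))
        h = pa.histogram_events(ev, bp.n_detectors, lut.n_crystals, tof)
        est = pa.fan_sum_efficiencies(h)
        # compare block 2 against its ring partners 0,4,6 (same geometry class)
        per_block = est.eff.sum(axis=1)
        ref = np.mean([per_block[0], per_block[4], per_block[6]])
        ratio = ref / per_block[2]
        se = ratio * np.sqrt(1 / per_block[2] + 1 / (3 * ref))
        assert abs(ratio - 2.0) < 4 * se + 0.1


class TestHotrodLayout:
    def test_six_sectors_all_diameters(self):
        rods = hotrod_layout()
        assert set(np.round(rods[:, 2], 3)) == {2.0, 1.5, 1.2, 1.0, 0.9, 0.8}
        assert np.all(np.hypot(rods[:, 0], rods[:, 1]) < 14.0)

    def test_rods_do_not_overlap(self):
        rods = hotrod_layout()
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(rods[:, :2]))
        np.fill_diagonal(d, np.inf)
        rr = rods[:, 2][:, None] / 2 + rods[:, 2][None, :] / 2
        assert np.all(d > rr - 1e-9)
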