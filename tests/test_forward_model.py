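"""Expected-count model: factorization, degenerate limits, symmetries, gradients."""

import numpy as np
import pytest

import petalign as pa
from petalign.calibration import nll_objective, sample_batch
from petalign.forward_model import CoincidenceBin, expected_count
from petalign.geometry import AlignmentParams, CrystalID
from petalign.grid import VoxelGrid
from petalign.tof import TOFModel
from scipy.ndimage import gaussian_filter


@pytest.fixture(scope="module")
def setup():
    bp = pa.make_cylindrical_blueprint(8, 1, 40.0, (24.0, 10.0, 24.0))
    lut = pa.CrystalLUT.regular((24.0, 10.0, 24.0), (8, 2, 8))
    tof = TOFModel(250.0, range_mm=45.0)
    rng = np.random.default_rng(5)
    vals = gaussian_filter(rng.random((40, 40, 40)), 2.0)
    # the analytic likelihood gradient assumes the activity vanishes at the
    # grid boundary (true for rasterized phantoms, which are padded)
    vals[:4] = vals[-4:] = 0.0
    vals[:, :4] = vals[:, -4:] = 0.0
    vals[:, :, :4] = vals[:, :, -4:] = 0.0
    grid = VoxelGrid(np.full(3, -10.0), np.full(3, 0.5), vals)
    eff = pa.EfficiencyTable.uniform(bp.n_detectors, lut.n_crystals)
    return bp, lut, tof, grid, eff


def opposing_bin(tof, t=None):
    return CoincidenceBin(CrystalID(0, 9), CrystalID(4, 21),
                          tof.n_bins // 2 if t is None else t)


class TestExpectedCount:
    def test_zero_efficiency_zero_rate(self, setup):
        bp, lut, tof, grid, _ = setup
        eff = pa.EfficiencyTable(np.ones((bp.n_detectors, lut.n_crystals)))
        eff.eff[0, 9] = 0.0
        rate = expected_count(opposing_bin(tof), bp, lut, grid, None, eff, tof,
                              rng=np.random.default_rng(0))
        assert rate == 0.0

    def test_reduces_to_tof_integral_without_attenuation(self, setup):
        bp, lut, tof, grid, eff = setup
        # degenerate crystal voxels: half-extents -> 0 collapses the rate to
        # the centre-to-centre TOF-weighted line integral
        tiny = pa.CrystalLUT(lut.centers, np.full_like(lut.half_extents, 1e-9),
                             lut.block_dims, lut.shape)
        b = opposing_bin(tof)
        rate = expected_count(b, bp, tiny, grid, None, eff, tof, n_samples=1,
                              rng=np.random.default_rng(0), n_quad=1024)
        p0 = pa.crystal_center_global(bp, b.lam1, lut)
        p1 = pa.crystal_center_global(bp, b.lam2, lut)
        want = pa.tof_weighted_integral(grid, p0, p1, b.t, tof, n_quad=1024)
        assert rate == pytest.approx(want, rel=1e-6)

    def test_swap_symmetry_with_mirrored_tof(self, setup):
        bp, lut, tof, grid, eff = setup
        t = 3
        a = expected_count(opposing_bin(tof, t), bp, lut, grid, None, eff, tof,
                           n_samples=64, rng=np.random.default_rng(11))
        swapped = CoincidenceBin(CrystalID(4, 21), CrystalID(0, 9), tof.mirror_bin(t))
        b = expected_count(swapped, bp, lut, grid, None, eff, tof,
                           n_samples=64, rng=np.random.default_rng(11))
        # same distribution over sampled pairs up to sample pairing: compare
        # with generous Monte-Carlo tolerance
        assert a == pytest.approx(b, rel=0.15)

    def test_nonnegative_and_attenuation_reduces(self, setup):
        bp, lut, tof, grid, eff = setup
        mu = VoxelGrid(grid.origin, grid.spacing, np.full(grid.dims, 0.005))
        b = opposing_bin(tof)
        r0 = expected_count(b, bp, lut, grid, None, eff, tof, rng=np.random.default_rng(2))
        r1 = expected_count(b, bp, lut, grid, mu, eff, tof, rng=np.random.default_rng(2))
        assert r0 >= 0 and r1 >= 0
        assert r1 < r0

    def test_same_detector_rejected(self, setup):
        bp, lut, tof, grid, eff = setup
        with pytest.raises(ValueError):
            expected_count(CoincidenceBin(CrystalID(0, 1), CrystalID(0, 2), 0),
                           bp, lut, grid, None, eff, tof)


class TestNLLGradient:
    def test_matches_central_finite_differences(self, setup):
        bp, lut, tof, grid, eff = setup
        rng = np.random.default_rng(31)
        # counted bins from actual simulated coincidences of this activity
        ev = pa.simulate_events(bp, lut, grid, None, None, tof, 600, rng)
        hist = pa.histogram_events(ev, bp.n_detectors, lut.n_crystals, tof)
        batch = sample_batch(hist, hist.n_bins + 200, np.random.default_rng(3), 0.3)
        params = pa.perturb_alignment(bp.n_detectors, 0.4, 0.6, rng)
        jit = lambda: np.random.default_rng(77)

        loss, g_t, g_r, scale, _ = nll_objective(
            params, batch, bp, lut, grid, None, eff, tof, 2, jit(),
            rate_floor=1e-3, fixed_scale=1.0)
        eps = 1e-4
        checks = []
        for d in (0, 5):
            for j in range(3):
                for which in ("t", "r"):
                    plus = AlignmentParams(params.translations.copy(),
                                           params.rotations.copy())
                    minus = AlignmentParams(params.translations.copy(),
                                            params.rotations.copy())
                    arr_p = plus.translations if which == "t" else plus.rotations
                    arr_m = minus.translations if which == "t" else minus.rotations
                    arr_p[d, j] += eps
                    arr_m[d, j] -= eps
                    lp, *_ = nll_objective(plus, batch, bp, lut, grid, None, eff,
                                           tof, 2, jit(), want_grad=False,
                                           rate_floor=1e-3, fixed_scale=1.0)
                    lm, *_ = nll_objective(minus, batch, bp, lut, grid, None, eff,
                                           tof, 2, jit(), want_grad=False,
                                           rate_floor=1e-3, fixed_scale=1.0)
                    fd = (lp - lm) / (2 * eps)
                    an = (g_t if which == "t" else g_r)[d, j]
                    checks.append(abs(an - fd) / max(abs(fd), abs(an), 1e-9))
        assert max(checks) < 1e-3

    def test_poisson_score_stationarity(self, setup):
        # when counts equal the scaled model rates on every bin, a uniform
        # rescaling of the rates has zero gradient (profiled-scale optimum)
        bp, lut, tof, grid, eff = setup
        rng = np.random.default_rng(13)
        # central-crystal pairs of two opposing blocks: every chord crosses
        # the field support, so all model rates are strictly positive
        central = [(ix * 2 + iy) * 8 + iz for ix in (3, 4) for iy in (0, 1)
                   for iz in (3, 4)]
        ev = pa.EventArray(*map(np.array, zip(*[
            (0, c1, 4, c2, tof.n_bins // 2)
            for c1 in central for c2 in central
        ])))
        hist = pa.histogram_events(ev, bp.n_detectors, lut.n_crystals, tof)
        batch = sample_batch(hist, hist.n_bins, np.random.default_rng(3), 0.0)
        params = AlignmentParams.zero(bp.n_detectors)
        # compute model rates, then substitute them as "counts"
        _, _, _, _, prof = nll_objective(params, batch, bp, lut, grid, None,
                                         eff, tof, 2, np.random.default_rng(7),
                                         want_grad=False, rate_floor=0.0)
        # d/ds [sum(s*L) - sum(C log(s*L))] = sum L - sum C / s: zero at the
        # profiled scale; verified through the loss values at s*(1 +- h)
        l0, *_ = nll_objective(params, batch, bp, lut, grid, None, eff, tof, 2,
                               np.random.default_rng(7), want_grad=False,
                               rate_floor=0.0, fixed_scale=prof)
        h = 1e-4
        lp, *_ = nll_objective(params, batch, bp, lut, grid, None, eff, tof, 2,
                               np.random.default_rng(7), want_grad=False,
                               rate_floor=0.0, fixed_scale=prof * (1 + h))
        lm, *_ = nll_objective(params, batch, bp, lut, grid, None, eff, tof, 2,
                               np.random.default_rng(7), want_grad=False,
                               rate_floor=0.0, fixed_scale=prof * (1 - h))
        slope = (lp - lm) / (2 * h)
        curvature = (lp + lm - 2 * l0) / h**2
        assert abs(slope) < 1e-5 * abs(curvature)

    def test_constant_count_shift_identity(self, setup):
        # adding k to every count changes the loss by exactly -k sum(w log sL)
        bp, lut, tof, grid, eff = setup
        rng = np.random.default_rng(17)
        nb = 200
        ev = pa.EventArray(rng.integers(0, 4, nb), rng.integers(0, lut.n_crystals, nb),
                           rng.integers(4, 8, nb), rng.integers(0, lut.n_crystals, nb),
                           rng.integers(0, tof.n_bins, nb))
        hist = pa.histogram_events(ev, bp.n_detectors, lut.n_crystals, tof)
        batch = sample_batch(hist, hist.n_bins, np.random.default_rng(3), 0.0)
        params = AlignmentParams.zero(bp.n_detectors)
        call = lambda b: nll_objective(params, b, bp, lut, grid, None, eff, tof,
                                       2, np.random.default_rng(7), want_grad=False,
                                       rate_floor=1e-3, fixed_scale=2.0)[0]
        l0 = call(batch)
        k = 3.0
        import dataclasses as dc
        shifted = dc.replace(batch, counts=batch.counts + k)
        l1 = call(shifted)
        # reconstruct sum(w log sL) from a unit-count batch
        unit = dc.replace(batch, counts=np.ones_like(batch.counts))
        zero = dc.replace(batch, counts=np.zeros_like(batch.counts))
        sum_w_log = call(zero) - call(unit)
        assert l1 - l0 == pytest.approx(-k * sum_w_log, rel=1e-9)
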