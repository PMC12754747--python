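"""Geometry: rotations, alignment application, crystal mapping, blueprints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import petalign as pa
from petalign.geometry import (
    AlignmentParams,
    euler_matrix,
    local_rotation_matrix,
)

ANGLES = st.floats(-180.0, 180.0, allow_nan=False)


def random_frame(rng):
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestLocalRotationMatrix:
    def test_zero_angles_identity(self, rng):
        b = random_frame(rng)
        assert np.allclose(local_rotation_matrix((0, 0, 0), b), np.eye(3), atol=1e-12)

    def test_quarter_turn_about_global_z(self):
        m = local_rotation_matrix((0, 0, 90.0), np.eye(3))
        assert np.allclose(m @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(ax=ANGLES, ay=ANGLES, az=ANGLES, seed=st.integers(0, 2**31 - 1))
    def test_proper_rotation(self, ax, ay, az, seed):
        b = random_frame(np.random.default_rng(seed))
        m = local_rotation_matrix((ax, ay, az), b)
        assert np.allclose(m.T @ m, np.eye(3), atol=1e-9)
        assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-9)

    def test_small_angle_composition_commutes(self, rng):
        # regression guard for the intrinsic x->y->z convention
        angles = rng.uniform(-0.1, 0.1, 3)
        m_xyz = euler_matrix(angles)
        m_zyx = (
            euler_matrix((angles[0], 0, 0))
            @ euler_matrix((0, angles[1], 0))
            @ euler_matrix((0, 0, angles[2]))
        )
        assert np.max(np.abs(m_xyz - m_zyx)) < 1e-5

    def test_rejects_non_orthonormal_axes(self):
        with pytest.raises(pa.InvalidGeometryError):
            local_rotation_matrix((1, 2, 3), np.ones((3, 3)))


class TestApplyAlignment:
    def test_zero_params_is_identity(self, small_scanner):
        bp, _ = small_scanner
        out = pa.apply_alignment(bp, AlignmentParams.zero(bp.n_detectors))
        assert np.array_equal(out.positions, bp.positions)
        assert np.array_equal(out.axes_x, bp.axes_x)

    def test_pure_translation_shifts_position_only(self, small_scanner):
        bp, _ = small_scanner
        p = AlignmentParams.zero(bp.n_detectors)
        p.translations[0] = (1.0, 2.0, 3.0)
        out = pa.apply_alignment(bp, p)
        assert np.allclose(out.positions[0] - bp.positions[0], (1, 2, 3))
        assert np.allclose(out.positions[1:], bp.positions[1:])
        assert np.allclose(out.axes_y, bp.axes_y)

    def test_round_trip_inverse(self, small_scanner, rng):
        bp, _ = small_scanner
        params = pa.perturb_alignment(bp.n_detectors, 1.5, 2.0, rng)
        moved = pa.apply_alignment(bp, params)
        # inverse: negate translation; invert the rotation about the *moved*
        # blocks' own axes is not the stored convention, so rebuild directly
        back = pa.BlueprintGeometry.from_basis(
            moved.positions - params.translations,
            np.stack([
                moved.basis[d] @ euler_matrix(params.rotations[d]).T
                for d in range(bp.n_detectors)
            ]),
        )
        assert np.max(np.abs(back.positions - bp.positions)) < 1e-9
        assert np.max(np.abs(back.basis - bp.basis)) < 1e-9

    def test_preserves_orthonormality(self, small_scanner, rng):
        bp, _ = small_scanner
        out = pa.apply_alignment(bp, pa.perturb_alignment(bp.n_detectors, 3.0, 30.0, rng))
        gram = np.einsum("nij,nik->njk", out.basis, out.basis)
        assert np.max(np.abs(gram - np.eye(3))) < 1e-9

    def test_mismatched_ndet_raises(self, small_scanner):
        bp, _ = small_scanner
        with pytest.raises(pa.InvalidGeometryError):
            pa.apply_alignment(bp, AlignmentParams.zero(bp.n_detectors + 1))

    def test_share_map_ties_groups(self, small_scanner, rng):
        bp, _ = small_scanner
        share = np.arange(bp.n_detectors) // 8  # one group per ring
        params = pa.perturb_alignment(bp.n_detectors, 1.0, 1.0, rng, share_map=share)
        full = params.expanded()
        assert full.translations.shape == (bp.n_detectors, 3)
        for g in range(2):
            rows = full.translations[share == g]
            assert np.all(rows == rows[0])


class TestCrystalCenterGlobal:
    def test_zero_local_center_is_block_position(self, small_scanner):
        bp, _ = small_scanner
        lut = pa.CrystalLUT(
            np.zeros((1, 3)), np.full((1, 3), 0.5), np.array([24.0, 10.0, 24.0])
        )
        c = pa.crystal_center_global(bp, pa.CrystalID(3, 0), lut)
        assert np.allclose(c, bp.positions[3])

    def test_global_basis_offset(self):
        bp = pa.BlueprintGeometry(
            np.array([[5.0, 6.0, 7.0], [0, 0, 100.0]]),
            np.array([[1.0, 0, 0]] * 2),
            np.array([[0, 1.0, 0]] * 2),
            np.array([[0, 0, 1.0]] * 2),
        )
        lut = pa.CrystalLUT(np.array([[1.0, 2.0, 3.0]]), np.full((1, 3), 0.1),
                            np.array([8.0, 8.0, 8.0]))
        assert np.allclose(
            pa.crystal_center_global(bp, pa.CrystalID(0, 0), lut), (6.0, 8.0, 10.0)
        )

    def test_matches_dense_matrix_oracle(self, small_scanner, rng):
        bp, lut = small_scanner
        for _ in range(20):
            d = int(rng.integers(0, bp.n_detectors))
            cr = int(rng.integers(0, lut.n_crystals))
            got = pa.crystal_center_global(bp, pa.CrystalID(d, cr), lut)
            basis = np.stack([bp.axes_x[d], bp.axes_y[d], bp.axes_z[d]], axis=1)
            want = bp.positions[d] + basis @ lut.centers[cr]
            assert np.max(np.abs(got - want)) < 1e-9

    def test_out_of_range_raises(self, small_scanner):
        bp, lut = small_scanner
        with pytest.raises(IndexError):
            pa.crystal_center_global(bp, pa.CrystalID(99, 0), lut)


class TestSampleCrystalPoints:
    def test_containment_after_inverse_transform(self, small_scanner, rng):
        bp, lut = small_scanner
        lam = pa.CrystalID(5, 17)
        pts = pa.sample_crystal_points(lam, lut, bp, 500, rng)
        local = (pts - bp.positions[5]) @ bp.basis[5]
        assert np.all(np.abs(local - lut.centers[17]) <= lut.half_extents[17] + 1e-12)

    def test_mean_converges_to_center(self, small_scanner):
        bp, lut = small_scanner
        lam = pa.CrystalID(2, 3)
        pts = pa.sample_crystal_points(lam, lut, bp, 100000, np.random.default_rng(7))
        center = pa.crystal_center_global(bp, lam, lut)
        # standard error of a uniform over +-h: h/sqrt(3 n)
        se = np.max(lut.half_extents[3]) / np.sqrt(3 * 100000)
        assert np.max(np.abs(pts.mean(axis=0) - center)) < 4 * se

    def test_deterministic_under_seed(self, small_scanner):
        bp, lut = small_scanner
        a = pa.sample_crystal_points(pa.CrystalID(0, 0), lut, bp, 10, np.random.default_rng(3))
        b = pa.sample_crystal_points(pa.CrystalID(0, 0), lut, bp, 10, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestCylindricalBlueprint:
    def test_block_count_and_azimuth_spacing(self):
        bp = pa.make_cylindrical_blueprint(8, 3, 75.0)
        assert bp.n_detectors == 24
        az = np.sort(np.arctan2(bp.positions[:8, 1], bp.positions[:8, 0]))
        assert np.allclose(np.diff(az), np.pi / 4, atol=1e-12)

    def test_radial_convention(self):
        bp = pa.make_cylindrical_blueprint(8, 3, 75.0, (48.0, 10.0, 48.0))
        r = np.hypot(bp.positions[:, 0], bp.positions[:, 1])
        assert np.allclose(r, 75.0 + 5.0)

    def test_rotational_symmetry(self):
        bp = pa.make_cylindrical_blueprint(6, 1, 50.0, (20.0, 10.0, 20.0))
        ang = 2 * np.pi / 6
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        rotated = bp.positions @ rot.T
        # the rotated set equals the original set of block centres
        d = np.linalg.norm(rotated[:, None] - bp.positions[None], axis=2)
        assert np.max(np.min(d, axis=1)) < 1e-9


class TestPerturbAlignment:
    def test_zero_sigma_gives_zero(self, rng):
        p = pa.perturb_alignment(10, 0.0, 0.0, rng)
        assert not np.any(p.translations) and not np.any(p.rotations)

    def test_sample_std_matches_sigma(self):
        p = pa.perturb_alignment(4000, 2.0, 1.0, np.random.default_rng(0))
        assert p.translations.std() == pytest.approx(2.0, rel=0.05)
        assert p.rotations.std() == pytest.approx(1.0, rel=0.05)

    def test_seed_determinism(self):
        a = pa.perturb_alignment(5, 1.0, 1.0, np.random.default_rng(9))
        b = pa.perturb_alignment(5, 1.0, 1.0, np.random.default_rng(9))
        assert np.array_equal(a.translations, b.translations)
        assert np.array_equal(a.rotations, b.rotations)


class TestCrystalLUT:
    def test_regular_binning_shapes_and_bounds(self):
        lut = pa.CrystalLUT.regular((48.0, 10.0, 48.0), (24, 5, 24))
        assert lut.n_crystals == 24 * 5 * 24
        assert np.allclose(lut.half_extents, 1.0)
        assert np.all(np.abs(lut.centers) + lut.half_extents <= 24.0 + 1e-12)

    def test_rejects_out_of_block_crystals(self):
        with pytest.raises(pa.InvalidGeometryError):
            pa.CrystalLUT(np.array([[30.0, 0, 0]]), np.full((1, 3), 1.0),
                          np.array([48.0, 10.0, 48.0]))

    def test_rejects_nonpositive_extent(self):
        with pytest.raises(pa.InvalidGeometryError):
            pa.CrystalLUT(np.zeros((1, 3)), np.zeros((1, 3)),
                          np.array([48.0, 10.0, 48.0]))
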