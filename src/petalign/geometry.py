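"""Parametric scanner geometry.

A PET scanner is modelled as ``Ndet`` rigid detector blocks.  The *blueprint*
holds the designed block positions ``P`` (mm) and per-block orthonormal local
axes ``(X, Y, Z)``.  The realized scanner deviates from the blueprint by
unknown per-block translations ``T`` (mm) and rotations ``R`` (degrees, about
the block's own blueprint axes); those deviations are the quantities the
calibration estimates.

Local frame convention (cylindrical scanners):

* ``X`` – planar/tangential axis (transaxial, tangent to the ring),
* ``Y`` – depth-of-interaction (DOI) axis, pointing radially *outward*, so the
  crystal front face looks at the scanner centre,
* ``Z`` – axial axis (parallel to the scanner bore).

Crystal voxels are the discretization cells of a block's interaction space.
A lookup table (:class:`CrystalLUT`) maps the crystal index ``cr`` to the
voxel centre and half-extents in the block-local frame; a crystal is globally
identified by ``lambda = (d, cr)``.

All coordinates are millimetres and all angles degrees at every interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "BlueprintGeometry",
    "AlignmentParams",
    "CrystalLUT",
    "CrystalID",
    "euler_matrix",
    "local_rotation_matrix",
    "apply_alignment",
    "crystal_center_global",
    "sample_crystal_points",
    "make_cylindrical_blueprint",
    "perturb_alignment",
]

_ORTHO_TOL = 1e-9


class InvalidGeometryError(ValueError):
    """Raised when a geometry object violates its invariants."""


class CrystalID(NamedTuple):
    """Global crystal-voxel identifier ``lambda = (d, cr)``."""

    d: int
    cr: int


def _as_f64(a, shape=None, name="array"):
    out = np.asarray(a, dtype=np.float64)
    if shape is not None and out.shape != shape:
        raise InvalidGeometryError(f"{name} has shape {out.shape}, expected {shape}")
    if not np.all(np.isfinite(out)):
        raise InvalidGeometryError(f"{name} contains non-finite entries")
    return out


@dataclass(frozen=True)
class BlueprintGeometry:
    """Designed (or realized) detector positions and local axes.

    Parameters
    ----------
    positions : (Ndet, 3) float array, mm
        Block centres ``P``.
    axes_x, axes_y, axes_z : (Ndet, 3) float arrays
        Unit local axes; ``(X_d, Y_d, Z_d)`` must be orthonormal and
        right-handed for every detector ``d``.
    """

    positions: np.ndarray
    axes_x: np.ndarray
    axes_y: np.ndarray
    axes_z: np.ndarray

    def __post_init__(self):
        pos = _as_f64(self.positions, name="positions")
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise InvalidGeometryError("positions must be (Ndet, 3)")
        n = pos.shape[0]
        ax = _as_f64(self.axes_x, (n, 3), "axes_x")
        ay = _as_f64(self.axes_y, (n, 3), "axes_y")
        az = _as_f64(self.axes_z, (n, 3), "axes_z")
        for v, nm in ((ax, "axes_x"), (ay, "axes_y"), (az, "axes_z")):
            if np.any(np.abs(np.linalg.norm(v, axis=1) - 1.0) > 1e-6):
                raise InvalidGeometryError(f"{nm} rows are not unit vectors")
        basis = np.stack([ax, ay, az], axis=2)  # columns X, Y, Z
        gram = np.einsum("nij,nik->njk", basis, basis)
        if np.max(np.abs(gram - np.eye(3))) > 1e-6:
            raise InvalidGeometryError("local axes are not orthonormal")
        if np.any(np.linalg.det(basis) < 0):
            raise InvalidGeometryError("local frames must be right-handed")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "axes_x", ax)
        object.__setattr__(self, "axes_y", ay)
        object.__setattr__(self, "axes_z", az)

    @property
    def n_detectors(self) -> int:
        return self.positions.shape[0]

    @property
    def basis(self) -> np.ndarray:
        """(Ndet, 3, 3) matrices with columns ``(X_d, Y_d, Z_d)``."""
        return np.stack([self.axes_x, self.axes_y, self.axes_z], axis=2)

    @classmethod
    def from_basis(cls, positions: np.ndarray, basis: np.ndarray) -> "BlueprintGeometry":
        basis = np.asarray(basis, dtype=np.float64)
        return cls(positions, basis[:, :, 0], basis[:, :, 1], basis[:, :, 2])

    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "axes_x": self.axes_x.tolist(),
            "axes_y": self.axes_y.tolist(),
            "axes_z": self.axes_z.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlueprintGeometry":
        return cls(
            np.asarray(d["positions"]),
            np.asarray(d["axes_x"]),
            np.asarray(d["axes_y"]),
            np.asarray(d["axes_z"]),
        )


@dataclass
class AlignmentParams:
    """Per-block rigid deviations from the blueprint.

    ``translations`` are in mm; ``rotations`` are Euler angles in degrees
    about the block's blueprint axes (intrinsic x -> y -> z order, see
    :func:`local_rotation_matrix`).

    ``share_map`` optionally ties detectors together: entry ``d`` is the
    parameter-group index of detector ``d``; all detectors in one group
    resolve to identical ``(T, R)``.  Tying is implemented by storing one
    learnable value per group and expanding on demand.
    """

    translations: np.ndarray
    rotations: np.ndarray
    share_map: np.ndarray | None = None

    def __post_init__(self):
        self.translations = _as_f64(self.translations, name="translations")
        self.rotations = _as_f64(self.rotations, name="rotations")
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise InvalidGeometryError("translations and rotations must both be (N, 3)")
        if self.share_map is not None:
            self.share_map = np.asarray(self.share_map, dtype=np.int64)
            groups = np.unique(self.share_map)
            if not np.array_equal(groups, np.arange(len(groups))):
                raise InvalidGeometryError("share_map groups must be 0..G-1")
            if self.translations.shape[0] not in (len(self.share_map), len(groups)):
                raise InvalidGeometryError("parameter rows must match detectors or groups")

    @classmethod
    def zero(cls, n_detectors: int, share_map=None) -> "AlignmentParams":
        n = n_detectors if share_map is None else int(np.max(share_map)) + 1
        return cls(np.zeros((n, 3)), np.zeros((n, 3)), share_map)

    @property
    def n_groups(self) -> int:
        return self.translations.shape[0]

    def expanded(self) -> "AlignmentParams":
        """Return per-detector parameters (share groups broadcast out)."""
        if self.share_map is None or self.translations.shape[0] == len(self.share_map):
            return AlignmentParams(self.translations.copy(), self.rotations.copy())
        return AlignmentParams(
            self.translations[self.share_map], self.rotations[self.share_map]
        )

    def __neg__(self) -> "AlignmentParams":
        return AlignmentParams(-self.translations, -self.rotations, self.share_map)


@dataclass(frozen=True)
class CrystalLUT:
    """Per-block crystal-voxel lookup table ``L: cr -> R^3`` (local frame).

    ``centers`` are the crystal-voxel centres, ``half_extents`` the voxel
    half-sizes (both mm, block-local frame).  ``block_dims`` is the full
    block bounding box (tangential, DOI depth, axial) centred on the block
    origin; every ``center +/- half_extent`` must stay inside it.
    """

    centers: np.ndarray
    half_extents: np.ndarray
    block_dims: np.ndarray
    shape: tuple = field(default=())

    def __post_init__(self):
        c = _as_f64(self.centers, name="centers")
        h = _as_f64(self.half_extents, name="half_extents")
        bd = _as_f64(self.block_dims, (3,), "block_dims")
        if c.shape != h.shape or c.ndim != 2 or c.shape[1] != 3:
            raise InvalidGeometryError("centers/half_extents must be matching (Ncr, 3)")
        if np.any(h <= 0):
            raise InvalidGeometryError("half_extents must be strictly positive")
        if np.any(np.abs(c) + h > bd / 2.0 + 1e-9):
            raise InvalidGeometryError("crystal voxels exceed the block bounding box")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "half_extents", h)
        object.__setattr__(self, "block_dims", bd)

    @property
    def n_crystals(self) -> int:
        return self.centers.shape[0]

    @classmethod
    def regular(cls, block_dims, shape) -> "CrystalLUT":
        """Regular ``nx x ny x nz`` binning of the block volume.

        ``shape = (nx, ny, nz)`` counts crystal voxels along the tangential,
        DOI and axial block axes; e.g. a ``(48, 10, 48)`` binning of a
        48 x 10 x 48 mm^3 block yields 1 x 1 x 1 mm^3 crystal voxels.
        Crystal indices are C-ordered over (ix, iy, iz).
        """
        block_dims = _as_f64(block_dims, (3,), "block_dims")
        shape = tuple(int(s) for s in shape)
        if any(s < 1 for s in shape):
            raise InvalidGeometryError("shape entries must be >= 1")
        pitch = block_dims / np.asarray(shape, dtype=np.float64)
        axes_idx = [np.arange(s) for s in shape]
        ix, iy, iz = np.meshgrid(*axes_idx, indexing="ij")
        idx = np.stack([ix.ravel(), iy.ravel(), iz.ravel()], axis=1)
        centers = (idx + 0.5) * pitch - block_dims / 2.0
        half = np.broadcast_to(pitch / 2.0, centers.shape).copy()
        return cls(centers, half, block_dims, shape)


def _single_axis_matrix(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


def euler_matrix(angles_deg) -> np.ndarray:
    """Rotation about the *global* basis by intrinsic x -> y -> z angles.

    Returns ``Rz(az) @ Ry(ay) @ Rx(ax)``, i.e. the x rotation is applied
    first.  Angles in degrees.
    """
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    return _single_axis_matrix(2, az) @ _single_axis_matrix(1, ay) @ _single_axis_matrix(0, ax)


def euler_matrix_derivatives(angles_deg) -> np.ndarray:
    """d(euler_matrix)/d(angle_k) for k in {x, y, z}, per *degree*.

    Returns a (3, 3, 3) array ``D[k]``.  Used by the analytic likelihood
    gradient.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    rx, ry, rz = (_single_axis_matrix(k, a[k]) for k in range(3))
    gen = [
        np.array([[0.0, 0, 0], [0, 0, -1], [0, 1, 0]]),
        np.array([[0.0, 0, 1], [0, 0, 0], [-1, 0, 0]]),
        np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 0]]),
    ]
    scale = np.pi / 180.0
    d = np.empty((3, 3, 3))
    d[0] = rz @ ry @ (gen[0] @ rx) * scale
    d[1] = rz @ (gen[1] @ ry) @ rx * scale
    d[2] = (gen[2] @ rz) @ ry @ rx * scale
    return d


def local_rotation_matrix(angles_deg, axes) -> np.ndarray:
    """Rotation by ``angles_deg`` about three orthonormal local axes.

    ``axes`` is a 3x3 matrix whose *columns* are the local X, Y, Z axes.
    The rotation is intrinsic x -> y -> z about those (fixed, blueprint)
    axes, which by conjugation equals ``B @ euler_matrix(angles) @ B.T``.
    Raises :class:`InvalidGeometryError` for non-orthonormal axes.
    """
    b = _as_f64(axes, (3, 3), "axes")
    if np.max(np.abs(b.T @ b - np.eye(3))) > 1e-6:
        raise InvalidGeometryError("axes must be orthonormal")
    return b @ euler_matrix(angles_deg) @ b.T


def apply_alignment(blueprint: BlueprintGeometry, params: AlignmentParams) -> BlueprintGeometry:
    """Apply per-block deviations: ``P_hat = P + T``, axes rotated by ``R``.

    The rotation of block ``d`` is about its own blueprint axes, so the new
    basis is ``B_d @ euler_matrix(R_d)``.
    """
    params = params.expanded()
    n = blueprint.n_detectors
    if params.translations.shape[0] != n:
        raise InvalidGeometryError(
            f"params cover {params.translations.shape[0]} detectors, geometry has {n}"
        )
    basis = blueprint.basis
    new_basis = np.empty_like(basis)
    for d in range(n):
        new_basis[d] = basis[d] @ euler_matrix(params.rotations[d])
    return BlueprintGeometry.from_basis(blueprint.positions + params.translations, new_basis)


def crystal_center_global(
    geometry: BlueprintGeometry, lam: CrystalID, lut: CrystalLUT
) -> np.ndarray:
    """Global position of crystal voxel centre ``lambda = (d, cr)``.

    ``P_d + L(cr)_x X_d + L(cr)_y Y_d + L(cr)_z Z_d``.
    """
    d, cr = int(lam[0]), int(lam[1])
    if not (0 <= d < geometry.n_detectors):
        raise IndexError(f"detector index {d} out of range")
    if not (0 <= cr < lut.n_crystals):
        raise IndexError(f"crystal index {cr} out of range")
    loc = lut.centers[cr]
    return (
        geometry.positions[d]
        + loc[0] * geometry.axes_x[d]
        + loc[1] * geometry.axes_y[d]
        + loc[2] * geometry.axes_z[d]
    )


def sample_crystal_points(
    lam: CrystalID,
    lut: CrystalLUT,
    geometry: BlueprintGeometry,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` points uniformly inside crystal voxel ``lam`` (global frame)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d, cr = int(lam[0]), int(lam[1])
    if not (0 <= d < geometry.n_detectors) or not (0 <= cr < lut.n_crystals):
        raise IndexError("crystal id out of range")
    local = lut.centers[cr] + rng.uniform(-1.0, 1.0, size=(n, 3)) * lut.half_extents[cr]
    return geometry.positions[d] + local @ geometry.basis[d].T


def make_cylindrical_blueprint(
    blocks_per_ring: int,
    rings: int,
    inner_radius: float,
    block_dims=(48.0, 10.0, 48.0),
    ring_pitch: float | None = None,
    phase_deg: float = 0.0,
) -> BlueprintGeometry:
    """Cylindrical scanner blueprint: equally spaced blocks on each ring.

    ``block_dims`` is (tangential, DOI depth, axial) in mm.  Block centres sit
    at transaxial radius ``inner_radius + depth/2`` so the crystal front face
    lies on the inner bore; ``ring_pitch`` defaults to the axial block size.
    The global frame is right-handed with z along the scanner axis and the
    origin at the geometric centre of the arrangement.
    """
    if blocks_per_ring < 1 or rings < 1 or inner_radius <= 0:
        raise InvalidGeometryError("arguments must be positive")
    block_dims = _as_f64(block_dims, (3,), "block_dims")
    if ring_pitch is None:
        ring_pitch = float(block_dims[2])
    r_c = inner_radius + block_dims[1] / 2.0
    pos, bx, by, bz = [], [], [], []
    for ring in range(rings):
        z = (ring - (rings - 1) / 2.0) * ring_pitch
        for b in range(blocks_per_ring):
            phi = np.deg2rad(phase_deg) + 2.0 * np.pi * b / blocks_per_ring
            c, s = np.cos(phi), np.sin(phi)
            pos.append([r_c * c, r_c * s, z])
            by.append([c, s, 0.0])          # DOI axis, radially outward
            bz.append([0.0, 0.0, 1.0])      # axial
            bx.append([s, -c, 0.0])         # tangential, = Y x Z
    return BlueprintGeometry(np.array(pos), np.array(bx), np.array(by), np.array(bz))


def perturb_alignment(
    n_detectors: int,
    sigma_t: float,
    sigma_r: float,
    rng: np.random.Generator,
    share_map=None,
) -> AlignmentParams:
    """I.i.d. zero-mean Gaussian deviations (mm / degrees), seed-reproducible."""
    if sigma_t < 0 or sigma_r < 0:
        raise ValueError("sigmas must be >= 0")
    n = n_detectors if share_map is None else int(np.max(share_map)) + 1
    return AlignmentParams(
        rng.normal(0.0, sigma_t, size=(n, 3)) if sigma_t > 0 else np.zeros((n, 3)),
        rng.normal(0.0, sigma_r, size=(n, 3)) if sigma_r > 0 else np.zeros((n, 3)),
        share_map,
    )
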