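"""Synthetic ground-truth coincidence generator and fan-sum efficiencies.

Replaces a full Monte-Carlo particle transport at desk scale: annihilation
positions are drawn from an analytic phantom (or a voxel grid), the two
back-to-back 511 keV photons are cast as opposite rays, and each side is
assigned the first crystal voxel whose box the ray enters (entry-face
assignment in the block-local frame).  Accepted pairs are thinned with
probability proportional to ``E_l1 * E_l2 * exp(-int A)`` and the TOF bin is
drawn from the true signed midpoint offset blurred by the Gaussian timing
kernel.  Energy deposition, scatter, randoms and positron physics are not
modelled: every accepted event is implicitly inside the energy window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .events import CoincidenceHistogram, EventArray, histogram_events
from .forward_model import EfficiencyTable
from .geometry import BlueprintGeometry, CrystalLUT
from .grid import VoxelGrid
from .tof import TOFModel

__all__ = [
    "PhantomSpec",
    "hotrod_layout",
    "voxelize_phantom",
    "sample_emission_points",
    "simulate_events",
    "fan_sum_efficiencies",
    "FanAcceptance",
    "make_fan_acceptance",
]

HOTROD_DIAMETERS = (2.0, 1.5, 1.2, 1.0, 0.9, 0.8)


@dataclass
class PhantomSpec:
    """Analytic calibration-phantom description.

    Use the classmethod constructors; ``kind`` is one of ``point_sources``
    (spheres with relative activities), ``bspline_tube`` (a thin tube along
    a clamped cubic B-spline through ordered control points),
    ``cylindrical_shell`` and ``hotrod`` (resolution phantom with triangular
    rod sectors).
    """

    kind: str
    centers: np.ndarray | None = None
    radii: np.ndarray | None = None
    activities: np.ndarray | None = None
    control_points: np.ndarray | None = None
    diameter: float = 0.0
    shell_radius: float = 0.0
    thickness: float = 0.0
    length: float = 0.0
    rod_diameters: tuple = HOTROD_DIAMETERS
    phantom_radius: float = 14.0
    _curve: np.ndarray | None = field(default=None, repr=False)
    _rods: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def point_sources(cls, centers, radii, activities=None) -> "PhantomSpec":
        centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
        radii = np.broadcast_to(np.asarray(radii, dtype=np.float64), centers.shape[0]).copy()
        if activities is None:
            activities = np.ones(centers.shape[0])
        activities = np.asarray(activities, dtype=np.float64)
        if np.any(radii <= 0) or np.any(activities < 0) or activities.sum() <= 0:
            raise ValueError("radii must be positive and activities nonnegative")
        return cls("point_sources", centers=centers, radii=radii, activities=activities)

    @classmethod
    def bspline_tube(cls, control_points, diameter: float) -> "PhantomSpec":
        cps = np.atleast_2d(np.asarray(control_points, dtype=np.float64))
        if cps.shape[0] < 2:
            raise ValueError("a tube needs at least 2 control points")
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        return cls("bspline_tube", control_points=cps, diameter=float(diameter))

    @classmethod
    def cylindrical_shell(cls, radius: float, thickness: float, length: float) -> "PhantomSpec":
        if min(radius, thickness, length) <= 0:
            raise ValueError("shell parameters must be positive")
        return cls("cylindrical_shell", shell_radius=radius, thickness=thickness, length=length)

    @classmethod
    def hotrod(
        cls,
        rod_diameters=HOTROD_DIAMETERS,
        phantom_radius: float = 14.0,
        length: float = 10.0,
        shell_thickness: float = 2.0,
    ) -> "PhantomSpec":
        """Resolution phantom: triangular rod sectors plus a uniformly
        filled shell around the rod chambers (the shell is the uniform
        region used for noise metrics); ``shell_thickness=0`` drops it."""
        if min(rod_diameters) <= 0 or phantom_radius <= 0 or length <= 0:
            raise ValueError("hotrod parameters must be positive")
        return cls(
            "hotrod",
            rod_diameters=tuple(rod_diameters),
            phantom_radius=phantom_radius,
            length=length,
            thickness=shell_thickness,
        )

    # ------------------------------------------------------------- helpers
    def curve_points(self, n: int = 4096) -> np.ndarray:
        """Arc-length-uniform points along the tube's B-spline."""
        if self.kind != "bspline_tube":
            raise ValueError("curve_points applies to tube phantoms")
        if self._curve is None or len(self._curve) != n:
            from scipy.interpolate import make_interp_spline

            cps = self.control_points
            u = np.linspace(0.0, 1.0, cps.shape[0])
            k = min(3, cps.shape[0] - 1)
            if k == 3:
                spl = make_interp_spline(
                    u, cps, k=3, bc_type=([(1, np.zeros(3))], [(1, np.zeros(3))])
                )
            else:
                spl = make_interp_spline(u, cps, k=k)
            dense = spl(np.linspace(0.0, 1.0, 8 * n))
            seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
            arc = np.concatenate([[0.0], np.cumsum(seg)])
            targets = np.linspace(0.0, arc[-1], n)
            idx = np.searchsorted(arc, targets).clip(0, len(dense) - 1)
            object.__setattr__(self, "_curve", dense[idx])
        return self._curve

    def rods(self) -> np.ndarray:
        """(n, 3) array of rod (x, y, diameter) for hotrod phantoms."""
        if self.kind != "hotrod":
            raise ValueError("rods applies to hotrod phantoms")
        if self._rods is None:
            object.__setattr__(
                self, "_rods", hotrod_layout(self.rod_diameters, self.phantom_radius)
            )
        return self._rods

    def bounding_box(self) -> np.ndarray:
        """(2, 3) [lower, upper] box containing all activity."""
        if self.kind == "point_sources":
            lo = (self.centers - self.radii[:, None]).min(axis=0)
            hi = (self.centers + self.radii[:, None]).max(axis=0)
        elif self.kind == "bspline_tube":
            pts = self.curve_points()
            lo = pts.min(axis=0) - self.diameter / 2.0
            hi = pts.max(axis=0) + self.diameter / 2.0
        elif self.kind == "cylindrical_shell":
            r = self.shell_radius + self.thickness / 2.0
            lo = np.array([-r, -r, -self.length / 2.0])
            hi = np.array([r, r, self.length / 2.0])
        elif self.kind == "hotrod":
            r = self.phantom_radius + self.thickness
            lo = np.array([-r, -r, -self.length / 2.0])
            hi = np.array([r, r, self.length / 2.0])
        else:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        return np.stack([lo, hi])


def hotrod_layout(diameters=HOTROD_DIAMETERS, phantom_radius: float = 14.0) -> np.ndarray:
    """Triangular-lattice rod positions in six 60-degree sectors.

    Rods of one diameter ``d`` fill one sector on a triangular lattice of
    pitch ``2 d`` (centre-to-centre), starting away from the phantom centre.
    Returns an (n, 3) array of (x, y, diameter).
    """
    out = []
    for s, d in enumerate(diameters):
        ang0 = np.deg2rad(60.0 * s + 30.0)  # sector bisector
        pitch = 2.0 * d
        row_h = pitch * np.sqrt(3.0) / 2.0
        r_start = 2.0 + pitch
        n_rows = int((phantom_radius - r_start) / row_h) + 1
        for i in range(n_rows):
            r = r_start + i * row_h
            n_in_row = i + 1
            for j in range(n_in_row):
                off = (j - (n_in_row - 1) / 2.0) * pitch
                # local sector frame: radial along bisector, lateral across
                x = r * np.cos(ang0) - off * np.sin(ang0)
                y = r * np.sin(ang0) + off * np.cos(ang0)
                rad = np.hypot(x, y)
                ang = np.arctan2(y, x)
                dang = np.angle(np.exp(1j * (ang - ang0)))
                if rad + d / 2.0 > phantom_radius - 0.5:
                    continue
                # keep a rod-width margin to the sector wedge edges (30 deg)
                if rad * np.sin(np.deg2rad(30.0) - abs(dang)) < d:
                    continue
                out.append((x, y, d))
    return np.asarray(out)


def _deposit_points(grid_vals, origin, spacing, pts, masses):
    """Trilinear (centroid-preserving) splat of point masses onto the grid."""
    u = (pts - origin) / spacing - 0.5
    i0 = np.floor(u).astype(np.int64)
    frac = u - i0
    dims = np.asarray(grid_vals.shape)
    for dx in range(2):
        for dy in range(2):
            for dz in range(2):
                idx = i0 + np.array([dx, dy, dz])
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                ok = np.all((idx >= 0) & (idx < dims), axis=1)
                np.add.at(grid_vals, tuple(idx[ok].T), (masses * w)[ok])


def voxelize_phantom(spec: PhantomSpec, spacing: float, padding: float = 1.0) -> VoxelGrid:
    """Rasterize an analytic phantom to a nonnegative activity grid.

    The grid integral (sum times voxel volume) is normalized to the
    phantom's total activity (1 unless point-source activities say
    otherwise).  Point sources far smaller than a voxel land in a single
    voxel; tubes are rasterized by sub-voxel coverage fractions of the
    region within ``diameter/2`` of the spline curve.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    box = spec.bounding_box()
    # snap the origin to the spacing lattice so voxel-centre positions are
    # reproducible regardless of padding
    lo = np.floor((box[0] - padding) / spacing) * spacing
    hi = box[1] + padding
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    vals = np.zeros(tuple(dims))
    sp = np.full(3, float(spacing))
    total_activity = 1.0

    if spec.kind == "point_sources":
        total_activity = float(spec.activities.sum())
        rng = np.random.default_rng(1234)  # fixed: rasterization is deterministic
        for c, r, a in zip(spec.centers, spec.radii, spec.activities):
            if a <= 0:
                continue
            if r < spacing / 2.0:
                _deposit_points(vals, lo, sp, c[None, :], np.array([a]))
            else:
                n = 512
                u = rng.normal(size=(n, 3))
                u /= np.linalg.norm(u, axis=1, keepdims=True)
                pts = c + u * (r * rng.random(n)[:, None] ** (1.0 / 3.0))
                _deposit_points(vals, lo, sp, pts, np.full(n, a / n))
    elif spec.kind == "bspline_tube":
        from scipy.spatial import cKDTree

        curve = spec.curve_points()
        tree = cKDTree(curve)
        r_t = spec.diameter / 2.0
        # candidate voxels within one spacing of the curve
        cand = set()
        reach = int(np.ceil((r_t + spacing) / spacing)) + 1
        cidx = np.floor((curve - lo) / spacing).astype(np.int64)
        offs = np.arange(-reach, reach + 1)
        for di in offs:
            for dj in offs:
                for dk in offs:
                    shifted = cidx + np.array([di, dj, dk])
                    ok = np.all((shifted >= 0) & (shifted < dims), axis=1)
                    cand.update(map(tuple, shifted[ok]))
        cand = np.array(sorted(cand))
        if len(cand) == 0:
            raise ValueError("empty phantom rasterization")
        sub = (np.arange(3) + 0.5) / 3.0
        ox, oy, oz = np.meshgrid(sub, sub, sub, indexing="ij")
        offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
        corners = lo + cand * spacing
        for off in offsets:
            pts = corners + off * spacing
            dist, _ = tree.query(pts, workers=-1)
            frac = (dist <= r_t).astype(np.float64) / len(offsets)
            np.add.at(vals, tuple(cand.T), frac)
    elif spec.kind in ("cylindrical_shell", "hotrod"):
        xs = lo[0] + (np.arange(dims[0]) + 0.5) * spacing
        ys = lo[1] + (np.arange(dims[1]) + 0.5) * spacing
        zs = lo[2] + (np.arange(dims[2]) + 0.5) * spacing
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        if spec.kind == "cylindrical_shell":
            rad = np.hypot(gx, gy)
            in_xy = (rad >= spec.shell_radius - spec.thickness / 2.0) & (
                rad <= spec.shell_radius + spec.thickness / 2.0
            )
        else:
            in_xy = np.zeros_like(gx, dtype=bool)
            for x, y, d in spec.rods():
                in_xy |= (gx - x) ** 2 + (gy - y) ** 2 <= (d / 2.0) ** 2
            if spec.thickness > 0:  # uniformly filled shell around the rods
                rad = np.hypot(gx, gy)
                in_xy |= (rad >= spec.phantom_radius) & (
                    rad <= spec.phantom_radius + spec.thickness
                )
        in_z = np.abs(zs) <= spec.length / 2.0
        vals = in_xy[:, :, None] * in_z[None, None, :] * 1.0
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")

    s = vals.sum()
    if s <= 0:
        raise ValueError("empty phantom rasterization")
    vals *= total_activity / (s * spacing**3)
    return VoxelGrid(lo, sp, vals)


def sample_emission_points(
    source, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw annihilation positions from a PhantomSpec or a VoxelGrid.

    Analytic specs are sampled analytically (uniform in ball / across the
    tube cross-section along arc length / in the shell or rod volumes); a
    VoxelGrid is sampled exactly from its trilinear interpolant.
    """
    if n == 0:
        return np.zeros((0, 3))
    if isinstance(source, VoxelGrid):
        vals = source.values
        if vals.sum() <= 0:
            raise ValueError("zero activity")
        if min(vals.shape) < 2:
            raise ValueError("grid too small to sample")
        cw = (
            vals[:-1, :-1, :-1] + vals[1:, :-1, :-1] + vals[:-1, 1:, :-1]
            + vals[:-1, :-1, 1:] + vals[1:, 1:, :-1] + vals[1:, :-1, 1:]
            + vals[:-1, 1:, 1:] + vals[1:, 1:, 1:]
        ).ravel()
        nz = np.nonzero(cw)[0]
        cdf = np.cumsum(cw[nz])
        cdf /= cdf[-1]
        seed = int(rng.integers(0, 2**31 - 1))
        return _kernels.sample_trilinear_density(
            vals, source.origin, source.spacing, n, cdf, nz.astype(np.int64), seed
        )
    spec: PhantomSpec = source
    if spec.kind == "point_sources":
        acts = spec.activities
        which = rng.choice(len(acts), size=n, p=acts / acts.sum())
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rr = spec.radii[which] * rng.random(n) ** (1.0 / 3.0)
        return spec.centers[which] + u * rr[:, None]
    if spec.kind == "bspline_tube":
        curve = spec.curve_points()
        idx = rng.integers(0, len(curve) - 1, size=n)
        frac = rng.random(n)[:, None]
        base = curve[idx] * (1 - frac) + curve[idx + 1] * frac
        tang = curve[np.minimum(idx + 1, len(curve) - 1)] - curve[np.maximum(idx - 1, 0)]
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        # orthonormal frame across the tube
        helper = np.where(np.abs(tang[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0.0, 1, 0]])
        n1 = np.cross(tang, helper)
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 = np.cross(tang, n1)
        theta = rng.uniform(0, 2 * np.pi, n)
        rad = spec.diameter / 2.0 * np.sqrt(rng.random(n))
        return base + (np.cos(theta) * rad)[:, None] * n1 + (np.sin(theta) * rad)[:, None] * n2
    if spec.kind == "cylindrical_shell":
        r2a = (spec.shell_radius - spec.thickness / 2.0) ** 2
        r2b = (spec.shell_radius + spec.thickness / 2.0) ** 2
        r = np.sqrt(rng.uniform(r2a, r2b, n))
        th = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-spec.length / 2.0, spec.length / 2.0, n)
        return np.stack([r * np.cos(th), r * np.sin(th), z], axis=1)
    if spec.kind == "hotrod":
        rods = spec.rods()
        areas = np.pi * (rods[:, 2] / 2.0) ** 2
        shell_area = np.pi * (
            (spec.phantom_radius + spec.thickness) ** 2 - spec.phantom_radius**2
        ) if spec.thickness > 0 else 0.0
        p = np.concatenate([areas, [shell_area]])
        which = rng.choice(len(p), size=n, p=p / p.sum())
        th = rng.uniform(0, 2 * np.pi, n)
        in_shell = which == len(rods)
        rod_i = np.where(in_shell, 0, which)
        rad = rods[rod_i, 2] / 2.0 * np.sqrt(rng.random(n))
        x = rods[rod_i, 0] + rad * np.cos(th)
        y = rods[rod_i, 1] + rad * np.sin(th)
        if np.any(in_shell):
            m = int(in_shell.sum())
            r2 = np.sqrt(rng.uniform(spec.phantom_radius**2,
                                     (spec.phantom_radius + spec.thickness) ** 2, m))
            x[in_shell] = r2 * np.cos(th[in_shell])
            y[in_shell] = r2 * np.sin(th[in_shell])
        z = rng.uniform(-spec.length / 2.0, spec.length / 2.0, n)
        return np.stack([x, y, z], axis=1)
    raise ValueError(f"unknown phantom kind {spec.kind!r}")


def simulate_events(
    gt_geometry: BlueprintGeometry,
    lut: CrystalLUT,
    source,
    attenuation: VoxelGrid | None,
    efficiencies: EfficiencyTable | None,
    tof: TOFModel,
    n_events: int,
    rng: np.random.Generator,
    max_trials: int | None = None,
    mu_crystal: float = 0.083,
    strict: bool = True,
) -> EventArray:
    """Generate ``n_events`` accepted back-to-back coincidences.

    ``source`` is a PhantomSpec or activity VoxelGrid; ``gt_geometry`` is
    the (misaligned) ground-truth scanner.  Each photon interacts at an
    exponential depth along its chord through the first block hit
    (``mu_crystal`` in 1/mm, default LYSO-like at 511 keV; photons whose
    depth exceeds the chord escape), and the event is assigned the crystal
    voxel containing the interaction point — matching the forward model's
    uniform-in-voxel interaction assumption.  ``mu_crystal=0`` reverts to
    entry-face assignment.  Events are deterministic under a fixed ``rng``
    state.
    """
    if n_events == 0:
        return EventArray.empty()
    if lut.shape == ():
        raise ValueError("simulate_events needs a regular CrystalLUT (with .shape)")
    nd = gt_geometry.n_detectors
    eff = efficiencies.eff if efficiencies is not None else None
    eff_max = float(eff.max()) if eff is not None else 1.0
    half_dims = lut.block_dims / 2.0
    lut_shape = np.asarray(lut.shape, dtype=np.int64)
    positions = gt_geometry.positions
    basis = np.ascontiguousarray(gt_geometry.basis)
    out = [[], [], [], [], []]
    n_acc = 0
    n_try = 0
    limit = max_trials if max_trials is not None else 400 * n_events + 100000
    chunk = max(2 * n_events, 1024)
    while n_acc < n_events:
        if n_try >= limit:
            if strict:
                raise RuntimeError(
                    f"acceptance too low: {n_acc}/{n_events} events after {n_try} trials"
                )
            break
        m = min(chunk, limit - n_try)
        n_try += m
        pts = sample_emission_points(source, m, rng)
        cosz = rng.uniform(-1.0, 1.0, m)
        phi = rng.uniform(0.0, 2.0 * np.pi, m)
        sinz = np.sqrt(1.0 - cosz**2)
        dirs = np.stack([sinz * np.cos(phi), sinz * np.sin(phi), cosz], axis=1)
        det = np.empty((m, 2), dtype=np.int64)
        cr = np.empty((m, 2), dtype=np.int64)
        entry = np.empty((m, 2, 3))
        u_depth = rng.random((m, 2))
        _kernels.trace_events(
            pts, dirs, positions, basis, half_dims, lut_shape,
            mu_crystal, u_depth, det, cr, entry,
        )
        hit = (det[:, 0] >= 0) & (det[:, 1] >= 0) & (det[:, 0] != det[:, 1])
        if not np.any(hit):
            continue
        pts_h = pts[hit]
        det_h = det[hit]
        cr_h = cr[hit]
        q1 = entry[hit, 0]
        q2 = entry[hit, 1]
        # thinning by efficiencies and attenuation survival
        p_keep = np.ones(len(pts_h))
        if eff is not None:
            p_keep *= eff[det_h[:, 0], cr_h[:, 0]] * eff[det_h[:, 1], cr_h[:, 1]] / eff_max**2
        if attenuation is not None:
            mu_len = _kernels.forward_events(
                attenuation.values, attenuation.origin, attenuation.spacing,
                np.ascontiguousarray(q1), np.ascontiguousarray(q2),
                np.zeros(len(q1)), 1.0, 1.0, True, 512,
            )
            p_keep *= np.exp(-mu_len)
        keep = rng.random(len(p_keep)) < p_keep
        if not np.any(keep):
            continue
        pts_h, det_h, cr_h, q1, q2 = (
            a[keep] for a in (pts_h, det_h, cr_h, q1, q2)
        )
        # TOF: true signed midpoint offset toward crystal 1, Gaussian blur
        u = q1 - q2
        seg = np.linalg.norm(u, axis=1)
        mid = 0.5 * (q1 + q2)
        tau = np.einsum("ij,ij->i", pts_h - mid, u) / seg
        if not tof.no_tof:
            tau = tau + rng.normal(0.0, tof.kernel_sigma, len(tau))
            tbin = tof.bin_of(tau)
        else:
            tbin = np.zeros(len(tau), dtype=np.int64)
        ok = tbin >= 0
        take = min(int(np.sum(ok)), n_events - n_acc)
        sel = np.nonzero(ok)[0][:take]
        out[0].append(det_h[sel, 0])
        out[1].append(cr_h[sel, 0])
        out[2].append(det_h[sel, 1])
        out[3].append(cr_h[sel, 1])
        out[4].append(tbin[sel])
        n_acc += take
    return EventArray(*[np.concatenate(c) for c in out])


class FanAcceptance:
    """Symmetric detector-pair acceptance predicate with a dense matrix."""

    def __init__(self, matrix: np.ndarray):
        self.matrix = matrix | matrix.T
        np.fill_diagonal(self.matrix, False)

    def __call__(self, d1: int, d2: int) -> bool:
        return bool(self.matrix[d1, d2])

    def pair_list(self) -> np.ndarray:
        iu = np.triu_indices(self.matrix.shape[0], k=1)
        keep = self.matrix[iu]
        return np.stack([iu[0][keep], iu[1][keep]], axis=1)


def make_fan_acceptance(
    blueprint: BlueprintGeometry,
    n_opposing: int,
    include_axial_neighbors: bool = True,
) -> FanAcceptance:
    """Fan of the ``n_opposing`` most transaxially opposed blocks per ring.

    With axial neighbours included, the same azimuthal fan in the rings
    directly above and below is accepted too (a middle-ring block of a
    three-ring scanner with ``n_opposing=3`` then sees nine partners).
    """
    if n_opposing < 1:
        raise ValueError("n_opposing must be >= 1")
    pos = blueprint.positions
    nd = len(pos)
    z = np.round(pos[:, 2], 6)
    rings = {v: i for i, v in enumerate(np.unique(z))}
    ring_idx = np.array([rings[v] for v in z])
    azim = np.arctan2(pos[:, 1], pos[:, 0])
    mat = np.zeros((nd, nd), dtype=bool)
    for d in range(nd):
        dphi = np.angle(np.exp(1j * (azim - azim[d] - np.pi)))
        order = np.argsort(np.abs(dphi), kind="stable")
        chosen = 0
        for o in order:
            if o == d or ring_idx[o] != ring_idx[d]:
                continue
            if chosen >= n_opposing:
                break
            chosen += 1
            mat[d, o] = True
            if include_axial_neighbors:
                same_az = np.abs(np.angle(np.exp(1j * (azim - azim[o])))) < 1e-9
                near_ring = np.abs(ring_idx - ring_idx[d]) == 1
                mat[d, same_az & near_ring] = True
    return FanAcceptance(mat)


def fan_sum_efficiencies(
    histogram: CoincidenceHistogram, acceptance: FanAcceptance | None = None
) -> EfficiencyTable:
    """Raw fan-sum counts as per-crystal efficiency estimates.

    Each crystal's efficiency is the total number of coincidences it
    recorded with partners inside its acceptance fan; no geometric
    correction is applied (the actual alignment is unknown at this stage).
    """
    if histogram.n_bins == 0:
        raise ValueError("empty histogram")
    nd, ncr = histogram.n_detectors, histogram.n_crystals
    eff = np.zeros((nd, ncr))
    if acceptance is None:
        ok = np.ones(histogram.n_bins, dtype=bool)
    else:
        ok = acceptance.matrix[histogram.d1, histogram.d2]
    cnt = histogram.counts.astype(np.float64)
    np.add.at(eff, (histogram.d1[ok], histogram.cr1[ok]), cnt[ok])
    np.add.at(eff, (histogram.d2[ok], histogram.cr2[ok]), cnt[ok])
    return EfficiencyTable(eff)
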