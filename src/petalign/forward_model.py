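"""Expected-count model for TOF coincidence bins.

The expected rate of a coincidence bin ``(lambda1, lambda2, t)`` given a
known tracer distribution ``F``, attenuation map ``A`` and per-crystal
detection efficiencies ``E`` is

``L = scale * E_l1 * E_l2 * exp(-int A dl) * int K_TOF(x, t) F(x) dl``

where both integrals run along the line between points drawn inside the two
crystal voxels and ``K_TOF`` is the Gaussian TOF kernel.  The rate is
averaged over ``n_samples`` such point pairs.  ``scale`` is a global rate
calibration absorbing acquisition duration and the arbitrary normalization
of fan-sum efficiencies; the likelihood profiles it analytically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _kernels
from .geometry import BlueprintGeometry, CrystalID, CrystalLUT
from .grid import VoxelGrid
from .tof import TOFModel

__all__ = [
    "EfficiencyTable",
    "CoincidenceBin",
    "line_integral",
    "attenuation_factor",
    "tof_weighted_integral",
    "expected_count",
    "default_n_quad",
]


@dataclass
class EfficiencyTable:
    """Per-crystal-voxel detection efficiencies ``E_lambda`` (Ndet x Ncr)."""

    eff: np.ndarray

    def __post_init__(self):
        self.eff = np.ascontiguousarray(self.eff, dtype=np.float64)
        if self.eff.ndim != 2:
            raise ValueError("eff must be (Ndet, Ncr)")
        if np.any(self.eff < 0):
            raise ValueError("efficiencies must be nonnegative")
        if not np.any(self.eff > 0):
            raise ValueError("efficiencies must not be all zero")

    @classmethod
    def uniform(cls, n_detectors: int, n_crystals: int) -> "EfficiencyTable":
        return cls(np.ones((n_detectors, n_crystals)))

    def save_csv(self, path) -> None:
        nd, ncr = self.eff.shape
        d, cr = np.divmod(np.arange(nd * ncr), ncr)
        np.savetxt(
            path,
            np.column_stack([d, cr, self.eff.ravel()]),
            fmt=("%d", "%d", "%.10g"),
            delimiter=",",
            header="d,cr,eff",
        )

    @classmethod
    def load_csv(cls, path) -> "EfficiencyTable":
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
        nd = int(arr[:, 0].max()) + 1
        ncr = int(arr[:, 1].max()) + 1
        eff = np.zeros((nd, ncr))
        eff[arr[:, 0].astype(int), arr[:, 1].astype(int)] = arr[:, 2]
        return cls(eff)


class CoincidenceBin(NamedTuple):
    lam1: CrystalID
    lam2: CrystalID
    t: int


def line_integral(grid: VoxelGrid, p0, p1) -> float:
    """Joseph's-method line integral of the (trilinear) field along p0 -> p1.

    Zero outside the grid support; raises for a degenerate segment.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    if np.linalg.norm(p1 - p0) <= 0.0:
        raise ValueError("degenerate segment: p0 == p1")
    return float(
        _kernels.joseph_line_integral(grid.values, grid.origin, grid.spacing, p0, p1)
    )


def attenuation_factor(attenuation: VoxelGrid, p0, p1) -> float:
    """Beer-Lambert survival factor ``exp(-int A dl)`` in (0, 1]."""
    return float(np.exp(-line_integral(attenuation, p0, p1)))


def default_n_quad(grid: VoxelGrid, nominal_length_mm: float, samples_per_voxel: float = 2.0) -> int:
    """Quadrature subdivisions of a nominal-length chord.

    The count is fixed per problem (not per line), which keeps the
    quadrature smooth under endpoint perturbations; the default resolves the
    grid at ``samples_per_voxel`` midpoints per voxel along the line.
    """
    h = float(np.min(grid.spacing)) / samples_per_voxel
    return max(16, int(np.ceil(nominal_length_mm / h)))


def tof_weighted_integral(
    grid: VoxelGrid,
    p0,
    p1,
    t: int,
    tof: TOFModel,
    n_quad: int | None = None,
) -> float:
    """Gaussian-TOF-weighted tracer line integral for TOF bin ``t``.

    The kernel is centred at the position encoded by bin ``t`` (signed
    offset from the LOR midpoint, positive toward ``p0``'s crystal) with
    FWHM ``tof.kernel_fwhm``, evaluated at the bin centre times the bin
    width (midpoint rule over the bin).
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    seg = np.linalg.norm(p1 - p0)
    if seg <= 0.0:
        raise ValueError("degenerate segment: p0 == p1")
    if n_quad is None:
        n_quad = default_n_quad(grid, seg)
    return float(
        _kernels.tof_weighted_line(
            grid.values,
            grid.origin,
            grid.spacing,
            p0,
            p1,
            tof.bin_center(t),
            tof.kernel_sigma,
            tof.bin_width,
            tof.no_tof,
            n_quad,
        )
    )


def expected_count(
    bin: CoincidenceBin,
    geometry: BlueprintGeometry,
    lut: CrystalLUT,
    activity: VoxelGrid,
    attenuation: VoxelGrid | None,
    efficiencies: EfficiencyTable,
    tof: TOFModel,
    n_samples: int = 5,
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
    n_quad: int | None = None,
) -> float:
    """Expected measurement rate of one coincidence bin (see module docstring).

    ``rng`` drives the in-voxel point sampling; with ``n_samples=1`` and
    vanishing crystal half-extents this reduces to the centre-to-centre
    evaluation.
    """
    lam1, lam2, t = bin
    if lam1.d == lam2.d:
        raise ValueError("coincidence requires two distinct detectors")
    if not 0 <= t < tof.n_bins:
        raise ValueError(f"TOF bin {t} out of range")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    if n_quad is None:
        nominal = 2.0 * float(np.max(np.abs(geometry.positions))) + 1.0
        n_quad = default_n_quad(activity, nominal)
    d1 = np.array([lam1.d], dtype=np.int64)
    cr1 = np.array([lam1.cr], dtype=np.int64)
    d2 = np.array([lam2.d], dtype=np.int64)
    cr2 = np.array([lam2.cr], dtype=np.int64)
    tb = np.array([t], dtype=np.int64)
    jit1 = rng.uniform(-1.0, 1.0, size=(1, n_samples, 3))
    jit2 = rng.uniform(-1.0, 1.0, size=(1, n_samples, 3))
    out_rate = np.zeros(1)
    out_grad = np.zeros((1, 12))
    has_att = attenuation is not None
    a_vals = attenuation.values if has_att else np.zeros((1, 1, 1))
    a_origin = attenuation.origin if has_att else np.zeros(3)
    a_spacing = attenuation.spacing if has_att else np.ones(3)
    _kernels.batch_expected_and_grad(
        d1, cr1, d2, cr2, tb,
        geometry.positions,
        geometry.basis,
        np.zeros((geometry.n_detectors, 3, 3, 3)),
        lut.centers, lut.half_extents,
        efficiencies.eff,
        jit1, jit2,
        activity.values, activity.origin, activity.spacing,
        activity.values, activity.origin, activity.spacing,
        has_att, a_vals, a_origin, a_spacing,
        tof.bin_centers, tof.kernel_sigma, tof.bin_width, tof.no_tof,
        n_quad, n_quad, False, out_rate, out_grad,
    )
    return float(scale * out_rate[0])
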