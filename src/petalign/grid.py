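"""Axis-aligned 3D scalar fields (tracer activity ``F`` and attenuation ``A``).

The grid is half-open: voxel ``(0, 0, 0)`` occupies
``[origin, origin + spacing)`` and its *centre* sits at
``origin + spacing/2``.  Interpolation is trilinear between voxel centres and
the field is zero outside the grid support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass
class VoxelGrid:
    """Nonnegative scalar field on a regular grid.

    Parameters
    ----------
    origin : (3,) mm
        Corner of voxel (0, 0, 0).
    spacing : (3,) mm, all > 0.
    values : (nx, ny, nz) array, >= 0
        Tracer activity per mm^3 (arbitrary units) or attenuation in 1/mm.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("values must be nonnegative")

    @property
    def dims(self) -> tuple:
        return self.values.shape

    @property
    def extent(self) -> np.ndarray:
        """(2, 3) array of [lower_corner, upper_corner] in mm."""
        upper = self.origin + self.spacing * np.asarray(self.values.shape)
        return np.stack([self.origin, upper])

    @property
    def total_mass(self) -> float:
        """Integral of the field: sum(values) * voxel volume."""
        return float(self.values.sum() * np.prod(self.spacing))

    def voxel_centers(self) -> tuple:
        """Per-axis arrays of voxel-centre coordinates."""
        return tuple(
            self.origin[i] + (np.arange(self.values.shape[i]) + 0.5) * self.spacing[i]
            for i in range(3)
        )

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at (n, 3) points; zero outside support."""
        from ._kernels import trilinear_many

        pts = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
        return trilinear_many(self.values, self.origin, self.spacing, pts)

    def cropped(self, pad_voxels: int = 2) -> "VoxelGrid":
        """Tight bounding-box crop around the nonzero support (plus padding)."""
        nz = np.nonzero(self.values)
        if len(nz[0]) == 0:
            return self
        lo, hi = [], []
        for ax in range(3):
            lo.append(max(0, int(nz[ax].min()) - pad_voxels))
            hi.append(min(self.values.shape[ax], int(nz[ax].max()) + 1 + pad_voxels))
        vals = self.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
        origin = self.origin + np.asarray(lo) * self.spacing
        return VoxelGrid(origin, self.spacing.copy(), vals)

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        """Raw float64 + JSON sidecar, or NIfTI when the suffix is .nii/.nii.gz."""
        path = Path(path)
        if path.suffix in (".nii", ".gz"):
            import nibabel as nib

            affine = np.diag([*self.spacing, 1.0])
            affine[:3, 3] = self.origin + self.spacing / 2.0
            nib.save(nib.Nifti1Image(self.values, affine), str(path))
            return
        raw = path.with_suffix(".raw")
        self.values.astype("<f8").tofile(raw)
        meta = {
            "origin": self.origin.tolist(),
            "spacing": self.spacing.tolist(),
            "dims": list(self.values.shape),
            "dtype": "<f8",
            "raw": raw.name,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        path = Path(path)
        if path.suffix in (".nii", ".gz"):
            import nibabel as nib

            img = nib.load(str(path))
            spacing = np.abs(np.diag(img.affine)[:3])
            origin = img.affine[:3, 3] - spacing / 2.0
            return cls(origin, spacing, np.asarray(img.dataobj, dtype=np.float64))
        meta = json.loads(path.with_suffix(".json").read_text())
        vals = np.fromfile(path.parent / meta["raw"], dtype=meta["dtype"]).reshape(meta["dims"])
        return cls(np.asarray(meta["origin"]), np.asarray(meta["spacing"]), vals)
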