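"""Evaluation metrics: Procrustes registration, alignment errors, image scores.

The likelihood is invariant under one common rigid motion of all blocks and
the phantom together, so estimated geometries are compared to a reference
only after a closed-form rigid Procrustes registration (rotation and
translation, no scaling or reflection) fitted on the block positions and
applied to positions and axes.  Alignment errors are then the mean per-axis
absolute position differences (mm) and the mean angles between corresponding
local axis vectors (degrees).

Image metrics (PSNR, SSIM, COV, peak-to-valley ratio) operate on
sum-normalized reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import BlueprintGeometry

__all__ = [
    "RigidTransform",
    "AlignmentErrorReport",
    "procrustes_align",
    "alignment_errors",
    "psnr",
    "ssim",
    "cov_uniform_region",
    "peak_to_valley",
    "PSNR_IDENTICAL",
]

PSNR_IDENTICAL = float("inf")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if np.max(np.abs(r.T @ r - np.eye(3))) > 1e-9 or np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper orthogonal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return vectors @ self.rotation.T

    def apply_geometry(self, geom: BlueprintGeometry) -> BlueprintGeometry:
        return BlueprintGeometry(
            self.apply(geom.positions),
            self.apply_vectors(geom.axes_x),
            self.apply_vectors(geom.axes_y),
            self.apply_vectors(geom.axes_z),
        )


def procrustes_align(estimated: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid registration of ``estimated`` onto ``reference``.

    Kabsch-style SVD solution of ``argmin sum || R p_hat + t - p* ||^2``
    with a reflection guard; no scaling.  Requires >= 3 non-collinear
    points.
    """
    est = np.asarray(estimated, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if est.shape != ref.shape or est.ndim != 2 or est.shape[1] != 3 or est.shape[0] < 3:
        raise ValueError("need matching (N>=3, 3) point sets")
    ce = est.mean(axis=0)
    cr = ref.mean(axis=0)
    a = est - ce
    b = ref - cr
    sv = np.linalg.svd(a.T @ b, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) point configuration")
    rot, _ = Rotation.align_vectors(b, a)  # proper rotation, reflection-safe
    r = rot.as_matrix()
    return RigidTransform(r, cr - r @ ce)


@dataclass(frozen=True)
class AlignmentErrorReport:
    """Mean per-axis translation (mm) and axis-angle rotation (deg) errors."""

    delta_t: np.ndarray
    delta_r: np.ndarray
    residual_positions: np.ndarray
    residual_angles: np.ndarray

    @property
    def mean_translation_um(self) -> float:
        """Mean of the three per-axis translation errors, micrometres."""
        return float(np.mean(self.delta_t) * 1000.0)

    def as_dict(self) -> dict:
        return {
            "delta_T_mm": self.delta_t.tolist(),
            "delta_R_deg": self.delta_r.tolist(),
        }

    def __str__(self) -> str:
        t = ", ".join(f"{v:.4f}" for v in self.delta_t)
        r = ", ".join(f"{v:.3f}" for v in self.delta_r)
        return f"dT (mm): [{t}]   dR (deg): [{r}]"


def alignment_errors(
    estimated: BlueprintGeometry,
    reference: BlueprintGeometry,
    pre_align: bool = True,
) -> AlignmentErrorReport:
    """Per-axis block position and orientation errors after optional Procrustes.

    ``delta_t[i]`` is the mean over detectors of ``|P*_{d,i} - P_hat_{d,i}|``;
    ``delta_r[i]`` the mean angle (deg) between the i-th local axes.
    """
    if estimated.n_detectors != reference.n_detectors:
        raise ValueError("geometries must have the same number of detectors")
    est = estimated
    if pre_align:
        est = procrustes_align(estimated.positions, reference.positions).apply_geometry(
            estimated
        )
    dpos = np.abs(reference.positions - est.positions)
    angles = np.empty((reference.n_detectors, 3))
    for i, (a_ref, a_est) in enumerate(
        ((reference.axes_x, est.axes_x), (reference.axes_y, est.axes_y), (reference.axes_z, est.axes_z))
    ):
        dots = np.einsum("nj,nj->n", a_ref, a_est)
        dots /= np.linalg.norm(a_ref, axis=1) * np.linalg.norm(a_est, axis=1)
        angles[:, i] = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    return AlignmentErrorReport(
        dpos.mean(axis=0), angles.mean(axis=0), dpos, angles
    )


def _sum_normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    s = img.sum()
    return img / s if s > 0 else img


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio ``10 log10(max(I)^2 / MSE)`` in dB.

    Both images are sum-normalized first; identical images return ``inf``.
    """
    ref = _sum_normalize(reference)
    tst = _sum_normalize(test)
    if ref.shape != tst.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return PSNR_IDENTICAL
    return float(10.0 * np.log10(ref.max() ** 2 / mse))


def ssim(reference: np.ndarray, test: np.ndarray) -> float:
    """Global (single-window) structural similarity index.

    Stabilization constants ``C1 = (0.01 L)^2`` and ``C2 = (0.03 L)^2``
    with ``L`` the reference dynamic range, after sum-normalization.
    """
    ref = _sum_normalize(reference)
    tst = _sum_normalize(test)
    if ref.shape != tst.shape:
        raise ValueError("shape mismatch")
    lrange = float(ref.max() - ref.min()) or 1e-12  # degenerate constant image
    c1 = (0.01 * lrange) ** 2
    c2 = (0.03 * lrange) ** 2
    mu1, mu2 = ref.mean(), tst.mean()
    v1, v2 = ref.var(), tst.var()
    cov = float(np.mean((ref - mu1) * (tst - mu2)))
    return float(
        (2 * mu1 * mu2 + c1) * (2 * cov + c2) / ((mu1**2 + mu2**2 + c1) * (v1 + v2 + c2))
    )


def cov_uniform_region(image: np.ndarray, mask: np.ndarray) -> float:
    """Coefficient of variation (percent) of the image inside the mask."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("shape mismatch")
    vals = image[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    mu = vals.mean()
    if mu <= 0:
        raise ValueError("region mean must be positive")
    return float(100.0 * vals.std() / mu)


def peak_to_valley(
    image,
    peak_points_by_diameter: dict,
    valley_points_by_diameter: dict,
) -> dict:
    """Mean rod-centre over inter-rod intensity, per rod diameter.

    ``image`` is a :class:`~petalign.grid.VoxelGrid` (interpolated at the
    given mm coordinates) or a plain array indexed by integer points.
    Returns ``{diameter: PVR}``; an exactly zero valley yields ``inf``.
    """
    out = {}
    for dia, peaks in peak_points_by_diameter.items():
        valleys = valley_points_by_diameter[dia]
        if hasattr(image, "interpolate"):
            pv = float(np.mean(image.interpolate(np.asarray(peaks))))
            vv = float(np.mean(image.interpolate(np.asarray(valleys))))
        else:
            arr = np.asarray(image, dtype=np.float64)
            pv = float(np.mean([arr[tuple(p)] for p in peaks]))
            vv = float(np.mean([arr[tuple(p)] for p in valleys]))
        out[dia] = float("inf") if vv == 0.0 else pv / vv
    return out
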