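"""Time-of-flight (TOF) model.

The arrival-time difference of the two annihilation photons localizes the
emission along the line of response (LOR).  A coincidence timing resolution
(CTR, FWHM in ps) translates into a Gaussian localization kernel along the
LOR with ``FWHM_mm = c * CTR / 2`` (the factor 2 because a time difference
``dt`` moves the position by ``c*dt/2``).  TOF measurements are discretized
into ``n_bins`` bins of width ``bin_width`` mm tiling a symmetric range
around the LOR midpoint.

Sign convention: the TOF coordinate ``tau`` of a point ``x`` on the LOR from
crystal 1 to crystal 2 is its signed distance from the LOR midpoint, positive
*toward crystal 1*.  Swapping the two crystals mirrors ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TOFModel", "SPEED_OF_LIGHT_MM_PER_PS"]

SPEED_OF_LIGHT_MM_PER_PS = 0.299792458

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TOFModel:
    """Gaussian TOF kernel and binning.

    Parameters
    ----------
    ctr_ps : float
        Coincidence timing resolution (FWHM, ps).  500 ps corresponds to a
        kernel FWHM of ~75 mm.
    bin_width : float, mm
        TOF bin width; defaults to ``kernel_fwhm / 3`` (sub-FWHM binning
        loses essentially no information while keeping histograms small).
    n_bins : int
        Number of bins; defaults to the smallest odd count covering
        ``[-range_mm, +range_mm]``.
    range_mm : float
        Half-range of TOF offsets to cover (typically the bore radius).
    no_tof : bool
        When True the kernel is identically 1 on a single wide bin, i.e.
        the likelihood degrades to plain (non-TOF) line integrals.
    """

    ctr_ps: float
    bin_width: float = field(default=0.0)
    n_bins: int = field(default=0)
    range_mm: float = 80.0
    no_tof: bool = False

    def __post_init__(self):
        if self.ctr_ps <= 0:
            raise ValueError("ctr_ps must be positive")
        if self.no_tof:
            object.__setattr__(self, "n_bins", 1)
            object.__setattr__(self, "bin_width", 2.0 * self.range_mm)
            return
        if self.bin_width <= 0:
            object.__setattr__(self, "bin_width", self.kernel_fwhm / 3.0)
        if self.n_bins <= 0:
            n = int(np.ceil(2.0 * self.range_mm / self.bin_width))
            n += 1 - n % 2  # odd, so one bin is centred on the midpoint
            object.__setattr__(self, "n_bins", n)

    @property
    def kernel_fwhm(self) -> float:
        """Gaussian kernel FWHM along the LOR, mm (= c * CTR / 2)."""
        return SPEED_OF_LIGHT_MM_PER_PS * self.ctr_ps / 2.0

    @property
    def kernel_sigma(self) -> float:
        return self.kernel_fwhm * _FWHM_TO_SIGMA

    @property
    def bin_centers(self) -> np.ndarray:
        """(n_bins,) bin centres on the signed TOF axis, mm."""
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.bin_width

    def bin_center(self, t: int) -> float:
        if not 0 <= t < self.n_bins:
            raise IndexError(f"TOF bin {t} out of range [0, {self.n_bins})")
        return (t - (self.n_bins - 1) / 2.0) * self.bin_width

    def mirror_bin(self, t: int) -> int:
        """Bin index after swapping the two crystals (tau -> -tau)."""
        return self.n_bins - 1 - t

    def bin_of(self, tau) -> np.ndarray:
        """Bin indices of signed TOF offsets; -1 when outside the range."""
        tau = np.asarray(tau, dtype=np.float64)
        idx = np.rint(tau / self.bin_width + (self.n_bins - 1) / 2.0).astype(np.int64)
        return np.where((idx >= 0) & (idx < self.n_bins), idx, -1)

    def kernel_weight(self, tau, t: int, exact: bool = False) -> np.ndarray:
        """Kernel mass assigned to bin ``t`` for emission offsets ``tau``.

        Midpoint rule by default (Gaussian density at the bin centre times
        the bin width); ``exact=True`` integrates the Gaussian over the bin
        with erf.  Unit area over the continuous TOF axis.
        """
        tau = np.asarray(tau, dtype=np.float64)
        if self.no_tof:
            return np.ones_like(tau)
        c = self.bin_center(t)
        s = self.kernel_sigma
        if exact:
            from scipy.special import erf

            a = (c - self.bin_width / 2.0 - tau) / (np.sqrt(2.0) * s)
            b = (c + self.bin_width / 2.0 - tau) / (np.sqrt(2.0) * s)
            return 0.5 * (erf(b) - erf(a))
        return self.bin_width * np.exp(-0.5 * ((tau - c) / s) ** 2) / (np.sqrt(2.0 * np.pi) * s)

    def to_dict(self) -> dict:
        return {
            "ctr_ps": self.ctr_ps,
            "bin_width": self.bin_width,
            "n_bins": self.n_bins,
            "range_mm": self.range_mm,
            "no_tof": self.no_tof,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TOFModel":
        return cls(**d)
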