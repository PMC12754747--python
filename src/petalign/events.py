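"""List-mode coincidence events and TOF coincidence histograms.

A coincidence is a pair of crystal voxels ``lambda1 = (d1, cr1)``,
``lambda2 = (d2, cr2)`` plus a TOF bin ``t``.  Events are stored
column-wise (:class:`EventArray`) for scale; the histogram
``C(lambda1, lambda2, t)`` is a sparse multiset count over canonical bins.

Canonical ordering: ``d1 < d2``; swapping the two crystals mirrors the TOF
bin (``t -> n_bins - 1 - t``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .geometry import CrystalID
from .tof import TOFModel

__all__ = ["ListModeEvent", "EventArray", "CoincidenceHistogram", "histogram_events"]


class ListModeEvent(NamedTuple):
    lam1: CrystalID
    lam2: CrystalID
    t: int


@dataclass
class EventArray:
    """Column-wise list-mode event store (a sequence of :class:`ListModeEvent`)."""

    d1: np.ndarray
    cr1: np.ndarray
    d2: np.ndarray
    cr2: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        n = len(self.d1)
        for name in ("d1", "cr1", "d2", "cr2", "t"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (n,):
                raise ValueError("event columns must be 1D and equally long")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.d1)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            return ListModeEvent(
                CrystalID(int(self.d1[i]), int(self.cr1[i])),
                CrystalID(int(self.d2[i]), int(self.cr2[i])),
                int(self.t[i]),
            )
        return EventArray(self.d1[i], self.cr1[i], self.d2[i], self.cr2[i], self.t[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def empty(cls) -> "EventArray":
        z = np.zeros(0, dtype=np.int64)
        return cls(z, z, z, z, z)

    @classmethod
    def from_events(cls, events) -> "EventArray":
        if isinstance(events, EventArray):
            return events
        events = list(events)
        if not events:
            return cls.empty()
        d1 = np.array([e.lam1.d for e in events])
        cr1 = np.array([e.lam1.cr for e in events])
        d2 = np.array([e.lam2.d for e in events])
        cr2 = np.array([e.lam2.cr for e in events])
        t = np.array([e.t for e in events])
        return cls(d1, cr1, d2, cr2, t)

    def canonicalized(self, n_tof_bins: int) -> "EventArray":
        """Events reordered so ``d1 < d2`` (TOF bin mirrored on swap)."""
        swap = self.d1 > self.d2
        d1 = np.where(swap, self.d2, self.d1)
        d2 = np.where(swap, self.d1, self.d2)
        cr1 = np.where(swap, self.cr2, self.cr1)
        cr2 = np.where(swap, self.cr1, self.cr2)
        t = np.where(swap, n_tof_bins - 1 - self.t, self.t)
        return EventArray(d1, cr1, d2, cr2, t)

    def save_csv(self, path) -> None:
        arr = np.stack([self.d1, self.cr1, self.d2, self.cr2, self.t], axis=1)
        np.savetxt(path, arr, fmt="%d", delimiter=",", header="d1,cr1,d2,cr2,tof_bin")

    @classmethod
    def load_csv(cls, path) -> "EventArray":
        arr = np.loadtxt(path, dtype=np.int64, delimiter=",", ndmin=2)
        if arr.size == 0:
            return cls.empty()
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])


def _encode(d1, cr1, d2, cr2, t, n_crystals, n_tof):
    # mixed-radix packing; detector count < 1024 keeps this inside int64
    code = d1.astype(np.int64)
    code = code * n_crystals + cr1
    code = code * 1024 + d2  # detector count < 1024 by construction
    code = code * n_crystals + cr2
    code = code * n_tof + t
    return code


@dataclass
class CoincidenceHistogram:
    """Sparse TOF coincidence histogram ``C(lambda1, lambda2, t)``.

    ``bins`` holds the canonical (d1 < d2) bin coordinates column-wise and
    ``counts`` the positive multiplicities.  ``n_detectors``/``n_crystals``
    describe the crystal index space; ``tof`` records the binning the events
    were histogrammed with.
    """

    d1: np.ndarray
    cr1: np.ndarray
    d2: np.ndarray
    cr2: np.ndarray
    t: np.ndarray
    counts: np.ndarray
    n_detectors: int
    n_crystals: int
    tof: TOFModel

    def __post_init__(self):
        if np.any(self.counts < 1):
            raise ValueError("stored bins must have counts >= 1")
        if np.any(self.d1 >= self.d2):
            raise ValueError("bins must be canonical (d1 < d2)")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def expand(self) -> EventArray:
        """Inverse of histogramming: the multiset of events (canonical order)."""
        rep = np.repeat(np.arange(self.n_bins), self.counts)
        return EventArray(
            self.d1[rep], self.cr1[rep], self.d2[rep], self.cr2[rep], self.t[rep]
        )

    def save_csv(self, path) -> None:
        arr = np.stack([self.d1, self.cr1, self.d2, self.cr2, self.t, self.counts], axis=1)
        header = (
            "d1,cr1,d2,cr2,tof_bin,count\n"
            f"n_detectors={self.n_detectors} n_crystals={self.n_crystals} "
            f"tof={self.tof.to_dict()}"
        )
        np.savetxt(Path(path), arr, fmt="%d", delimiter=",", header=header)


def histogram_events(
    events,
    n_detectors: int,
    n_crystals: int,
    tof: TOFModel,
) -> CoincidenceHistogram:
    """Exact multiset count of events into a sparse histogram (total preserved)."""
    ev = EventArray.from_events(events).canonicalized(tof.n_bins)
    if len(ev) == 0:
        z = np.zeros(0, dtype=np.int64)
        return CoincidenceHistogram(z, z, z, z, z, z, n_detectors, n_crystals, tof)
    codes = _encode(ev.d1, ev.cr1, ev.d2, ev.cr2, ev.t, n_crystals, tof.n_bins)
    uniq, counts = np.unique(codes, return_counts=True)
    t = uniq % tof.n_bins
    rest = uniq // tof.n_bins
    cr2 = rest % n_crystals
    rest //= n_crystals
    d2 = rest % 1024
    rest //= 1024
    cr1 = rest % n_crystals
    d1 = rest // n_crystals
    return CoincidenceHistogram(
        d1, cr1, d2, cr2, t, counts.astype(np.int64), n_detectors, n_crystals, tof
    )
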