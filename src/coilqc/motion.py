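"""Frame-wise displacement and motion scrubbing.

FD of volume i sums the absolute volume-to-volume changes of the six
rigid-body parameters, with rotations converted to arc length on a sphere
of radius 50 mm (the approximate mean distance from cerebral cortex to
the head center):

    FD_i = |dx_i| + |dy_i| + |dz_i| + r * (|da_i| + |db_i| + |dg_i|)

Volumes with FD above 0.2 mm are censored (scrubbed).  FD_0 := 0 since
the first volume has no predecessor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coilqc.io import CensorVector, REASON_MOTION, RealignmentParams


@dataclass
class FDSeries:
    """Frame-wise displacement per volume, mm."""

    fd_mm: np.ndarray
    radius_mm: float = 50.0

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if self.fd_mm.ndim != 1:
            raise ValueError("FD must be a 1D series")
        if np.any(self.fd_mm < 0) or not np.all(np.isfinite(self.fd_mm)):
            raise ValueError("FD values must be finite and nonnegative")
        if not self.radius_mm > 0:
            raise ValueError("radius must be positive")

    @property
    def n_volumes(self) -> int:
        return self.fd_mm.size


def compute_fd(rp: RealignmentParams, radius_mm: float = 50.0) -> FDSeries:
    """Frame-wise displacement of a realignment-parameter series."""
    if rp.n_volumes < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    if not radius_mm > 0:
        raise ValueError("radius must be positive")
    d = np.abs(np.diff(rp.values, axis=0))  # |value(i) - value(i-1)|
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return FDSeries(np.concatenate([[0.0], fd]), radius_mm)


def scrub(fd: FDSeries, fd_threshold: float = 0.2) -> CensorVector:
    """Censor volumes whose FD strictly exceeds the threshold (mm).

    Only the exceeding volume itself is flagged; neighbors are kept.
    """
    if not fd_threshold > 0:
        raise ValueError("fd_threshold must be positive")
    flags = fd.fd_mm > fd_threshold
    reasons = {int(i): REASON_MOTION for i in np.flatnonzero(flags)}
    return CensorVector(flags, reasons)
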