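"""Shared data model and readers/writers for the standard formats.

4D scans and masks are NIfTI-1 (via nibabel); realignment parameters are
6-column whitespace text in either the SPM (``rp_*.txt``: translations then
rotations) or FSL (``*.par``: rotations then translations) column order;
censor vectors are written in three common dialects (FSL outlier matrix,
AFNI 1D, plain 0-based index list).

Conventions: the slice axis is the third spatial axis; volume indices are
0-based internally and 1-based in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class FormatError(ValueError):
    """An input file does not have the expected structure."""


class ConfigError(ValueError):
    """Inconsistent or missing configuration."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Scan4D:
    """A 4D functional time series.

    Parameters
    ----------
    voxels : ndarray, shape (x, y, z, t)
        Intensities in arbitrary scanner units; the third spatial axis is
        the slice axis.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths in mm.
    """

    voxels: np.ndarray
    tr_seconds: float
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise FormatError(
                f"Scan4D requires a 4D array, got {self.voxels.ndim}D"
            )
        if any(d < 1 for d in self.voxels.shape):
            raise FormatError("all Scan4D dimensions must be >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("Scan4D intensities must be finite")
        if not (self.tr_seconds > 0 and np.isfinite(self.tr_seconds)):
            raise ConfigError(f"TR must be positive, got {self.tr_seconds}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    @property
    def n_volumes(self) -> int:
        return self.voxels.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def drop_initial(self, n: int) -> "Scan4D":
        """Return a copy without the first *n* volumes."""
        if not 0 <= n < self.n_volumes:
            raise ConfigError(
                f"cannot discard {n} of {self.n_volumes} volumes"
            )
        return Scan4D(self.voxels[..., n:], self.tr_seconds,
                      self.voxel_size_mm, self.affine)


@dataclass
class BackgroundMask:
    """Boolean 3D mask of outside-brain (background) voxels."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"mask must be 3D, got {self.voxels.ndim}D"
            )

    def check_grid(self, scan: Scan4D) -> None:
        if self.voxels.shape != scan.spatial_shape:
            raise FormatError(
                f"mask shape {self.voxels.shape} does not match scan "
                f"spatial shape {scan.spatial_shape}"
            )


@dataclass
class RealignmentParams:
    """Rigid-body realignment parameters, one row per volume.

    Canonical column order: x, y, z translations (mm) then alpha, beta,
    gamma rotations (radians).
    """

    values: np.ndarray  # (n_volumes, 6)

    COLUMNS = ("x_mm", "y_mm", "z_mm", "alpha_rad", "beta_rad", "gamma_rad")

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 6:
            raise FormatError(
                f"realignment parameters need 6 columns, got "
                f"{self.values.shape[1]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("realignment parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.values[:, 3:]

    def drop_initial(self, n: int) -> "RealignmentParams":
        if not 0 <= n < self.n_volumes:
            raise ConfigError(f"cannot discard {n} of {self.n_volumes} rows")
        return RealignmentParams(self.values[n:])


REASON_NOISE = "noise"
REASON_MOTION = "motion"
REASON_BOTH = "both"


@dataclass
class CensorVector:
    """Per-volume censor flags with the reason for each flagged volume."""

    flags: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise FormatError("censor flags must be a 1D vector")
        for idx, reason in self.reasons.items():
            if not self.flags[idx]:
                raise ValueError(f"reason given for uncensored volume {idx}")
            if reason not in (REASON_NOISE, REASON_MOTION, REASON_BOTH):
                raise ValueError(f"unknown censor reason {reason!r}")

    @property
    def n_volumes(self) -> int:
        return self.flags.size

    @property
    def n_censored(self) -> int:
        return int(self.flags.sum())

    def censored_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    @staticmethod
    def union(noise: "CensorVector | None",
              motion: "CensorVector | None") -> "CensorVector":
        """Merge two censor vectors, recording the per-volume reason."""
        if noise is None and motion is None:
            raise ValueError("at least one censor vector required")
        n = (noise or motion).n_volumes
        nz = noise.flags if noise is not None else np.zeros(n, bool)
        mz = motion.flags if motion is not None else np.zeros(n, bool)
        if nz.size != mz.size:
            raise FormatError("censor vectors differ in length")
        flags = nz | mz
        reasons: dict[int, str] = {}
        for i in np.flatnonzero(flags):
            i = int(i)
            if nz[i] and mz[i]:
                reasons[i] = REASON_BOTH
            elif nz[i]:
                reasons[i] = REASON_NOISE
            else:
                reasons[i] = REASON_MOTION
        return CensorVector(flags, reasons)


# ---------------------------------------------------------------------------
# readers / writers


def read_scan(path: str | Path, tr_override: float | None = None) -> Scan4D:
    """Read a 4D NIfTI-1 image.

    The TR is taken from the header (pixdim[4]); a zero or missing header
    TR requires ``tr_override``, and an explicit override always wins.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) >= 4 else 0.0
    tr = tr_override if tr_override is not None else header_tr
    if not tr or tr <= 0:
        raise ConfigError(
            f"{path}: header TR is {header_tr}; pass an explicit TR"
        )
    voxel_size = tuple(float(z) for z in zooms[:3])
    return Scan4D(data, tr, voxel_size, np.asarray(img.affine))


def read_mask(path: str | Path) -> BackgroundMask:
    """Read a 3D NIfTI-1 mask; any nonzero voxel counts as background."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return BackgroundMask(data != 0)


def read_map(path: str | Path) -> np.ndarray:
    """Read a 3D NIfTI-1 statistical/network map as float array."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D map, got {data.ndim}D")
    return data


def write_scan(scan: Scan4D, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(scan.voxels, dtype=np.float32),
                          scan.affine)
    img.header.set_zooms(tuple(scan.voxel_size_mm) + (scan.tr_seconds,))
    nib.save(img, str(path))


def write_mask(mask: BackgroundMask, path: str | Path,
               affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def write_map(data: np.ndarray, path: str | Path,
              affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


_DIALECTS_RP = ("spm", "fsl")


def read_realignment(path: str | Path, dialect: str = "spm"
                     ) -> RealignmentParams:
    """Read a 6-column motion-parameter file into canonical order.

    ``spm`` files list 3 translations (mm) then 3 rotations (rad);
    ``fsl`` ``.par`` files list 3 rotations (rad) then 3 translations (mm).
    Both are mapped to (x, y, z, alpha, beta, gamma).
    """
    if dialect not in _DIALECTS_RP:
        raise ConfigError(f"unknown realignment dialect {dialect!r}")
    try:
        raw = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse motion file: {exc}")
    if raw.shape[1] != 6:
        raise FormatError(
            f"{path}: expected 6 columns, got {raw.shape[1]}"
        )
    if dialect == "fsl":
        raw = raw[:, [3, 4, 5, 0, 1, 2]]
    return RealignmentParams(raw)


def write_realignment(rp: RealignmentParams, path: str | Path,
                      dialect: str = "spm") -> None:
    if dialect not in _DIALECTS_RP:
        raise ConfigError(f"unknown realignment dialect {dialect!r}")
    vals = rp.values
    if dialect == "fsl":
        vals = vals[:, [3, 4, 5, 0, 1, 2]]
    np.savetxt(str(path), vals, fmt="%.10g")


_DIALECTS_CENSOR = ("fsl_outlier_matrix", "afni_1d", "plain_index")


def write_censor(censor: CensorVector, path: str | Path,
                 dialect: str = "afni_1d") -> None:
    """Write censor flags in one of three text dialects.

    - ``fsl_outlier_matrix``: one indicator column per censored volume
      (empty file when nothing is censored);
    - ``afni_1d``: one row per volume, 1 = keep, 0 = censor;
    - ``plain_index``: 0-based censored indices, one per line.
    """
    if dialect not in _DIALECTS_CENSOR:
        raise ConfigError(f"unknown censor dialect {dialect!r}")
    if censor.n_volumes == 0:
        raise FormatError("cannot write an empty censor vector")
    path = Path(path)
    if dialect == "afni_1d":
        lines = ["0" if f else "1" for f in censor.flags]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "plain_index":
        idx = censor.censored_indices()
        path.write_text("".join(f"{i}\n" for i in idx))
    else:  # fsl_outlier_matrix
        idx = censor.censored_indices()
        if idx.size == 0:
            path.write_text("")
            return
        mat = np.zeros((censor.n_volumes, idx.size), dtype=int)
        mat[idx, np.arange(idx.size)] = 1
        np.savetxt(path, mat, fmt="%d")


def read_censor(path: str | Path, dialect: str = "afni_1d",
                n_volumes: int | None = None) -> CensorVector:
    """Inverse of :func:`write_censor`.

    ``plain_index`` and an all-clean ``fsl_outlier_matrix`` need
    ``n_volumes`` to reconstruct the vector length.
    """
    if dialect not in _DIALECTS_CENSOR:
        raise ConfigError(f"unknown censor dialect {dialect!r}")
    path = Path(path)
    text = path.read_text()
    if dialect == "afni_1d":
        keep = np.array([int(t) for t in text.split()], dtype=int)
        return CensorVector(keep == 0)
    if dialect == "plain_index":
        if n_volumes is None:
            raise ConfigError("plain_index reading requires n_volumes")
        flags = np.zeros(n_volumes, dtype=bool)
        idx = [int(t) for t in text.split()]
        flags[idx] = True
        return CensorVector(flags)
    # fsl_outlier_matrix
    if not text.strip():
        if n_volumes is None:
            raise ConfigError(
                "empty outlier matrix requires n_volumes"
            )
        return CensorVector(np.zeros(n_volumes, dtype=bool))
    mat = np.loadtxt(path, ndmin=2)
    return CensorVector(mat.any(axis=1))
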