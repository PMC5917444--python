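"""Confound regression and band-pass filtering of 4D time series.

The cleaning model follows the standard resting-state recipe: 24
motion-derived regressors (the six realignment parameters, their squares,
their backward temporal differences and the squared differences), mean
signals from caller-supplied WM/CSF/global masks plus their temporal
differences, voxel-wise OLS removal of all confounds, and a zero-phase
0.01-0.1 Hz Butterworth band-pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from coilqc.io import BackgroundMask, RealignmentParams, Scan4D

_MOTION_NAMES = ("trans_x", "trans_y", "trans_z",
                 "rot_alpha", "rot_beta", "rot_gamma")


def build_motion_confounds(rp: RealignmentParams) -> pd.DataFrame:
    """24 motion regressors: params, squares, differences, squared diffs.

    Temporal differences use the backward difference with first row 0
    (no predecessor).
    """
    if rp.n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    base = rp.values
    diff = np.vstack([np.zeros((1, 6)), np.diff(base, axis=0)])
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(_MOTION_NAMES):
        cols[name] = base[:, j]
    for j, name in enumerate(_MOTION_NAMES):
        cols[f"{name}_sq"] = base[:, j] ** 2
    for j, name in enumerate(_MOTION_NAMES):
        cols[f"{name}_diff"] = diff[:, j]
    for j, name in enumerate(_MOTION_NAMES):
        cols[f"{name}_diff_sq"] = diff[:, j] ** 2
    return pd.DataFrame(cols)


def extract_signal(scan: Scan4D, roi_mask: BackgroundMask | np.ndarray
                   ) -> np.ndarray:
    """Mean time series over an ROI mask (e.g. WM, CSF or whole brain)."""
    vox = (roi_mask.voxels if isinstance(roi_mask, BackgroundMask)
           else np.asarray(roi_mask).astype(bool))
    if vox.shape != scan.spatial_shape:
        raise ValueError(
            f"ROI shape {vox.shape} does not match scan {scan.spatial_shape}"
        )
    if not vox.any():
        raise ValueError("ROI mask is empty")
    return scan.voxels[vox].mean(axis=0)


def add_temporal_difference(confounds: pd.DataFrame,
                            name: str,
                            series: np.ndarray) -> pd.DataFrame:
    """Append a signal and its backward temporal difference (row 0 = 0)."""
    series = np.asarray(series, dtype=float)
    out = confounds.copy()
    out[name] = series
    out[f"{name}_diff"] = np.concatenate([[0.0], np.diff(series)])
    return out


def regress_confounds(scan: Scan4D, confounds: pd.DataFrame) -> Scan4D:
    """Voxel-wise OLS removal of the confound columns.

    An intercept is always included, so residuals have (near-)zero mean.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    X = np.column_stack([np.ones(scan.n_volumes),
                         np.asarray(confounds, dtype=float)])
    names = ["intercept"] + list(confounds.columns)
    if X.shape[0] != scan.n_volumes:
        raise ValueError(
            f"confounds have {X.shape[0]} rows for {scan.n_volumes} volumes"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR exposes which columns are linearly dependent
        from scipy.linalg import qr
        _, r, piv = qr(X, mode="economic", pivoting=True)
        dep = sorted(names[j] for j in piv[rank:])
        raise ValueError(
            f"confound matrix is rank deficient; collinear columns: {dep}"
        )
    Y = scan.voxels.reshape(-1, scan.n_volumes).T  # (T, V)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T.reshape(scan.voxels.shape)
    return Scan4D(out, scan.tr_seconds, scan.voxel_size_mm, scan.affine)


def bandpass(scan: Scan4D, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 2) -> Scan4D:
    """Zero-phase Butterworth band-pass along the time axis.

    A second-order Butterworth is applied forward-backward (``filtfilt``)
    after removing the voxel mean, which keeps the filter zero-phase and
    removes DC cleanly.  The upper edge must lie below the Nyquist
    frequency 1/(2*TR).
    """
    nyquist = 1.0 / (2.0 * scan.tr_seconds)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below Nyquist {nyquist:.4g} Hz "
            f"at TR {scan.tr_seconds}s"
        )
    b, a = signal.butter(order, [low_hz / nyquist, high_hz / nyquist],
                         btype="bandpass")
    Y = scan.voxels.reshape(-1, scan.n_volumes)
    mean = Y.mean(axis=1, keepdims=True)
    filtered = signal.filtfilt(b, a, Y - mean, axis=1, padtype="even")
    return Scan4D(filtered.reshape(scan.voxels.shape), scan.tr_seconds,
                  scan.voxel_size_mm, scan.affine)


def bandpass_series(x: np.ndarray, tr_seconds: float,
                    low_hz: float = 0.01, high_hz: float = 0.1,
                    order: int = 2) -> np.ndarray:
    """Band-pass a single 1D series (same filter as :func:`bandpass`)."""
    x = np.asarray(x, dtype=float)
    scan = Scan4D(x[None, None, None, :], tr_seconds)
    return bandpass(scan, low_hz, high_hz, order).voxels[0, 0, 0]
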