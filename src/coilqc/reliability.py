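"""Test-retest reliability metrics for session-wise imaging measures.

Implements ICC(3,1) from the two-way subject x condition ANOVA,
eta-squared spatial similarity between two maps, one-sample t network
masks with Bonferroni family-wise-error control, and within-network
functional connectivity (the mean map value inside a network mask).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def icc_3_1(values: np.ndarray) -> float:
    """Intraclass correlation ICC(3,1) of a subject x condition matrix.

    With BMS the between-subject mean square and EMS the residual
    (condition error) mean square of the two-way ANOVA without
    replication, and k the number of conditions:

        ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS)

    Values near 1 mean between-subject differences dominate the error;
    negative values (EMS > BMS) are returned as computed.  When every
    cell is identical the denominator vanishes and 1 is returned with a
    degenerate-input warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2D subject x condition matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix must be complete and finite")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    if denom == 0:
        warnings.warn("degenerate ICC input (all cells identical); "
                      "returning 1", stacklevel=2)
        return 1.0
    return float((bms - ems) / denom)


def eta_squared(a: np.ndarray, b: np.ndarray,
                mask: np.ndarray | None = None) -> float:
    """Spatial similarity of two maps; 1 = identical, 0 = no similarity.

    With m_i = (a_i + b_i)/2 the voxel-wise mean of the pair and M the
    grand mean of m over the N in-mask voxels:

        eta^2 = 1 - sum_i [(a_i - m_i)^2 + (b_i - m_i)^2]
                    / sum_i [(a_i - M)^2 + (b_i - M)^2]

    Unlike a correlation it is sensitive to differences in scale and
    offset, not just pattern.  Symmetric in (a, b).  Returns NaN when
    both maps are constant and equal to M (denominator zero: similarity
    is undefined, not perfect).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape does not match maps")
        a, b = a[mask], b[mask]
    a, b = a.ravel(), b.ravel()
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("maps must be finite within the mask")
    m = (a + b) / 2.0
    grand = m.mean()
    num = np.sum((a - m) ** 2 + (b - m) ** 2)
    den = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if den == 0:
        warnings.warn("both maps constant: eta-squared undefined",
                      stacklevel=2)
        return float("nan")
    return float(1.0 - num / den)


@dataclass
class NetworkMask:
    """Boolean network-membership mask with generation provenance."""

    voxels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def one_sample_t_mask(maps: np.ndarray | list[np.ndarray],
                      alpha: float = 0.0001,
                      analysis_mask: np.ndarray | None = None,
                      two_sided: bool = False) -> NetworkMask:
    """Network mask from a voxel-wise one-sample t-test across maps.

    A voxel enters the mask when its one-sample t statistic across the
    n maps (mean / (sd/sqrt(n)), df = n-1) is significant at
    ``alpha`` after Bonferroni correction over the voxels of the
    analysis mask (the whole grid by default).  The default test is
    one-sided positive, since network membership is a positive-
    connectivity notion.  Zero-variance voxels are included (with a
    warning) when their mean is positive — the t statistic is infinite —
    and excluded when their mean is zero or negative.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim < 2:
        raise ValueError("need a stack of maps")
    n = maps.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 maps for a t-test, got {n}")
    grid_shape = maps.shape[1:]
    if analysis_mask is None:
        analysis_mask = np.ones(grid_shape, dtype=bool)
    else:
        analysis_mask = np.asarray(analysis_mask).astype(bool)
        if analysis_mask.shape != grid_shape:
            raise ValueError("analysis mask shape does not match maps")
    n_test = int(analysis_mask.sum())
    if n_test == 0:
        raise ValueError("analysis mask is empty")
    cutoff = alpha / n_test  # Bonferroni

    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    include = np.zeros(grid_shape, dtype=bool)

    zero_var = (sd == 0) & analysis_mask
    if np.any(zero_var & (mean > 0)):
        warnings.warn("zero-variance voxels with positive mean included "
                      "in network mask (infinite t)", stacklevel=2)
        include |= zero_var & (mean > 0)

    ok = analysis_mask & (sd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, mean / (sd / np.sqrt(n)), 0.0)
    if two_sided:
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    else:
        p = stats.t.sf(t, df=n - 1)
    include |= ok & (p < cutoff)

    if not include.any():
        warnings.warn("network mask is empty at the requested threshold",
                      stacklevel=2)
    return NetworkMask(include, provenance={
        "n_maps": n,
        "alpha": alpha,
        "correction": "bonferroni",
        "n_voxels_tested": n_test,
        "two_sided": two_sided,
    })


def wnfc(subject_map: np.ndarray, mask: NetworkMask | np.ndarray) -> float:
    """Within-network functional connectivity: mean map value in the mask."""
    vox = mask.voxels if isinstance(mask, NetworkMask) else \
        np.asarray(mask).astype(bool)
    subject_map = np.asarray(subject_map, dtype=float)
    if subject_map.shape != vox.shape:
        raise ValueError(
            f"map shape {subject_map.shape} does not match mask {vox.shape}"
        )
    if not vox.any():
        raise ValueError("network mask is empty")
    return float(subject_map[vox].mean())
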