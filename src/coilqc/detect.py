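"""Slice-wise detection of gradient-coil noise from background intensity.

The detector works on the mean outside-brain background intensity
``I_m(n)`` of every slice m and volume n.  It assumes (1) the clean
background level ``I_bg`` of a slice is nearly constant over the scan,
though it differs between slices, and (2) a slice hit by gradient-coil
noise has a higher mean background ``I_noise > I_bg``.

Per slice the algorithm is:

1. difference successive volumes, ``dI(n) = I(n) - I(n-1)``;
2. collect the jump volumes ``n_p`` where ``dI(n) > thr`` (thr is the
   assumed minimum intensity jump caused by the noise);
3. ``min_noise = min I(n_p)`` approximates the smallest noisy level;
4. ``I_bg = median{ I(n) : I(n) < min_noise }`` — the median keeps
   residual noisy volumes from inflating the background estimate;
5. flag every volume with ``I(n) - I_bg > thr`` as noisy.

A volume is censored when at least one of its slices is flagged.  Two
edge cases the flowchart leaves open are resolved as follows: with no
positive jump above threshold (``n_p`` empty) the background is the
median of the whole series and step 5 still applies, which flags scans
that start noisy and only decay; with no volume below ``min_noise`` the
background is inestimable and the whole slice is conservatively flagged,
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from coilqc.io import CensorVector, REASON_NOISE, BackgroundMask, Scan4D
from coilqc.phantom import NoiseGroundTruth


@dataclass
class SliceIntensityMatrix:
    """Mean background intensity per (slice, volume), scanner units."""

    I: np.ndarray

    def __post_init__(self) -> None:
        self.I = np.atleast_2d(np.asarray(self.I, dtype=float))
        if not np.all(np.isfinite(self.I)):
            raise ValueError("background intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.I.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.I.shape[1]

    def drop_initial(self, n: int) -> "SliceIntensityMatrix":
        return SliceIntensityMatrix(self.I[:, n:])


@dataclass
class DetectionParams:
    """Detector threshold in scanner units (default 3).

    ``thr`` is both the minimum volume-to-volume background jump treated
    as a noise onset and the margin above the background estimate beyond
    which a volume is flagged.
    """

    thr: float = 3.0

    def __post_init__(self) -> None:
        if not self.thr > 0:
            raise ValueError(f"threshold must be positive, got {self.thr}")


@dataclass
class SliceDetectionState:
    """Intermediate quantities of the per-slice detection."""

    delta: np.ndarray            # I(n) - I(n-1), length N-1 (n = 1..N-1)
    jump_volumes: np.ndarray     # n_p, indices into 1..N-1
    min_noise: float | None      # min I(n_p), None when n_p empty
    i_bg: float | None           # background estimate (None if inestimable)
    all_flagged: bool = False    # background inestimable -> whole slice


@dataclass
class DetectionResult:
    noisy: np.ndarray                       # (n_slices, n_volumes) bool
    censor: CensorVector
    per_slice: list[SliceDetectionState]
    params: DetectionParams


def compute_background_intensity(scan: Scan4D, mask: BackgroundMask
                                 ) -> SliceIntensityMatrix:
    """Mean background intensity I_m(n) for every slice m and volume n."""
    mask.check_grid(scan)
    out = np.empty((scan.n_slices, scan.n_volumes))
    for m in range(scan.n_slices):
        sl = mask.voxels[:, :, m]
        if not sl.any():
            raise ValueError(f"slice {m} has no background voxels in mask")
        out[m] = scan.voxels[:, :, m, :][sl].mean(axis=0)
    return SliceIntensityMatrix(out)


def detect_slice(series: np.ndarray, params: DetectionParams
                 ) -> tuple[SliceDetectionState, np.ndarray]:
    """Run the jump/background/flag steps on one slice's intensity series.

    Returns the intermediate state and the per-volume noisy flags.
    """
    I = np.asarray(series, dtype=float).ravel()
    if I.size < 2:
        raise ValueError("series must have at least 2 volumes")
    thr = params.thr
    delta = I[1:] - I[:-1]
    n_p = np.flatnonzero(delta > thr) + 1  # volume index of each jump

    if n_p.size == 0:
        i_bg = float(np.median(I))
        state = SliceDetectionState(delta, n_p, None, i_bg)
        return state, I - i_bg > thr

    min_noise = float(np.min(I[n_p]))
    below = I[I < min_noise]
    if below.size == 0:
        warnings.warn(
            "no volumes below min I_noise: background inestimable, "
            "flagging the entire slice",
            stacklevel=2,
        )
        state = SliceDetectionState(delta, n_p, min_noise, None,
                                    all_flagged=True)
        return state, np.ones_like(I, dtype=bool)

    i_bg = float(np.median(below))
    state = SliceDetectionState(delta, n_p, min_noise, i_bg)
    return state, I - i_bg > thr


def detect(I: SliceIntensityMatrix, params: DetectionParams | float = None
           ) -> DetectionResult:
    """Apply the slice detector independently to every slice.

    A volume is censored when any slice is flagged noisy in it.
    """
    if params is None:
        params = DetectionParams()
    elif not isinstance(params, DetectionParams):
        params = DetectionParams(float(params))
    noisy = np.zeros((I.n_slices, I.n_volumes), dtype=bool)
    states: list[SliceDetectionState] = []
    for m in range(I.n_slices):
        state, flags = detect_slice(I.I[m], params)
        states.append(state)
        noisy[m] = flags
    vol_flags = noisy.any(axis=0)
    reasons = {int(i): REASON_NOISE for i in np.flatnonzero(vol_flags)}
    return DetectionResult(noisy, CensorVector(vol_flags, reasons),
                           states, params)


def default_threshold_grid(start: float = 0.1, stop: float = 10.0,
                           step: float = 0.1) -> np.ndarray:
    """The default sweep grid, 0.1 to 10 in steps of 0.1."""
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


def threshold_sweep(I: SliceIntensityMatrix,
                    thresholds: np.ndarray | list[float] | None = None
                    ) -> "SweepResult":
    """Censored-volume count as a function of the detector threshold."""
    thresholds = (default_threshold_grid() if thresholds is None
                  else np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValueError("thresholds must be nonempty")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    counts = np.empty(thresholds.size, dtype=int)
    noisy_matrices = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # inestimable-background warnings
        for j, thr in enumerate(thresholds):
            res = detect(I, DetectionParams(float(thr)))
            counts[j] = res.censor.n_censored
            noisy_matrices.append(res.noisy)
    return SweepResult(thresholds, counts, noisy_matrices)


@dataclass
class SweepResult:
    thresholds: np.ndarray
    counts: np.ndarray
    noisy_matrices: list[np.ndarray] = field(default_factory=list,
                                             repr=False)


def suggest_threshold(sweep: SweepResult,
                      flat_tolerance: int = 0,
                      run_length: int = 3) -> tuple[float, bool]:
    """Smallest threshold where the sweep curve starts to plateau.

    The curve of censored-volume counts drops sharply while the threshold
    is below the background fluctuation, then plateaus over the range of
    thresholds separating the clean background level from the noisy one;
    the start of that plateau is a good operating threshold.  A plateau is
    ``run_length`` consecutive successive-count changes each within
    ``flat_tolerance``.  Returns ``(threshold, plateau_found)``; when no
    plateau exists the sweep's maximum threshold is returned with a
    warning and ``plateau_found=False``.
    """
    thr = np.asarray(sweep.thresholds, dtype=float)
    counts = np.asarray(sweep.counts)
    if thr.size < 3:
        raise ValueError("need at least 3 thresholds in the sweep")
    diffs = np.abs(np.diff(counts.astype(int)))
    window = min(run_length, diffs.size)
    for i in range(diffs.size - window + 1):
        if np.all(diffs[i:i + window] <= flat_tolerance):
            return float(thr[i]), True
    warnings.warn("no plateau found in threshold sweep; returning the "
                  "maximum swept threshold", stacklevel=2)
    return float(thr[-1]), False


@dataclass
class TruthEvaluation:
    """Slice-level detector performance against injected ground truth."""

    sensitivity: float | None      # None when no noise was injected
    specificity: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float | None


def evaluate_against_truth(result: DetectionResult,
                           truth: NoiseGroundTruth,
                           sweep: SweepResult | None = None
                           ) -> TruthEvaluation:
    """Score detection against ground truth at the slice level.

    Sensitivity/specificity come from ``result``; if a ``sweep`` is given,
    slice-level ROC points (TPR, FPR) per swept threshold and the
    trapezoidal area under the curve are also reported.
    """
    t = truth.noisy
    if result.noisy.shape != t.shape:
        raise ValueError(
            f"shape mismatch: detection {result.noisy.shape} vs "
            f"truth {t.shape}"
        )
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    d = result.noisy
    sens = float((d & t).sum() / n_pos) if n_pos else None
    spec = float((~d & ~t).sum() / n_neg) if n_neg else 1.0

    thresholds = np.array([])
    tpr = np.array([])
    fpr = np.array([])
    auc = None
    if sweep is not None and sweep.noisy_matrices:
        thresholds = np.asarray(sweep.thresholds)
        tpr = np.array([
            (m & t).sum() / n_pos if n_pos else np.nan
            for m in sweep.noisy_matrices
        ])
        fpr = np.array([
            (m & ~t).sum() / n_neg if n_neg else np.nan
            for m in sweep.noisy_matrices
        ])
        if n_pos and n_neg:
            fx = np.concatenate([[0.0], fpr, [1.0]])
            fy = np.concatenate([[0.0], tpr, [1.0]])
            order = np.argsort(fx, kind="stable")
            auc = float(np.trapezoid(fy[order], fx[order]))
    return TruthEvaluation(sens, spec, thresholds, tpr, fpr, auc)
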