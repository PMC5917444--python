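"""End-to-end QC orchestration: detection, scrubbing, merging, exclusion.

``run_qc`` discards the initial volumes, runs noise detection and/or
motion scrubbing per the requested mode, merges the censor vectors with
per-volume reasons, applies the minimum-retained-volumes exclusion rule
(a scan keeping fewer than ``min_volumes`` analyzable volumes — 120 by
default, i.e. 5 minutes at TR 2.5 s — is excluded), and writes censor
files and a machine-readable report.  ``run_evaluation`` scores the
detector against a synthetic ground truth (sweep, ROC, suggested
threshold).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coilqc.detect import (
    DetectionParams,
    compute_background_intensity,
    default_threshold_grid,
    detect,
    evaluate_against_truth,
    suggest_threshold,
    threshold_sweep,
)
from coilqc.io import (
    CensorVector,
    ConfigError,
    read_mask,
    read_realignment,
    read_scan,
    write_censor,
)
from coilqc.motion import compute_fd, scrub
from coilqc.phantom import NoiseGroundTruth

log = logging.getLogger("coilqc")


def _pkg_version() -> str:
    import coilqc
    return coilqc.__version__

MODES = ("none", "noise", "motion", "both")


@dataclass
class RunConfig:
    """Parameters of a QC run.

    ``mode`` selects which censoring is applied: ``noise`` (gradient-coil
    detection), ``motion`` (FD scrubbing), ``both`` (union), or ``none``.
    The noise- and motion-corrected analyses are normally run separately;
    joint censoring often leaves too few volumes, so when using ``both``
    consider lowering ``min_volumes`` (e.g. to 96, 4 minutes at TR 2.5 s).
    """

    scan: str | None = None
    mask: str | None = None
    realignment: str | None = None
    realignment_dialect: str = "spm"
    mode: str = "noise"
    thr: float = 3.0
    fd_threshold: float = 0.2
    radius_mm: float = 50.0
    min_volumes: int = 120
    n_discard_initial: int = 5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    tr_override: float | None = None
    censor_dialect: str = "afni_1d"
    seed: int = 0
    out_dir: str = "qc_out"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode}")
        if self.thr <= 0 or self.fd_threshold <= 0 or self.radius_mm <= 0:
            raise ConfigError("thresholds and radius must be positive")
        if self.min_volumes < 1:
            raise ConfigError("min_volumes must be >= 1")
        if self.n_discard_initial < 0:
            raise ConfigError("n_discard_initial must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ScanReport:
    """Volume accounting and the exclusion decision for one scan."""

    scan_id: str
    mode: str
    n_total: int
    n_discarded_initial: int
    n_noise_censored: int
    n_motion_censored: int
    n_both: int
    n_censored_union: int
    n_remaining: int
    excluded: bool
    exclusion_reason: str
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        d.pop("provenance")
        return pd.DataFrame([d])


def _accounting(censor: CensorVector) -> tuple[int, int, int]:
    """(noise-involved, motion-involved, both) flagged-volume counts."""
    n_noise = sum(1 for r in censor.reasons.values()
                  if r in ("noise", "both"))
    n_motion = sum(1 for r in censor.reasons.values()
                   if r in ("motion", "both"))
    n_both = sum(1 for r in censor.reasons.values() if r == "both")
    return n_noise, n_motion, n_both


def run_qc(config: RunConfig,
           scan=None, mask=None, rp=None,
           write_outputs: bool = True) -> ScanReport:
    """Run the full QC pipeline on one scan.

    Inputs can be passed as in-memory objects or read from the paths in
    ``config``.  Volume counts in the report refer to the series after
    the initial-volume discard; a scan is excluded when fewer than
    ``config.min_volumes`` volumes remain after censoring (strictly
    fewer: a scan retaining exactly the floor is kept).
    """
    scan_id = Path(config.scan).name if config.scan else "in-memory"
    if scan is None:
        if config.scan is None:
            raise ConfigError("no scan given")
        scan = read_scan(config.scan, tr_override=config.tr_override)
    n_total = scan.n_volumes
    scan = scan.drop_initial(config.n_discard_initial)
    n_analyzed = scan.n_volumes
    log.info("%s: %d volumes, %d analyzed after discarding %d",
             scan_id, n_total, n_analyzed, config.n_discard_initial)

    noise_censor = None
    noisy_matrix = None
    if config.mode in ("noise", "both"):
        if mask is None:
            if config.mask is None:
                raise ConfigError("noise mode requires a background mask")
            mask = read_mask(config.mask)
        mask.check_grid(scan)
        I = compute_background_intensity(scan, mask)
        result = detect(I, DetectionParams(config.thr))
        noise_censor = result.censor
        noisy_matrix = result.noisy
        log.info("%s: noise detection flagged %d volumes at thr=%g",
                 scan_id, noise_censor.n_censored, config.thr)

    motion_censor = None
    fd = None
    if config.mode in ("motion", "both"):
        if rp is None:
            if config.realignment is None:
                raise ConfigError("motion mode requires realignment params")
            rp = read_realignment(config.realignment,
                                  config.realignment_dialect)
        rp = rp.drop_initial(config.n_discard_initial)
        if rp.n_volumes != scan.n_volumes:
            raise ConfigError(
                f"realignment rows ({rp.n_volumes}) do not match analyzed "
                f"volumes ({scan.n_volumes})"
            )
        fd = compute_fd(rp, config.radius_mm)
        motion_censor = scrub(fd, config.fd_threshold)
        log.info("%s: scrubbing flagged %d volumes at FD>%g",
                 scan_id, motion_censor.n_censored, config.fd_threshold)

    if noise_censor is None and motion_censor is None:
        censor = CensorVector(np.zeros(n_analyzed, dtype=bool))
    else:
        censor = CensorVector.union(noise_censor, motion_censor)

    n_noise, n_motion, n_both = _accounting(censor)
    n_union = censor.n_censored
    n_remaining = n_analyzed - n_union
    excluded = n_remaining < config.min_volumes
    reason = (f"only {n_remaining} volumes remain after censoring "
              f"(< {config.min_volumes})" if excluded else "")

    report = ScanReport(
        scan_id=scan_id,
        mode=config.mode,
        n_total=n_total,
        n_discarded_initial=config.n_discard_initial,
        n_noise_censored=n_noise,
        n_motion_censored=n_motion,
        n_both=n_both,
        n_censored_union=n_union,
        n_remaining=n_remaining,
        excluded=excluded,
        exclusion_reason=reason,
        provenance={
            "config_hash": config.config_hash(),
            "coilqc_version": _pkg_version(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "thr": config.thr,
            "fd_threshold": config.fd_threshold,
            "min_volumes": config.min_volumes,
        },
    )

    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_censor(censor, out / f"censor_{config.censor_dialect}.txt",
                     config.censor_dialect)
        if noisy_matrix is not None:
            rows = [(m + 1, n + 1, int(noisy_matrix[m, n]))
                    for m in range(noisy_matrix.shape[0])
                    for n in range(noisy_matrix.shape[1])]
            pd.DataFrame(rows, columns=["slice", "volume", "noisy"]).to_csv(
                out / "noisy_slices.tsv", sep="\t", index=False)
        if fd is not None:
            pd.DataFrame({
                "volume": np.arange(1, fd.n_volumes + 1),
                "fd_mm": fd.fd_mm,
            }).to_csv(out / "fd.tsv", sep="\t", index=False,
                      float_format="%.6f")
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
    return report


@dataclass
class EvaluationResult:
    sweep_table: pd.DataFrame
    roc_table: pd.DataFrame
    suggested_threshold: float
    plateau_found: bool
    sensitivity: float | None
    specificity: float
    auc: float | None


def run_evaluation(I, truth: NoiseGroundTruth,
                   thr: float = 3.0,
                   thresholds: np.ndarray | None = None,
                   out_dir: str | Path | None = None) -> EvaluationResult:
    """Score the detector against ground truth on a synthetic scan.

    ``I`` is the slice-intensity matrix of the *analyzed* volumes and
    ``truth`` must already be trimmed to the same volumes.  Produces the
    threshold-sweep table, slice-level ROC points and AUC, the suggested
    (plateau) threshold, and sensitivity/specificity at ``thr``.
    """
    if thresholds is None:
        thresholds = default_threshold_grid()
    sweep = threshold_sweep(I, thresholds)
    result = detect(I, DetectionParams(thr))
    ev = evaluate_against_truth(result, truth, sweep)
    suggested, plateau = suggest_threshold(sweep)

    sweep_table = pd.DataFrame({
        "threshold": sweep.thresholds,
        "n_censored": sweep.counts,
    })
    roc_table = pd.DataFrame({
        "threshold": ev.thresholds,
        "tpr": ev.tpr,
        "fpr": ev.fpr,
    })
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sweep_table.to_csv(out / "sweep.tsv", sep="\t", index=False,
                           float_format="%.6f")
        roc_table.to_csv(out / "roc.tsv", sep="\t", index=False,
                         float_format="%.6f")
        with open(out / "evaluation.json", "w") as fh:
            json.dump({
                "suggested_threshold": suggested,
                "plateau_found": plateau,
                "thr": thr,
                "sensitivity": ev.sensitivity,
                "specificity": ev.specificity,
                "auc": ev.auc,
            }, fh, indent=2)
    return EvaluationResult(sweep_table, roc_table, suggested, plateau,
                            ev.sensitivity, ev.specificity, ev.auc)
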