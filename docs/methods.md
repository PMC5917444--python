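# Methods

## Detection model

The detector consumes only the mean background intensity `I_m(n)` of
each slice `m` and volume `n`, computed over an outside-brain mask. Its
two assumptions: the clean background level of a slice is nearly
constant over the scan (though it differs between slices, so slices are
processed independently, with no pooling or spatial smoothing), and a
slice hit by gradient-coil noise has a strictly higher mean background.
The algorithm finds upward volume-to-volume jumps larger than `thr`,
takes the smallest intensity among the jump targets as a lower bound on
the noisy level, estimates the clean background as the **median** of all
volumes below that bound (the median resists contamination by noisy
volumes that never produced a detectable jump), and flags every volume
more than `thr` above that estimate. Volumes with at least one noisy
slice are censored.

Two branches are underdetermined by that outline and resolved here:

- **No jump above threshold.** The background is taken as the median of
  the whole series and the flagging rule still applies. This preserves
  detection of scans that begin noisy and only decay (the only jumps are
  negative) while leaving genuinely clean slices unflagged, since for
  them no volume sits more than `thr` above the median.
- **No volume below the estimated noisy level.** The background would be
  inestimable, so the entire slice is flagged with a warning. With a
  strictly positive threshold this branch is actually unreachable — the
  volume preceding the jump that attains `min I_noise` is always below
  it — but it is kept as a defensive guard for hand-constructed states.

Comparisons are strict (`>`), in both the jump rule and the flagging
rule, and in raw scanner units; only positive jumps enter the jump set.
Medians of even-length sets are the midpoint of the central pair.

## Thresholds and diagnostics

The default `thr = 3` scanner units is the operating point used for all
downstream censoring; it is always overridable. The sweep diagnostic
counts censored volumes over a grid of thresholds (default 0.1 to 10 in
steps of 0.1). On clean scans the count drops from "all volumes" to zero
as soon as the threshold clears the background jitter; on corrupted
scans it plateaus at the corrupted-volume count over the range
separating the clean and noisy levels. `suggest_threshold` returns the
smallest threshold opening a run of 3 consecutive successive-count
changes within a flatness tolerance of 0 counts (both configurable);
with no such run it returns the largest swept threshold with a warning.
ROC points are computed at slice level (a slice × volume cell is one
decision), with the trapezoidal AUC over the swept thresholds plus the
(0,0) and (1,1) endpoints.

## Censoring, exclusion and accounting

Frame-wise displacement sums absolute parameter differences, rotations
converted to arc length on a 50 mm sphere; `FD_0 := 0` (no predecessor),
so the first volume is never motion-censored. Scrubbing flags only the
volume whose FD strictly exceeds 0.2 mm, with no neighbor augmentation.
Noise and motion censors are merged by union with a per-volume reason
(`noise`, `motion`, `both`). After discarding the first 5 volumes
(scanner equilibration), a scan is excluded when *strictly fewer* than
`min_volumes = 120` volumes remain — 5 minutes at TR 2.5 s; the floor is
counted after the initial discard. Noise- and motion-corrected analyses
are intended to run separately; joint censoring (`mode=both`) is
available and usually warrants lowering the floor (e.g. to 96, 4
minutes). Volume indices are 0-based in code and censor files that
require it, 1-based in human-readable tables.

## Cleaning

Confounds are the 24 motion regressors (6 parameters, squares, backward
differences with first row 0, squared differences) plus optional mean
WM/CSF/global signals with their temporal differences. Removal is
voxel-wise OLS with an always-included intercept; a rank-deficient
design raises an error naming the collinear columns rather than silently
dropping them. The band-pass is an order-2 Butterworth applied
forward-backward (`filtfilt`, zero phase) after removing the voxel mean,
with even padding at the edges; at TR 2.5 s the measured amplitude
response passes 0.05 Hz above 0.9 and attenuates 0.15 Hz below 0.1.
Censoring is applied downstream by dropping flagged volumes, after
regression and filtering.

## Reliability metrics

ICC(3,1) uses the two-way subject × condition ANOVA without replication:
`(BMS − EMS)/(BMS + (k−1)·EMS)`. Adding per-condition or global
constants leaves it unchanged; negative estimates are reported as
computed (truncating to 0 would hide pathology); the all-cells-identical
degenerate case returns 1 with a warning, reading the zero denominator
as the between-subject-dominance limit. η² follows the printed
two-map formula with `m_i` the voxel-wise pair mean and `M̄` its grand
mean; two equal constant maps yield NaN (undefined), not 1. Network
masks come from a voxel-wise one-sample t-test across subject maps,
one-sided positive by default (network membership is a
positive-connectivity notion; two-sided available), thresholded at
p < 0.0001 with **Bonferroni** correction over the analysis-mask voxels.
Random-field-based FWE would need smoothness estimation out of scope
here; Bonferroni is deterministic and conservative, and the correction
is recorded in the mask provenance. Zero-variance voxels with positive
mean are included with a warning (infinite t); WNFC is the plain mean of
a subject map inside the mask.

## Synthetic phantoms

`make_phantom` emulates the target acquisition: 64×64 in-plane, 39
slices, 198 volumes, TR 2.5 s, a centered ellipsoidal brain at intensity
1000 (so display units match typical EPI), background baseline drawn
once per slice near 20, and i.i.d. voxel-wise Gaussian fluctuation.
Injected noise is an additive alternating-row striped pattern applied to
the whole slice (brain and background alike), rescaled so its mean over
that slice's background voxels equals exactly
`noise_amplitude_fraction_of_brain × brain_intensity` — 50 units (5%) by
default, the low end of the artifact's intensity range. Volumes are hit
independently with probability `noise_fraction_volumes` (default 0.2);
within a hit volume, slices are hit with probability
`noise_fraction_slices_within_volume` (default 1.0 = all slices). The
exact injected (slice, volume) set is returned as ground truth. All
generators are deterministic given their seed.

The default per-voxel fluctuation sd of 8 makes the *slice-mean*
background jitter by roughly 0.15–0.2 units (sd/√n_background). That is
the regime where a threshold sweep on a clean scan starts at every
volume flagged near thr = 0.1 and reaches zero well before thr = 2,
matching the qualitative behaviour of clean scanner data. Detection
stress tests instead use the separation regime — per-voxel sd 0.3 with
increment 15 = 5·thr — where exact ground-truth recovery at thr = 3 is
essentially certain at fixture sizes.

What the phantom does **not** model: BOLD signal and physiological
noise, Rician background statistics, k-space reconstruction and the
artifact's true point-spread (the stripe texture is cosmetic — the
detector only sees slice means), slow scanner drift, and spatially
correlated noise. Passing tests therefore demonstrate the algorithmic
contracts (exact recovery under separation, correct accounting,
calibration of the sweep), not performance on real scans where the
clean-background-constancy assumption can be violated. For real data the
binarization of a segmentation-derived outside-brain mask is the user's
choice and is accepted as an input mask.

`make_motion_trace` produces smoothed random-walk drift (translations sd
`baseline_sd` mm; rotations sd `baseline_sd/50` rad so both contribute
comparably to FD on the 50 mm sphere) plus single-volume translation
spikes. `make_session_maps` adds voxel-wise i.i.d. subject effects and
session noise to a smooth template, so every voxel follows the two-way
model with implied ICC(3,1) = σ_b²/(σ_b² + σ_w²), enabling
parameter-recovery tests (mean estimated ICC within ±0.05 of the implied
0.5 over 200 replicates of 50 subjects × 4 sessions).

## Problem sizes and numerics

Unit tests run on 20×20×6×60 phantoms, which exercise the same code
paths as the full geometry; the acceptance-scale checks use the full
64×64×39×198 phantom (one clean, one heavily corrupted). The acceptance
script regenerates the clean full-geometry phantom from the given seed.
OLS uses `numpy.linalg.lstsq`; orthogonality and idempotence hold to
1e-8 on fixture sizes. The ICC cross-check against an independent ANOVA
implementation agrees to 1e-10.
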