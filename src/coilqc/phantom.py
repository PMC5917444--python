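"""Synthetic EPI phantoms with ground-truth gradient-coil noise.

The generator emulates the acquisition the detector targets: a 64x64
in-plane grid, 39 slices, 198 volumes at TR 2.5 s, an ellipsoidal "brain"
at high intensity surrounded by low-intensity background, and whole-slice
striped noise injected into random volumes/slices at a few percent of the
brain intensity.  Every injection is recorded so detector output can be
scored against exact ground truth.

The background model has two components: a per-slice constant baseline
(different slices see different mean background, as real EPI does) and
i.i.d. voxel-wise fluctuation.  The default fluctuation is large enough
that the *slice-mean* background jitters by a few tenths of a unit, which
is what makes a threshold sweep start at "every volume flagged" near zero
threshold and fall to zero well below the default threshold, as observed
on clean scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coilqc.io import BackgroundMask, RealignmentParams, Scan4D


class SpecError(ValueError):
    """Invalid phantom specification."""


@dataclass
class NoiseGroundTruth:
    """Which (slice, volume) cells received injected noise.

    ``noisy`` is a boolean (n_slices, n_volumes) matrix; ``increment`` is
    the mean background-intensity increase of each injection in scanner
    units.
    """

    noisy: np.ndarray
    increment: float

    def __post_init__(self) -> None:
        self.noisy = np.asarray(self.noisy, dtype=bool)
        if self.noisy.ndim != 2:
            raise SpecError("ground truth must be (slice, volume)")

    def drop_initial(self, n: int) -> "NoiseGroundTruth":
        return NoiseGroundTruth(self.noisy[:, n:], self.increment)

    @property
    def noisy_volumes(self) -> np.ndarray:
        """Volumes with at least one injected slice."""
        return self.noisy.any(axis=0)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic EPI scan.

    Defaults mirror the target acquisition (64x64x39, 198 volumes,
    TR 2.5 s) with brain intensity 1000 and noise at 5% of brain
    intensity, i.e. a mean background increment of 50 units.
    """

    n_x: int = 64
    n_y: int = 64
    n_slices: int = 39
    n_volumes: int = 198
    tr_seconds: float = 2.5
    brain_intensity: float = 1000.0
    background_mean: float = 20.0
    background_sd: float = 8.0
    noise_fraction_volumes: float = 0.2
    noise_fraction_slices_within_volume: float = 1.0
    noise_amplitude_fraction_of_brain: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_x", "n_y", "n_slices", "n_volumes"):
            if getattr(self, name) < 1:
                raise SpecError(f"{name} must be >= 1")
        if self.brain_intensity <= 0 or self.background_mean <= 0:
            raise SpecError("intensities must be positive")
        if self.background_sd < 0:
            raise SpecError("background_sd must be nonnegative")
        for name in ("noise_fraction_volumes",
                     "noise_fraction_slices_within_volume",
                     "noise_amplitude_fraction_of_brain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be in [0, 1], got {v}")

    @property
    def increment(self) -> float:
        """Mean background increase per injection, scanner units."""
        return self.noise_amplitude_fraction_of_brain * self.brain_intensity


def _brain_mask(spec: PhantomSpec) -> np.ndarray:
    """Centered ellipsoid occupying ~60% of each axis."""
    x = np.arange(spec.n_x) - (spec.n_x - 1) / 2.0
    y = np.arange(spec.n_y) - (spec.n_y - 1) / 2.0
    z = np.arange(spec.n_slices) - (spec.n_slices - 1) / 2.0
    ax, ay, az = 0.3 * spec.n_x, 0.3 * spec.n_y, 0.45 * spec.n_slices
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    return (xx / ax) ** 2 + (yy / ay) ** 2 + (zz / az) ** 2 <= 1.0


def _stripe_pattern(n_x: int, n_y: int) -> np.ndarray:
    """Alternating-row texture with spatial mean 1.

    Rows alternate between 1.5 and 0.5 (falling back to uniform for a
    single row), so the added noise looks striped while its mean over any
    row-balanced region equals the configured increment after scaling.
    """
    rows = np.where(np.arange(n_y) % 2 == 0, 1.5, 0.5)
    return np.broadcast_to(rows[None, :], (n_x, n_y)).copy()


def make_phantom(spec: PhantomSpec
                 ) -> tuple[Scan4D, BackgroundMask, NoiseGroundTruth]:
    """Generate a 4D phantom, its outside-brain mask and the ground truth.

    The scan is brain ellipsoid + per-slice background baseline + i.i.d.
    fluctuation; selected volumes receive an additive whole-slice striped
    pattern whose mean over the background voxels of that slice equals
    ``spec.increment``.  Output is fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    brain = _brain_mask(spec)
    background = ~brain
    for m in range(spec.n_slices):
        if not background[:, :, m].any():
            raise SpecError(f"slice {m} has no background voxels")

    shape = (spec.n_x, spec.n_y, spec.n_slices, spec.n_volumes)
    # per-slice constant baseline near background_mean (drawn once)
    baselines = spec.background_mean * rng.uniform(0.8, 1.2, spec.n_slices)
    vox = np.empty(shape, dtype=np.float32)
    vox[:] = baselines[None, None, :, None]
    vox[brain, :] = spec.brain_intensity
    if spec.background_sd > 0:
        fluct = rng.standard_normal(shape, dtype=np.float32)
        fluct *= np.float32(spec.background_sd)
        vox += fluct

    # pick noisy volumes, then noisy slices within each
    noisy = np.zeros((spec.n_slices, spec.n_volumes), dtype=bool)
    vol_hit = rng.random(spec.n_volumes) < spec.noise_fraction_volumes
    for n in np.flatnonzero(vol_hit):
        if spec.noise_fraction_slices_within_volume >= 1.0:
            slices = np.arange(spec.n_slices)
        else:
            hit = (rng.random(spec.n_slices)
                   < spec.noise_fraction_slices_within_volume)
            slices = np.flatnonzero(hit)
        noisy[slices, n] = True

    if noisy.any() and spec.increment > 0:
        stripe = _stripe_pattern(spec.n_x, spec.n_y)
        for m in range(spec.n_slices):
            bg = background[:, :, m]
            # rescale so the mean over this slice's background voxels is
            # exactly the configured increment
            pattern = stripe * (spec.increment / stripe[bg].mean())
            cols = np.flatnonzero(noisy[m])
            if cols.size:
                vox[:, :, m, cols] += pattern[:, :, None].astype(np.float32)

    scan = Scan4D(vox, spec.tr_seconds)
    return scan, BackgroundMask(background), NoiseGroundTruth(
        noisy, spec.increment)


def make_motion_trace(n_volumes: int,
                      baseline_sd: float = 0.02,
                      spike_volumes: tuple[int, ...] = (),
                      spike_size_mm: float = 0.3,
                      seed: int = 0) -> RealignmentParams:
    """Smooth low-amplitude realignment drift plus translation spikes.

    Each of the six parameters is a smoothed random walk rescaled to
    standard deviation ``baseline_sd`` mm for translations and
    ``baseline_sd / 50`` rad for rotations (equal FD contributions on
    the 50 mm sphere).  Each spike adds ``spike_size_mm`` to the x
    translation at
    a single volume, so frame-wise displacement jumps at that volume and
    the next.  Spikes at volume 0 are rejected: FD has no predecessor
    there, so a volume-0 spike would be undetectable by construction.
    """
    if n_volumes < 2:
        raise SpecError("need at least 2 volumes")
    for v in spike_volumes:
        if not 1 <= v < n_volumes:
            raise SpecError(f"spike volume {v} outside [1, {n_volumes})")
    rng = np.random.default_rng(seed)
    vals = np.zeros((n_volumes, 6))
    if baseline_sd > 0:
        walk = np.cumsum(rng.normal(size=(n_volumes, 6)), axis=0)
        # edge-padded moving average, rescaled to the requested sd;
        # rotations are scaled by 1/50 rad per mm so their FD
        # contribution on the 50 mm sphere matches the translations'
        kernel = np.ones(9) / 9.0
        for j in range(6):
            padded = np.pad(walk[:, j], 4, mode="edge")
            sm = np.convolve(padded, kernel, mode="valid")
            sm -= sm.mean()
            sd = sm.std()
            if sd > 0:
                sm *= baseline_sd / sd
            if j >= 3:
                sm /= 50.0
            vals[:, j] = sm
    for v in spike_volumes:
        vals[v, 0] += spike_size_mm
    return RealignmentParams(vals)


def make_session_maps(n_subjects: int,
                      n_sessions: int,
                      between_subject_sd: float,
                      within_subject_sd: float,
                      grid_shape: tuple[int, int, int] = (8, 8, 4),
                      seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Multi-session 3D maps under a two-way random-effects model.

    map[s, c] = template + subject_effect[s] + session_noise[s, c], with
    voxel-wise i.i.d. Gaussian subject effects (sd ``between_subject_sd``)
    and session noise (sd ``within_subject_sd``).  Returns
    ``(maps, subject_effects)`` with ``maps`` of shape
    ``(n_subjects, n_sessions) + grid_shape``; at every voxel the
    subject x session values follow the ANOVA model whose implied
    ICC(3,1) is sigma_b^2 / (sigma_b^2 + sigma_w^2).
    """
    if n_subjects < 2 or n_sessions < 2:
        raise SpecError("need >= 2 subjects and >= 2 sessions")
    if between_subject_sd < 0 or within_subject_sd < 0:
        raise SpecError("standard deviations must be nonnegative")
    rng = np.random.default_rng(seed)
    gx = np.linspace(-1, 1, grid_shape[0])[:, None, None]
    gy = np.linspace(-1, 1, grid_shape[1])[None, :, None]
    gz = np.linspace(-1, 1, grid_shape[2])[None, None, :]
    template = np.exp(-(gx ** 2 + gy ** 2 + gz ** 2))  # smooth blob
    subj = rng.normal(0.0, 1.0, (n_subjects,) + grid_shape)
    subj *= between_subject_sd
    noise = rng.normal(0.0, 1.0, (n_subjects, n_sessions) + grid_shape)
    noise *= within_subject_sd
    maps = template[None, None] + subj[:, None] + noise
    return maps, subj


def implied_icc(between_subject_sd: float, within_subject_sd: float) -> float:
    """Model-implied ICC(3,1) for :func:`make_session_maps` data."""
    b2 = between_subject_sd ** 2
    w2 = within_subject_sd ** 2
    if b2 + w2 == 0:
        return 1.0
    return b2 / (b2 + w2)
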