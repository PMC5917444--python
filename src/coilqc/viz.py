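"""Diagnostic plots for noise detection."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_detection(I, noisy: np.ndarray, path: str | Path) -> None:
    """Four-panel detection summary for one scan.

    Rows: whole-image mean background intensity per volume; per-slice
    background intensity traces; number of noisy slices per volume; the
    noisy (slice, volume) matrix.
    """
    fig, axes = plt.subplots(4, 1, figsize=(8, 10), sharex=True)
    vols = np.arange(1, I.n_volumes + 1)
    axes[0].plot(vols, I.I.mean(axis=0), lw=0.8)
    axes[0].set_ylabel("mean background")
    for m in range(I.n_slices):
        axes[1].plot(vols, I.I[m], lw=0.4, alpha=0.5)
    axes[1].set_ylabel("per-slice background")
    axes[2].bar(vols, noisy.sum(axis=0), width=1.0)
    axes[2].set_ylabel("# noisy slices")
    axes[3].imshow(noisy, aspect="auto", interpolation="nearest",
                   cmap="viridis", origin="lower",
                   extent=(0.5, I.n_volumes + 0.5, 0.5, I.n_slices + 0.5))
    axes[3].set_ylabel("slice")
    axes[3].set_xlabel("volume")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sweep(sweep, path: str | Path,
               chosen_thr: float | None = None) -> None:
    """Censored-volume count vs. threshold, with the chosen threshold."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep.thresholds, sweep.counts, marker=".", lw=0.8)
    if chosen_thr is not None:
        ax.axvline(chosen_thr, ls="--", color="tab:blue")
    ax.set_xlabel("threshold (scanner units)")
    ax.set_ylabel("censored volumes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
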