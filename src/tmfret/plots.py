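"""Report figures: Weber plots, phasor plots, distance-distribution spaghetti."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .distributions import DistanceDistribution
from .fdmodel import FDDataset, phasor_coordinates

_CONDITION_COLORS = {"apo": "k", "cAMP": "r", "cGMP": "g", "donor-only": "0.6"}


def _color(condition: str) -> str:
    return _CONDITION_COLORS.get(condition, "b")


def weber_plot(
    datasets: list[FDDataset],
    fits: list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
    path: str | Path | None = None,
):
    """Phase delay (solid) and modulation ratio (dashed) vs frequency.

    ``fits`` holds optional (frequencies, phase, mod) model curves, one per
    dataset.
    """
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax2 = ax.twinx()
    for i, ds in enumerate(datasets):
        c = _color(ds.condition)
        ax.semilogx(ds.frequencies / 1e6, ds.phase_deg, "o", color=c, ms=4,
                    label=ds.condition or None)
        ax2.semilogx(ds.frequencies / 1e6, ds.mod_ratio, "s", mfc="none", color=c, ms=4)
        if fits is not None:
            f, ph, m = fits[i]
            ax.semilogx(f / 1e6, ph, "-", color=c, lw=1)
            ax2.semilogx(f / 1e6, m, "--", color=c, lw=1)
    ax.set_xlabel("modulation frequency (MHz)")
    ax.set_ylabel("phase delay (deg)")
    ax2.set_ylabel("modulation ratio")
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    if seen:
        ax.legend(seen.values(), seen.keys(), fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def phasor_plot(datasets: list[FDDataset], path: str | Path | None = None):
    """Phasor (g, s) points with the universal semicircle."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "-", color="0.8", lw=1)
    for ds in datasets:
        g, s = phasor_coordinates(ds.phase_deg, ds.mod_ratio)
        ax.plot(g, s, "o", ms=3, color=_color(ds.condition), label=ds.condition or None)
    ax.set_xlabel("g (in-phase)")
    ax.set_ylabel("s (out-of-phase)")
    ax.set_aspect("equal")
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    if seen:
        ax.legend(seen.values(), seen.keys(), fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def distribution_plot(
    dists: list[tuple[str, DistanceDistribution]],
    overlays: list[tuple[str, np.ndarray, np.ndarray]] | None = None,
    path: str | Path | None = None,
):
    """Spaghetti plot of fitted distance distributions with optional overlays."""
    fig, ax = plt.subplots(figsize=(6, 4))
    r = np.linspace(10, 60, 600)
    for label, dist in dists:
        ax.plot(r, dist.pdf(r), "-", lw=1, color=_color(label), alpha=0.7, label=label)
    for label, rr, dd in overlays or []:
        ax.plot(rr, dd, "--", lw=1.2, color="0.4", label=label)
    ax.set_xlabel("donor-acceptor distance (Å)")
    ax.set_ylabel("probability density (1/Å)")
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    if seen:
        ax.legend(seen.values(), seen.keys(), fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
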