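"""Minimal rendering of the analysis artifacts (headless matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fluctuations import DFMap
from .geometry import COMCloud, DistanceDistribution

__all__ = ["df_heatmap", "cloud_scatter", "distribution_plot"]


def df_heatmap(dfmap: DFMap, path: str | Path, vmax: float | None = None) -> None:
    """Residue×residue heat map of a distance-fluctuation matrix."""
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(
        dfmap.values,
        origin="lower",
        cmap="viridis",
        vmax=vmax,
        extent=(
            dfmap.residues[0],
            dfmap.residues[-1],
            dfmap.residues[0],
            dfmap.residues[-1],
        ),
    )
    unit = "nm²" if dfmap.statistic == "variance" else "nm"
    fig.colorbar(im, ax=ax, label=f"distance fluctuation ({unit})")
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cloud_scatter(cloud: COMCloud, path: str | Path) -> None:
    """2-D projections of a centre-of-mass cloud, coloured by ligand state."""
    keys = [l.state_key if l is not None else "?" for l in cloud.labels]
    uniq = sorted(set(keys))
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.6), sharey=False)
    pts = (cloud.points - cloud.reference) * 10.0  # Å relative to start
    for key in uniq:
        mask = np.array([k == key for k in keys])
        axes[0].scatter(pts[mask, 0], pts[mask, 1], s=4, alpha=0.5, label=key)
        axes[1].scatter(pts[mask, 0], pts[mask, 2], s=4, alpha=0.5, label=key)
    axes[0].set_xlabel("x (Å)")
    axes[0].set_ylabel("y (Å)")
    axes[1].set_xlabel("x (Å)")
    axes[1].set_ylabel("z (Å)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def distribution_plot(dist: DistanceDistribution, path: str | Path, label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.bar(dist.centers, dist.counts, width=np.diff(dist.edges), align="center")
    ax.axvline(dist.mean, color="k", ls="--", lw=1, label=f"mean {dist.mean:.1f} Å")
    ax.set_xlabel("distance (Å)")
    ax.set_ylabel("count")
    if label:
        ax.set_title(label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
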