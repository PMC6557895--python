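"""Thin plotting layer: distance histograms, convergence curves, PC scatter."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_distance_histograms", "plot_convergence", "plot_pc_scatter"]


def plot_distance_histograms(distance_sets: dict[str, np.ndarray], path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, values in distance_sets.items():
        ax.hist(values, bins=30, density=True, histtype="step", label=label)
    ax.set_xlabel("pseudo-distance")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_convergence(curves: list[np.ndarray], path, labels=None) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, c in enumerate(curves):
        ax.plot(np.arange(len(c)), c, marker="o", ms=3,
                label=None if labels is None else labels[i])
    ax.set_xlabel("generation t")
    ax.set_ylabel("intra-population distance")
    if labels is not None:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pc_scatter(pcs: np.ndarray, groups, path, axes=(-2, -4)) -> None:
    """Scatter of two principal components, colored by group label."""
    fig, ax = plt.subplots(figsize=(5, 5))
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        ax.scatter(pcs[sel, axes[0]], pcs[sel, axes[1]], s=8, label=str(g))
    ax.set_xlabel(f"PC[{axes[0]}]")
    ax.set_ylabel(f"PC[{axes[1]}]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
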