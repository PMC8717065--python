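"""Optional matplotlib figures mirroring the standard views of the results:
ensemble trajectories, combination boxplots, and phase-surface heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_trajectories", "plot_combo_boxes", "plot_phase_surface"]


def plot_trajectories(ensembles: dict, label: str, path=None):
    """Per-day ensemble-mean unsafe rate, one curve per swept value."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for value, ens in ensembles.items():
        mean = ens.day_mean
        ax.plot(np.arange(1, mean.size + 1), mean, label=f"{label}={value:g}")
    ax.set_xlabel("day")
    ax.set_ylabel("unsafe-behavior rate")
    ax.set_ylim(bottom=0)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_combo_boxes(summaries: dict, path=None):
    """Boxplots of replicate steady-state rates for the 3x3 level scenarios."""
    fig, ax = plt.subplots(figsize=(8, 4))
    labels = list(summaries)
    ax.boxplot([summaries[k].rates for k in labels], tick_labels=labels, whis=1.5)
    ax.set_xlabel("conformity level - rule-awareness level")
    ax.set_ylabel("steady-state unsafe rate")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_phase_surface(surface, path=None):
    """Heatmap of mean unsafe rate per (conformity, rule-awareness) cell,
    one panel per checkpoint day."""
    n = len(surface.checkpoints)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), squeeze=False)
    vmax = float(surface.rates.max()) or 1.0
    for t, day in enumerate(surface.checkpoints):
        ax = axes[0][t]
        im = ax.imshow(
            surface.rates[t].T,
            origin="lower",
            aspect="auto",
            vmin=0.0,
            vmax=vmax,
            extent=(
                surface.c_grid.min(), surface.c_grid.max(),
                surface.a_grid.min(), surface.a_grid.max(),
            ),
        )
        ax.set_title(f"t = {day}")
        ax.set_xlabel("conformity")
        if t == 0:
            ax.set_ylabel("rule awareness")
    fig.colorbar(im, ax=[a for row in axes for a in row], label="unsafe rate")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
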