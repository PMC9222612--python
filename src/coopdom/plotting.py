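"""Plot helpers for trajectories and r-sweeps (convenience only).

All quantitative output lives in the CSV/JSON files; plots are a visual
aid and nothing reads numbers back out of them.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = ["plot_trajectories", "plot_sweep"]


def plot_trajectories(
    trajectories: Sequence[Trajectory],
    path=None,
    layer_names: Sequence[str] | None = None,
    title: str | None = None,
):
    """One panel per layer: replicate trajectories (faint) plus their mean."""
    n_layers = trajectories[0].n_layers
    if layer_names is None:
        layer_names = [f"layer {ell}" for ell in range(n_layers)]
    fig, axes = plt.subplots(
        n_layers, 1, figsize=(7, 2.4 * n_layers), sharex=True, squeeze=False
    )
    steps = np.arange(trajectories[0].fractions.shape[1])
    for ell in range(n_layers):
        ax = axes[ell, 0]
        stack = np.stack([t.fractions[ell] for t in trajectories])
        for row in stack:
            ax.plot(steps, row, color="C0", alpha=0.15, lw=0.6)
        ax.plot(steps, stack.mean(axis=0), color="C3", lw=1.5, label="replicate mean")
        ax.set_ylabel("cooperator fraction")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(layer_names[ell], fontsize=9)
        ax.legend(loc="upper right", fontsize=7)
    axes[-1, 0].set_xlabel("time step")
    if title:
        fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_sweep(table: pd.DataFrame, path=None, layer_names: Sequence[str] | None = None):
    """Stationary cooperator fraction vs r, one errorbar line per layer."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for ell, sub in table.groupby("layer"):
        name = layer_names[ell] if layer_names else f"layer {ell}"
        ax.errorbar(
            sub["r"], sub["mean"], yerr=sub["sd"], marker="o", capsize=3, label=name
        )
    ax.set_xlabel("payoff parameter r")
    ax.set_ylabel("stationary cooperator fraction")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
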