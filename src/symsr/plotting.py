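"""Figure helpers for the experiment results (SVG/PNG via matplotlib).

Each function takes result objects produced by :mod:`symsr.experiments`
and writes a figure to ``path``; the format follows the file extension.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_sr_maps",
    "plot_sweep",
    "plot_com_histograms",
    "plot_generalization",
]


def plot_sr_maps(result, path) -> None:
    """Heatmaps of learned ring SR maps per (rule, policy), one panel each."""
    keys = sorted(result.maps)
    fig, axes = plt.subplots(1, len(keys), figsize=(3 * len(keys), 3), squeeze=False)
    for ax, key in zip(axes[0], keys):
        im = ax.imshow(result.maps[key], cmap="viridis")
        ax.set_title("/".join(key), fontsize=9)
        ax.set_xlabel("cell")
        ax.set_ylabel("state")
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_sweep(matrices: dict, alpha_grid, beta_grid, path) -> None:
    """log10 loss-ratio matrices of the (alpha, beta) sweep, one panel per layer."""
    fig, axes = plt.subplots(1, len(matrices), figsize=(4.5 * len(matrices), 3.6), squeeze=False)
    for ax, (layer, mat) in zip(axes[0], matrices.items()):
        finite = np.nan_to_num(mat, nan=0.0, posinf=np.nanmax(mat[np.isfinite(mat)]))
        lim = np.max(np.abs(finite))
        im = ax.imshow(finite, cmap="RdBu_r", vmin=-lim, vmax=lim, origin="lower")
        ax.set_xticks(range(len(beta_grid)), [f"{b:g}" for b in beta_grid])
        ax.set_yticks(range(len(alpha_grid)), [f"{a:g}" for a in alpha_grid])
        ax.set_xlabel("beta")
        ax.set_ylabel("alpha")
        ax.set_title(f"{layer}: log10 loss ratio", fontsize=9)
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_com_histograms(track_result, path, bin_cm: float = 3.0) -> None:
    """Distribution of per-cell COM shifts for both layers plus the relative series."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    shifts = {
        "CA3 (recurrent)": track_result.ca3.shifts["shift"],
        "CA1 (feedforward)": track_result.ca1.shifts["shift"],
    }
    lo = min(s.min() for s in shifts.values())
    hi = max(s.max() for s in shifts.values())
    bins = np.arange(np.floor(lo / bin_cm) * bin_cm, hi + bin_cm, bin_cm)
    for (label, s), color in zip(shifts.items(), ("tab:red", "tab:blue")):
        ax1.hist(s, bins=bins, alpha=0.6, label=label, color=color)
    ax1.axvline(0, color="k", lw=0.8)
    ax1.set_xlabel("COM shift, last five minus first five laps (cm)")
    ax1.set_ylabel("cells")
    ax1.legend(fontsize=8)
    ax1.set_title(f"{track_result.condition} recurrent rule", fontsize=9)
    for res, label, color in (
        (track_result.ca3, "CA3", "tab:red"),
        (track_result.ca1, "CA1", "tab:blue"),
    ):
        series = res.relative.groupby("lap")["relative_com"].median()
        ax2.plot(series.index, series.values, marker="o", ms=3, label=label, color=color)
    ax2.axhline(0, color="k", lw=0.8)
    ax2.set_xlabel("lap")
    ax2.set_ylabel("median COM relative to lap 12 (cm)")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_generalization(df: pd.DataFrame, path) -> None:
    """Per-episode step curves (seed-averaged) with the target switch marked."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    colors = {"classical": "tab:blue", "symmetric": "tab:red"}
    n_train = int(df[df.phase == "train"]["episode"].max()) + 1
    for agent, grp in df.groupby("agent"):
        color = colors.get(agent)
        for phase, offset, ax_metric in (("train", 0, None), ("generalize", n_train, None)):
            sub = grp[grp.phase == phase].groupby("episode")
            ax1.plot(sub["steps"].mean().index + offset, sub["steps"].mean().values,
                     color=color, lw=1, label=agent if phase == "train" else None)
            ax2.plot(sub["entropy"].mean().index + offset, sub["entropy"].mean().values,
                     color=color, lw=1, label=agent if phase == "train" else None)
    for ax, ylabel in ((ax1, "steps per episode"), (ax2, "policy entropy (nats)")):
        ax.axvline(n_train, color="k", ls="--", lw=0.8)
        ax.set_xlabel("episode")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
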