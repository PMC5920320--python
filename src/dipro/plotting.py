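"""Figures: positional variance diagrams, trajectory fan plots, and
cumulative-abnormality sigmoids."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_positional_variance", "plot_trajectory_fan",
           "plot_cumulative_curves"]


def plot_positional_variance(posterior, path=None, title="Positional variance"):
    """Greyscale matrix with events ordered by the ML sequence top to
    bottom: intensity of cell (event, position) is the posterior (or
    bootstrap) confidence that the event occupies that position."""
    pv = posterior.positional_variance
    names = posterior.biomarkers
    order = [names.index(n) for n in posterior.ml_sequence]
    mat = pv[order]
    fig, ax = plt.subplots(figsize=(6, 0.35 * len(names) + 1.5))
    ax.imshow(mat, cmap="Greys", aspect="auto", vmin=0, vmax=1)
    ax.set_yticks(range(len(names)))
    ax.set_yticklabels(posterior.ml_sequence, fontsize=7)
    ax.set_xlabel("sequence position")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_trajectory_fan(traj, path=None, title="", max_samples=60):
    """Sampled time-courses (grey), the mean trajectory (dashed black),
    anchor levels as horizontal lines (green normal, red abnormal), and
    the transition-time density sketched along the time axis."""
    fig, ax = plt.subplots(figsize=(6, 4))
    v = traj.values
    for ts in traj.sample_times[:max_samples]:
        okm = np.isfinite(ts)
        ax.plot(ts[okm], v[okm], color="0.7", lw=0.6, zorder=1)
    okm = np.isfinite(traj.mean_times)
    ax.plot(traj.mean_times[okm], v[okm], "k--", lw=2, zorder=3)
    ax.axhline(traj.anchors.canonical_normal, color="green", lw=1.2)
    ax.axhline(traj.anchors.canonical_abnormal, color="red", lw=1.2)
    if len(traj.transition_times):
        tt = -traj.transition_times
        ax2 = ax.twinx()
        ax2.hist(tt, bins=30, density=True, alpha=0.3, color="tab:blue")
        ax2.set_ylabel("transition-time density")
    ax.set_xlabel("years from canonical abnormality (t = 0)")
    ax.set_ylabel("biomarker value")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_cumulative_curves(curves: dict, path=None,
                           title="Cumulative probability of abnormality"):
    """One sigmoid per biomarker on a shared pre-abnormality time axis,
    legend ordered by the time each reaches probability one half."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ordered = sorted(curves.items(), key=lambda kv: kv[1][2])
    cmap = plt.get_cmap("viridis")
    for i, (name, (t, C, t50)) in enumerate(ordered):
        color = cmap(i / max(len(ordered) - 1, 1))
        ls = "-" if i % 2 == 0 else "--"
        ax.plot(t, C, ls, color=color, label=f"{name} (t50={t50:.1f}y)")
    ax.axhline(0.5, color="0.6", ls=":", lw=1)
    ax.set_xlabel("years prior to canonical abnormality")
    ax.set_ylabel("cumulative probability of abnormality")
    ax.set_title(title)
    ax.legend(fontsize=6, loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
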