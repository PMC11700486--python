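"""Figures: variation curves and condition-mean comparisons."""

from __future__ import annotations

import numpy as np

from .constants import CHANNELS, JOINTS, N_CYCLE_POINTS, PLANES, channel_index
from .datasets import StudyDataset

__all__ = ["plot_variation_curves", "plot_condition_means"]

_LEVEL_STYLE = {
    "inter_trial": dict(color="tab:blue"),
    "inter_session": dict(color="tab:orange"),
    "inter_session_clothing": dict(color="tab:red"),
}
_COND_LINESTYLE = {0: "-", 1: "--"}


def _grid():
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        len(JOINTS), len(PLANES), figsize=(11, 12), sharex=True
    )
    for j, joint in enumerate(JOINTS):
        for p, plane in enumerate(PLANES):
            ax = axes[j, p]
            if j == 0:
                ax.set_title(plane)
            if p == 0:
                ax.set_ylabel(f"{joint}\n(deg)")
            if j == len(JOINTS) - 1:
                ax.set_xlabel("gait cycle (%)")
    return fig, axes


def plot_variation_curves(results) -> "matplotlib.figure.Figure":
    """4x3 grid of variation SD curves for every level and condition."""
    fig, axes = _grid()
    x = np.arange(N_CYCLE_POINTS)
    conds = list(results.model.conditions)
    for cs in results.curve_sets():
        style = dict(_LEVEL_STYLE[cs.level])
        ls = _COND_LINESTYLE.get(conds.index(cs.condition) if cs.condition else 0, "-")
        label = cs.level + (f" ({cs.condition})" if cs.condition else "")
        for joint in JOINTS:
            for plane in PLANES:
                ax = axes[JOINTS.index(joint), PLANES.index(plane)]
                ax.plot(
                    x, cs.values[channel_index(joint, plane)],
                    linestyle=ls, linewidth=1.2, label=label, **style,
                )
    axes[0, 0].legend(fontsize=7, loc="upper left")
    fig.suptitle("Variation across the gait cycle")
    fig.tight_layout()
    return fig


def plot_condition_means(
    dataset: StudyDataset, rmsd: np.ndarray | None = None, session: int = 1
) -> "matplotlib.figure.Figure":
    """Session-1 cohort mean +/- SD per condition, with the between-condition
    RMSD inset in each panel."""
    fig, axes = _grid()
    x = np.arange(N_CYCLE_POINTS)
    colors = {0: "tab:green", 1: "black"}
    for ci, cond in enumerate(dataset.conditions()):
        per_subject = []
        for subj in dataset.subjects():
            keys = dataset.select(subject=subj, sessions=(session,), conditions=(cond,))
            if keys:
                per_subject.append(dataset.stack(keys).mean(axis=0))
        if not per_subject:
            continue
        stack = np.asarray(per_subject)
        mean, sd = stack.mean(axis=0), stack.std(axis=0, ddof=1)
        for joint in JOINTS:
            for plane in PLANES:
                idx = channel_index(joint, plane)
                ax = axes[JOINTS.index(joint), PLANES.index(plane)]
                c = colors.get(ci, None)
                ax.plot(x, mean[idx], color=c, linewidth=1.2, label=cond)
                ax.fill_between(
                    x, mean[idx] - sd[idx], mean[idx] + sd[idx], color=c, alpha=0.2
                )
    if rmsd is not None:
        for i, (joint, plane) in enumerate(CHANNELS):
            ax = axes[JOINTS.index(joint), PLANES.index(plane)]
            ax.text(
                0.97, 0.95, f"RMSD {rmsd[i]:.2f}°",
                transform=ax.transAxes, ha="right", va="top", fontsize=7,
            )
    axes[0, 0].legend(fontsize=7, loc="lower left")
    fig.suptitle(f"Session-{session} cohort means by clothing condition")
    fig.tight_layout()
    return fig
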