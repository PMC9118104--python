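"""Diagnostic figures: positional variance diagrams, staging histograms,
per-event mixture fits."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_positional_variance", "plot_staging_histogram", "plot_mixture_fit"]


def plot_positional_variance(pvd, event_names, order=None, ax=None, title=None):
    """Heatmap of event-by-position posterior frequencies, rows in ML order."""
    pvd = np.asarray(pvd)
    z = pvd.shape[0]
    if order is None:
        order = np.arange(z)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(pvd[np.asarray(order)], cmap="Blues", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(z))
    ax.set_yticklabels([event_names[i] for i in order], fontsize=7)
    ax.set_xlabel("position in sequence")
    if title:
        ax.set_title(title)
    return ax


def plot_staging_histogram(staging, n_stages=None, ax=None):
    """Proportion of each group at each model stage (cases vs controls)."""
    frame = staging.stages
    if n_stages is None:
        n_stages = len(staging.sequence) + 1
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    width = 0.4
    stages = np.arange(n_stages)
    for offset, (label, color) in zip(
        (-width / 2, width / 2), (("control", "tab:blue"), ("case", "tab:orange"))
    ):
        sub = frame[frame["group"] == label] if "group" in frame else frame
        if len(sub) == 0:
            continue
        counts = np.bincount(sub["stage"], minlength=n_stages)[:n_stages]
        ax.bar(stages + offset, counts / counts.sum(), width, label=label, color=color)
    ax.set_xlabel("model stage")
    ax.set_ylabel("proportion of group")
    ax.legend()
    return ax


def plot_mixture_fit(fit, control_values, case_values, ax=None, name=None):
    """Histograms of both groups with the fitted components and P(E|x)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grid = fit.grid_
    ax.hist(control_values, bins=30, density=True, alpha=0.4, label="controls")
    ax.hist(case_values, bins=30, density=True, alpha=0.4, label="cases")
    ax.plot(grid, fit.pdf_normal(grid), label="normal component")
    ax.plot(grid, fit.pdf_abnormal(grid), label="abnormal component")
    ax2 = ax.twinx()
    ax2.plot(grid, fit.posterior(grid), "k--", lw=1, label="P(E|x)")
    ax2.set_ylim(0, 1.05)
    ax.set_xlabel(name or "adjusted volume")
    ax.legend(fontsize=7)
    return ax
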