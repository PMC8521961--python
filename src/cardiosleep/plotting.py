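"""Plotting helpers for posterior series and screening metrics."""

from __future__ import annotations

import numpy as np


def plot_posteriors(p, labels_true=None, thresholds=None, ax=None):
    """Plot per-epoch p(Wake) over the night with the 0.5 decision line,
    optional confidence thresholds and an optional reference hypnogram strip."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(p.p_wake)) * 0.5  # minutes
    ax.plot(x, p.p_wake, lw=0.8, color="tab:green", label="p(Wake)")
    ax.axhline(0.5, color="k", lw=0.8, ls="--")
    if thresholds is not None:
        ax.axhline(thresholds.t_w, color="tab:orange", lw=0.8, ls=":",
                   label="wake confidence")
        ax.axhline(1.0 - thresholds.t_s, color="tab:red", lw=0.8, ls=":",
                   label="sleep confidence")
    if labels_true is not None:
        wake = np.asarray(labels_true) == 1
        ax.fill_between(x, 0, 1, where=wake, alpha=0.12, color="gray",
                        label="reference wake")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("p(Wake)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_severity_boxes(values_by_class: dict, threshold: float | None = None,
                        ylabel: str = "", ax=None):
    """Boxplots of a per-patient metric per severity class, with the chosen
    detection threshold as a horizontal line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    names = list(values_by_class)
    ax.boxplot([values_by_class[k] for k in names], tick_labels=names)
    if threshold is not None:
        ax.axhline(threshold, color="tab:red", lw=1.2)
    ax.set_ylabel(ylabel)
    return ax
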