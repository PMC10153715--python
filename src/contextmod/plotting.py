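"""Diagnostic plots: per-cell psychometric fits and threshold boxplots."""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .fit import FitResult, cell_coefficients
from .observers import GUESS


def psychometric_fit_plot(fit: FitResult, participant, task: str, ax=None,
                          x_range=(-3, 3)):
    """Posterior-mean psychometric curves with 95 % HDI ribbons for one
    participant and task, one curve per context condition."""
    import matplotlib.pyplot as plt

    from .fit import hdi

    if ax is None:
        _, ax = plt.subplots()
    x = np.linspace(*x_range, 101)
    g = GUESS[task]
    for cond in fit.conditions:
        b0, b1 = cell_coefficients(fit, participant, task, cond)
        curves = 0.5 * g + (1 - 0.5 * g) * expit(
            b0[:, None] + b1[:, None] * x[None, :])
        mean = curves.mean(axis=0)
        bounds = np.array([hdi(curves[:, i]) for i in range(x.size)])
        line, = ax.plot(x, mean, label=cond)
        ax.fill_between(x, bounds[:, 0], bounds[:, 1], alpha=0.2,
                        color=line.get_color())
    ax.axhline(0.75 if g else 0.5, ls=":", c="gray", lw=0.8)
    ax.set_xlabel("scaled local input strength")
    ax.set_ylabel("P(correct)" if g else "P('Different')")
    ax.set_title(f"{task}, participant {participant}")
    ax.legend()
    return ax


def threshold_boxplot(thresholds, ax=None):
    """Boxplots of scaled thresholds per task x condition with subject lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    tasks = list(dict.fromkeys(thresholds["task"]))
    conds = ("Isolated", "Different", "Same")
    positions, data, labels = [], [], []
    pos = 0
    for task in tasks:
        sub = thresholds[thresholds["task"] == task]
        wide = sub.pivot_table(index="participant", columns="condition",
                               values="threshold")[list(conds)]
        for cond in conds:
            positions.append(pos)
            data.append(wide[cond].to_numpy())
            labels.append(f"{task[:3]}\n{cond[:4]}")
            pos += 1
        for row in wide.to_numpy():
            ax.plot(positions[-3:], row, color="gray", alpha=0.2, lw=0.6)
        pos += 1
    ax.boxplot(data, positions=positions, widths=0.6)
    ax.set_xticks(positions, labels, fontsize=7)
    ax.set_ylabel("z-scaled threshold")
    return ax
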