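"""Learning-curve plots: group mean latency and per-participant power fits.

Figures are regenerated deterministically from fitted results; no RNG is
involved, so replotting from the same results is byte-stable in content.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_learning_curves", "plot_group_curve"]


def plot_group_curve(results, ax=None):
    """Mean latency per trial across the cohort, with SEM band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    Y = np.array([s.latencies for s in results.model.series])
    x = np.arange(1, Y.shape[1] + 1)
    mean = Y.mean(axis=0)
    sem = Y.std(axis=0, ddof=1) / np.sqrt(Y.shape[0])
    ax.plot(x, mean, "o-", color="tab:blue", ms=4)
    ax.fill_between(x, mean - sem, mean + sem, alpha=0.25, color="tab:blue")
    ax.set_xlabel("trial")
    ax.set_ylabel("time to sensor (s)")
    ax.set_title("group learning curve")
    return ax


def plot_learning_curves(results, path=None, max_participants: int = 25):
    """Group curve plus a grid of per-participant curves with power fits.

    Each panel shows the observed latencies, the fitted power curve over
    trials up to the participant's cut-off (dashed beyond it) and the
    cut-off trial as a vertical line.
    """
    learning = results.learning.set_index("participant_id")
    series = results.model.series[:max_participants]
    n = len(series)
    ncols = 5
    nrows = int(np.ceil(n / ncols)) + 1
    fig = plt.figure(figsize=(3 * ncols, 2.4 * nrows))
    gs = fig.add_gridspec(nrows, ncols)
    ax0 = fig.add_subplot(gs[0, :2])
    plot_group_curve(results, ax=ax0)
    for i, s in enumerate(series):
        ax = fig.add_subplot(gs[1 + i // ncols, i % ncols])
        row = learning.loc[s.participant_id]
        x = np.arange(1, s.n_trials + 1)
        ax.plot(x, s.latencies, "k.", ms=5)
        xf = np.linspace(1, s.n_trials, 100)
        yf = row["a"] * xf ** row["b"]
        cut = int(row["cutoff_trial"])
        ax.plot(xf[xf <= cut], yf[xf <= cut], "-", color="tab:red", lw=1.5)
        ax.plot(xf[xf > cut], yf[xf > cut], "--", color="tab:red", lw=0.8)
        ax.axvline(cut, color="grey", lw=0.7, ls=":")
        ax.set_title(
            f"{s.participant_id}  b={row['b']:.2f}", fontsize=8
        )
        ax.set_ylim(0, s.t_max * 1.05)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
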