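"""Optional figures: traces, ISI histograms, anticipation scatter, weights.

Convenience only — all quantitative output lives in the CSV/JSON artifacts.
Each function draws on a provided or fresh matplotlib Axes and returns it.
"""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_trace(trajectory, neurons=("master", "slave"), t_max=None, ax=None):
    """Membrane variable x over time for the chosen neurons."""
    ax = _axes(ax)
    t = trajectory.t
    m = slice(None) if t_max is None else t <= t_max
    for name in neurons:
        ax.plot(t[m], trajectory.x(name)[m], lw=0.7, label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("x")
    ax.legend(frameon=False)
    return ax


def plot_isi_histogram(hist, ax=None, log=True):
    ax = _axes(ax)
    widths = np.diff(hist.edges)
    ax.bar(hist.edges[:-1], hist.counts, width=widths, align="edge")
    if log:
        ax.set_yscale("symlog")
    ax.set_xlabel("ISI")
    ax.set_ylabel("count")
    return ax


def plot_anticipation_vs_isi(clusters, ax=None):
    """Scatter of per-spike anticipation against preceding ISI, by cluster."""
    ax = _axes(ax)
    df = clusters.pairs
    ax.scatter(
        df["preceding_isi"], df["anticipation"], s=6, c=df["cluster"], cmap="tab10"
    )
    ax.set_xlabel("preceding ISI")
    ax.set_ylabel("anticipation")
    return ax


def plot_weight_trace(trace, ax=None, **kwargs):
    ax = _axes(ax)
    ev = trace.events
    ax.plot(ev["event_time"], ev["weight"], drawstyle="steps-post", **kwargs)
    ax.axhline(trace.initial_weight, ls=":", c="gray", lw=0.8)
    ax.set_xlabel("time")
    ax.set_ylabel("synaptic weight magnitude")
    return ax
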