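"""Plots mirroring the study's figures: relative traces and index dots."""

from __future__ import annotations

import numpy as np

from .isoforms import HIGH_IIA, MAIN
from .kinetics import FluorescenceTrace, normalize_trace

GROUP_COLORS = {"CON": "tab:blue", "EXP": "tab:red"}


def _get_ax(ax):
    if ax is not None:
        return ax.figure, ax
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    return fig, ax


def plot_relative_traces(traces: list[FluorescenceTrace], results, ax=None):
    """Relative fluorescence over time, coloured by group.

    High-IIa preparations draw in black, as in the study's individual
    trace plots; blank wells are omitted.
    """
    fig, ax = _get_ax(ax)
    meta = {r.preparation_id: r.group for r in results.records}
    for tr in traces:
        if tr.condition != "ATP" or tr.preparation_id not in meta:
            continue
        rel = normalize_trace(tr)
        if results.strata.get(tr.preparation_id) == HIGH_IIA:
            color = "black"
        else:
            color = GROUP_COLORS.get(meta[tr.preparation_id], "gray")
        ax.plot(rel.times, rel.relative_intensity, color=color, alpha=0.4,
                linewidth=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("relative fluorescence intensity")
    ax.set_title("QD fluorescence decay during ATP hydrolysis")
    return fig, ax


def plot_index_distribution(results, ax=None):
    """Solid dots = qualified preparations; open circles = animal means."""
    fig, ax = _get_ax(ax)
    columns = [("CON", MAIN), ("EXP", MAIN), ("EXP", HIGH_IIA)]
    labels = []
    for x, (group, stratum) in enumerate(columns):
        preps = [p for p in results.preparations
                 if p.group == group and p.stratum == stratum and not p.failed]
        animals = [a for a in results.animals
                   if a.group == group and a.stratum == stratum]
        if not preps and stratum == HIGH_IIA:
            labels.append("EXP*\n(none)")
            continue
        color = "black" if stratum == HIGH_IIA else GROUP_COLORS[group]
        jitter = np.linspace(-0.12, 0.12, max(len(preps), 1))
        ax.scatter(x + jitter, [p.mean_index for p in preps],
                   color=color, s=25, zorder=3, label=None)
        ax.scatter([x] * len(animals), [a.mean_index for a in animals],
                   facecolors="none", edgecolors=color, s=90, zorder=4)
        labels.append(f"{group}*" if stratum == HIGH_IIA else group)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels)
    ax.set_ylabel("efficiency index (1/s per mg/mL)")
    ax.set_title("initial decay rate, blank-subtracted and normalised")
    return fig, ax
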