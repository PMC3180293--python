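"""Static figures for per-unit and population results (matplotlib)."""

from __future__ import annotations

import numpy as np

from .density import SDFMatrix, median_split_sdf
from .roc import RocTimeCourse


def plot_median_split(sdf: SDFMatrix, rt_ms, ax=None):
    """Mean SDFs of the faster- and slower-half RT trials on one axis."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    fast, slow = median_split_sdf(sdf, rt_ms)
    ax.plot(sdf.times_ms, fast, label="faster half", color="tab:red")
    ax.plot(sdf.times_ms, slow, label="slower half", color="tab:blue")
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("time from alignment event (ms)")
    ax.set_ylabel("firing rate (sp/s)")
    ax.legend(frameon=False)
    return ax


def plot_roc_timecourse(tc: RocTimeCourse, ax=None):
    """Sliding-window scaled ROC index; significant windows filled."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(tc.window_centers_ms, tc.index, color="0.4")
    sig = tc.significant
    pos, neg = sig & (tc.index > 0), sig & (tc.index < 0)
    ax.scatter(tc.window_centers_ms[pos], tc.index[pos], color="tab:red",
               zorder=3, s=14, label="significant > 0")
    ax.scatter(tc.window_centers_ms[neg], tc.index[neg], color="tab:blue",
               zorder=3, s=14, label="significant < 0")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("window center (ms)")
    ax.set_ylabel("ROC index")
    ax.legend(frameon=False)
    return ax


def plot_type_scatter(profiles, direction="contra", ax=None,
                      threshold=0.1):
    """Premovement index vs RT-rate correlation, colored by type."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    sub = profiles[profiles["direction"] == direction]
    colors = {"1": "tab:orange", "2": "tab:red", "3": "tab:green",
              "4": "tab:blue", "unclassified": "0.6"}
    for label, g in sub.groupby("type"):
        rep = g[g["representative"]] if label != "unclassified" else g
        dim = g.drop(rep.index)
        ax.scatter(rep["r"], rep["premovement_index"],
                   color=colors[label], s=18, label=f"type {label}"
                   if label != "unclassified" else "unclassified")
        ax.scatter(dim["r"], dim["premovement_index"], color=colors[label],
                   s=10, alpha=0.35)
    for v in (-threshold, threshold):
        ax.axhline(v, color="0.8", lw=0.6)
        ax.axvline(v, color="0.8", lw=0.6)
    ax.set_xlabel("RT-rate correlation r")
    ax.set_ylabel("premovement activity index")
    ax.set_title(f"{direction}versive movements")
    ax.legend(frameon=False, fontsize=8)
    return ax
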