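"""Figure helpers: polar tuning plots, cohort donut plots, OKR trajectories."""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .io import EyeTraceSet
from .okr import SaccadeEvent
from .tuning import DirectionTuning, DsPopulationSummary

__all__ = ["polar_tuning_plot", "population_donut_plot", "okr_trajectory_plot"]


def polar_tuning_plot(tuning: DirectionTuning, ax=None, path: str | Path | None = None):
    """Average response at the 12 directions on polar axes, with the
    vector-sum preferred direction marked."""
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.deg2rad(np.append(tuning.directions_deg, tuning.directions_deg[0]))
    r = np.append(tuning.raw_responses, tuning.raw_responses[0])
    ax.plot(theta, r, lw=1.5)
    if not np.isnan(tuning.preferred_direction_deg):
        ax.annotate(
            "", xy=(np.deg2rad(tuning.preferred_direction_deg), r.max()),
            xytext=(0, 0), arrowprops={"arrowstyle": "->", "color": "crimson"})
    ax.set_title(f"{tuning.roi_id}  DSI={tuning.dsi:.2f}", fontsize=9)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def population_donut_plot(summary: DsPopulationSummary, ax=None,
                          path: str | Path | None = None):
    """Cohort composition: direction-selective / responsive / unresponsive."""
    if ax is None:
        _, ax = plt.subplots()
    n_unresp = summary.n_total - summary.n_responsive
    n_nonds = summary.n_responsive - summary.n_ds
    sizes = [summary.n_ds, n_nonds, n_unresp]
    labels = [f"DS ({summary.n_ds})", f"responsive ({n_nonds})",
              f"unresponsive ({n_unresp})"]
    keep = [i for i, s in enumerate(sizes) if s > 0]
    ax.pie([sizes[i] for i in keep], labels=[labels[i] for i in keep],
           wedgeprops={"width": 0.4}, startangle=90)
    ax.set_title(f"n = {summary.n_total}, DS fraction "
                 f"{summary.ds_fraction:.1%}", fontsize=9)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def okr_trajectory_plot(eyes: EyeTraceSet, events: Sequence[SaccadeEvent] = (),
                        ax=None, path: str | Path | None = None):
    """Both eyes' angle traces with detected saccade peaks labelled."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(eyes.time_s, eyes.left_angle_deg, lw=0.8, label="left")
    ax.plot(eyes.time_s, eyes.right_angle_deg, lw=0.8, label="right")
    for e in events:
        ax.plot(e.time_s, e.d_p, "v", ms=5,
                color="tab:blue" if e.eye == "left" else "tab:orange")
    lo, hi = eyes.stimulus_window
    ax.axvspan(lo, hi, alpha=0.08, color="gray")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("eye angle (deg)")
    ax.legend(loc="upper right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
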