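"""Response kinetics: entry (20%-of-max) time, peak time, rising time.

The moment the smoothed dF/F0 first reaches 20% of its stimulus-epoch
maximum is taken as the time the moving stimulus entered the receptive
field; the peak time is when the response reaches its maximum; rising time
is their difference.  Trials whose 20% crossing falls outside the stimulus
epoch, or that never respond, are excluded.  Together these timings serve
as a receptive-field-size proxy for moving-bar responses.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .preprocessing import DffTrace, gaussian_smooth

__all__ = ["KineticsResult", "compute_kinetics", "trial_kinetics", "pool_kinetics"]

ENTRY_FRACTION = 0.2


@dataclass
class KineticsResult:
    """Entry/peak/rising times (seconds from stimulus onset) of one trial."""

    roi_id: str
    trial_id: int
    entry_time_s: float | None
    peak_time_s: float | None
    rising_time_s: float | None
    excluded: bool
    reason: str = ""


def compute_kinetics(
    trial_trace: np.ndarray,
    times_s: np.ndarray,
    stimulus_slice: slice,
    smoothing_window: int = 25,
    roi_id: str = "",
    trial_id: int = 0,
) -> KineticsResult:
    """Kinetics of one trial's dF/F0 series.

    ``trial_trace`` covers the analysis window (preceding adaptation epoch
    concatenated with the stimulus epoch) so the smoother's edge behaviour
    at stimulus onset is governed by recorded data rather than padding;
    ``stimulus_slice`` restricts the search.  Times are reported relative
    to stimulus onset, with the 20% crossing linearly interpolated between
    frames.
    """
    trial_trace = np.asarray(trial_trace, dtype=float)
    if times_s.shape != trial_trace.shape:
        raise ValueError("times_s and trial_trace must share one shape")
    n_stim = stimulus_slice.stop - stimulus_slice.start
    if n_stim < 3:
        raise ValueError("stimulus epoch must span >= 3 frames")

    smoothed = gaussian_smooth(trial_trace, smoothing_window)
    stim = smoothed[stimulus_slice]
    onset_s = times_s[stimulus_slice.start]

    peak_idx = int(np.argmax(stim))
    peak = stim[peak_idx]
    if peak <= 0:
        return KineticsResult(roi_id, trial_id, None, None, None,
                              excluded=True, reason="no response")
    threshold = ENTRY_FRACTION * peak
    above = np.nonzero(stim >= threshold)[0]
    first = int(above[0])
    global_first = stimulus_slice.start + first
    if first == 0 and global_first > 0 and smoothed[global_first - 1] >= threshold:
        # already above threshold at epoch start: the crossing happened
        # before the stimulus, so entry time is not measurable
        return KineticsResult(roi_id, trial_id, None, None, None,
                              excluded=True, reason="entry before stimulus epoch")
    if first == 0:
        entry_s = 0.0
    else:
        lo, hi = stim[first - 1], stim[first]
        frac = (threshold - lo) / (hi - lo) if hi > lo else 0.0
        t_lo = times_s[stimulus_slice.start + first - 1]
        t_hi = times_s[stimulus_slice.start + first]
        entry_s = float(t_lo + frac * (t_hi - t_lo) - onset_s)
    peak_s = float(times_s[stimulus_slice.start + peak_idx] - onset_s)
    return KineticsResult(roi_id, trial_id, entry_s, peak_s,
                          peak_s - entry_s, excluded=False)


def trial_kinetics(trace: DffTrace, smoothing_window: int = 25,
                   use_mean_trace: bool = False) -> list[KineticsResult]:
    """Kinetics for each kept trial of a :class:`DffTrace` (or, optionally,
    for the trial-averaged trace as a single result)."""
    if use_mean_trace:
        if trace.mean_trace is None:
            raise ValueError("mean_trace undefined; run reject_outlier_trials")
        return [compute_kinetics(trace.mean_trace, trace.times_s,
                                 trace.stimulus_slice, smoothing_window,
                                 roi_id=trace.roi_id, trial_id=-1)]
    trials = (trace.kept_trials if trace.kept_trials is not None
              else np.arange(trace.n_trials))
    return [
        compute_kinetics(trace.dff[t], trace.times_s, trace.stimulus_slice,
                         smoothing_window, roi_id=trace.roi_id, trial_id=int(t))
        for t in trials
    ]


def pool_kinetics(results: Sequence[KineticsResult],
                  labels: Sequence[str]) -> dict:
    """Pool per-trial kinetics by group and compare the two groups.

    Responsive (non-excluded) trials across all stimulus sizes are pooled
    per group; peak and rising times are compared with a two-sided
    Mann-Whitney test when exactly two groups are present.
    """
    if len(results) != len(labels):
        raise ValueError("results and labels must align")
    groups: dict[str, list[KineticsResult]] = {}
    for r, lab in zip(results, labels):
        if not r.excluded:
            groups.setdefault(lab, []).append(r)
    if not groups:
        raise ValueError("no non-excluded trials in any group")
    out: dict = {"groups": {}}
    for lab, rs in groups.items():
        peak = np.asarray([r.peak_time_s for r in rs])
        rise = np.asarray([r.rising_time_s for r in rs])
        out["groups"][lab] = {
            "n": len(rs),
            "peak_time_mean_s": float(peak.mean()),
            "peak_time_sd_s": float(peak.std(ddof=1)) if len(rs) > 1 else 0.0,
            "rising_time_mean_s": float(rise.mean()),
            "rising_time_sd_s": float(rise.std(ddof=1)) if len(rs) > 1 else 0.0,
        }
    if len(groups) == 2:
        (la, ra), (lb, rb) = groups.items()
        for metric, attr in (("peak_time", "peak_time_s"),
                             ("rising_time", "rising_time_s")):
            a = [getattr(r, attr) for r in ra]
            b = [getattr(r, attr) for r in rb]
            mw = stats.mannwhitneyu(a, b, alternative="two-sided")
            out[f"{metric}_mannwhitney"] = {
                "groups": (la, lb),
                "u": float(mw.statistic),
                "pvalue": float(mw.pvalue),
            }
    return out
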