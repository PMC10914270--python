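"""Raw fluorescence to per-trial dF/F0 traces.

Pipeline order per ROI and stimulus condition:

1. background subtraction — the mean of >= 3 blank-region traces is removed
   from every ROI frame-by-frame;
2. baseline F0 — per trial, the mean fluorescence over a window at the end
   of the adaptation epoch that precedes the stimulus (dendritic ROIs: the
   ~3.5 s immediately before stimulus onset; somata: the last 5 s of the
   20-s adaptation, with an optional additive offset in the denominator);
3. dF/F0 = (F - F0) / F0 (dendrite) or (F - F0) / (F0 + offset) (soma);
4. trial-level outlier rejection on stimulus-epoch variance;
5. trial averaging over the kept trials ("final raw response").

The module also provides the window-25 Gaussian smoother used by the
kinetics analysis and the iterative Grubbs test used to trim group samples
before statistics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .io import RoiTraceSet
from .protocol import Condition, ConditionWindow, StimulusProtocol

__all__ = [
    "DffParams",
    "DffTrace",
    "DegenerateBaselineError",
    "subtract_background",
    "compute_dff",
    "reject_outlier_trials",
    "gaussian_smooth",
    "grubbs_iterative",
]


class DegenerateBaselineError(ValueError):
    """Baseline F0 (or F0 + offset) is non-positive; dF/F0 is undefined."""


@dataclass(frozen=True)
class DffParams:
    """Preprocessing parameters.

    baseline_mode
        ``"dendrite"``: F0 from the ``dendrite_baseline_s`` window (default
        3.5 s) immediately before stimulus onset, denominator F0.
        ``"soma"``: F0 from the last ``soma_baseline_s`` (default 5 s) of
        the adaptation epoch, denominator F0 + ``offset``.
    trial_peak_sd_mult
        Peak threshold multiplier on baseline SD used in trial QC reporting
        (default 5).
    trial_var_sd_mult
        A trial is rejected when its stimulus-epoch dF/F0 variance deviates
        from the other trials' mean variance by more than this multiple of
        their SD (default 4).
    smoothing_window
        Gaussian window length in frames for the kinetics smoother
        (default 25).
    grubbs_alpha
        Significance level of the iterative Grubbs outlier test applied to
        group samples (default 1e-4, i.e. 0.01%).
    """

    baseline_mode: str = "dendrite"
    dendrite_baseline_s: float = 3.5
    soma_baseline_s: float = 5.0
    offset: float = 0.0
    trial_peak_sd_mult: float = 5.0
    trial_var_sd_mult: float = 4.0
    smoothing_window: int = 25
    grubbs_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if self.baseline_mode not in {"dendrite", "soma"}:
            raise ValueError("baseline_mode must be 'dendrite' or 'soma'")
        if self.trial_peak_sd_mult <= 0 or self.trial_var_sd_mult <= 0:
            raise ValueError("SD multipliers must be > 0")
        if self.dendrite_baseline_s <= 0 or self.soma_baseline_s <= 0:
            raise ValueError("baseline windows must be > 0")
        if not 0 < self.grubbs_alpha < 1:
            raise ValueError("grubbs_alpha must lie in (0, 1)")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")

    @property
    def baseline_s(self) -> float:
        return (self.dendrite_baseline_s if self.baseline_mode == "dendrite"
                else self.soma_baseline_s)


@dataclass
class DffTrace:
    """Per-trial dF/F0 for one ROI under one stimulus condition.

    ``dff`` covers the analysis window — the adaptation epoch preceding the
    stimulus plus the stimulus epoch — with shape ``(n_trials, n_window)``.
    ``baseline_slice`` and ``stimulus_slice`` index into that window.
    ``kept_trials`` lists trials surviving outlier rejection; ``mean_trace``
    is their average (the "final raw response"); both are ``None`` until
    :func:`reject_outlier_trials` runs (``mean_trace`` then averages kept
    trials, or is ``None`` when every trial was rejected).
    """

    roi_id: str
    condition: Condition
    dff: np.ndarray
    times_s: np.ndarray            # window times, seconds from sweep onset
    baseline_slice: slice
    stimulus_slice: slice
    F0: np.ndarray                 # per trial
    baseline_sd: np.ndarray        # per-trial SD of baseline-window dF/F0
    frame_rate_hz: float
    kept_trials: np.ndarray | None = None
    mean_trace: np.ndarray | None = None
    rejection_reasons: dict[int, str] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.dff.shape[0]

    def stimulus_dff(self, trial: int | None = None) -> np.ndarray:
        if trial is None:
            return self.dff[:, self.stimulus_slice]
        return self.dff[trial, self.stimulus_slice]

    @property
    def stimulus_onset_s(self) -> float:
        return float(self.times_s[self.stimulus_slice.start])


# --------------------------------------------------------------------- #
# background subtraction

def subtract_background(trace_set: RoiTraceSet) -> RoiTraceSet:
    """Subtract the frame-wise mean of the blank-region traces from every ROI.

    Requires >= 3 blank traces; the returned set has none (they are
    consumed).
    """
    if trace_set.blank is None or trace_set.blank.shape[0] < 3:
        n = 0 if trace_set.blank is None else trace_set.blank.shape[0]
        raise ValueError(f"background subtraction needs >= 3 blank traces, got {n}")
    background = trace_set.blank.mean(axis=0)  # (n_trials, n_frames)
    return replace(trace_set, F=trace_set.F - background[None], blank=None)


# --------------------------------------------------------------------- #
# dF/F0

def _window_indices(protocol: StimulusProtocol, cw: ConditionWindow,
                    params: DffParams) -> tuple[np.ndarray, slice, slice]:
    """Frame indices of the analysis window and baseline/stimulus slices."""
    t = protocol.frame_times()
    win = np.nonzero((t >= cw.adaptation.start_s) & (t < cw.stimulus.end_s))[0]
    if win.size == 0:
        raise ValueError(f"no frames in window for condition {cw.condition}")
    tw = t[win]
    # baseline: the last baseline_s of the adaptation epoch (immediately
    # before stimulus onset when the stimulus follows the adaptation
    # directly, e.g. moving bars and flash onset; for the post-offset OFF
    # window the same pre-flash adaptation serves as baseline)
    base_start = cw.adaptation.end_s - params.baseline_s
    if base_start < cw.adaptation.start_s - 1e-9:
        raise ValueError(
            f"baseline window ({params.baseline_s} s) does not fit inside the "
            f"adaptation epoch ({cw.adaptation.duration_s} s)"
        )
    base = np.nonzero((tw >= base_start) & (tw < cw.adaptation.end_s))[0]
    stim = np.nonzero((tw >= cw.stimulus.start_s) & (tw < cw.stimulus.end_s))[0]
    if base.size == 0 or stim.size == 0:
        raise ValueError(f"empty baseline or stimulus window for {cw.condition}")
    return win, slice(int(base[0]), int(base[-1]) + 1), slice(int(stim[0]), int(stim[-1]) + 1)


def compute_dff(trace_set: RoiTraceSet, params: DffParams | None = None) -> list[DffTrace]:
    """Compute per-trial dF/F0 traces for every ROI x stimulus condition.

    Raises :class:`DegenerateBaselineError` if any trial's F0 (dendrite
    mode) or F0 + offset (soma mode) is non-positive.
    """
    params = params or DffParams()
    protocol = trace_set.protocol
    if protocol is None:
        raise ValueError("trace set has no protocol; frame registration is undefined")
    out: list[DffTrace] = []
    for cw in protocol.condition_windows():
        win, base_sl, stim_sl = _window_indices(protocol, cw, params)
        tw = protocol.frame_times()[win]
        for i, rid in enumerate(trace_set.roi_ids):
            F = trace_set.F[i][:, win]  # (n_trials, n_window)
            F0 = F[:, base_sl].mean(axis=1)
            denom = F0 if params.baseline_mode == "dendrite" else F0 + params.offset
            if np.any(denom <= 0):
                bad = int(np.nonzero(denom <= 0)[0][0])
                raise DegenerateBaselineError(
                    f"ROI {rid}, condition {cw.condition}, trial {bad}: "
                    f"baseline denominator {denom[bad]:.3g} <= 0"
                )
            dff = (F - F0[:, None]) / denom[:, None]
            baseline_sd = dff[:, base_sl].std(axis=1, ddof=0)
            out.append(DffTrace(
                roi_id=rid, condition=cw.condition, dff=dff, times_s=tw,
                baseline_slice=base_sl, stimulus_slice=stim_sl,
                F0=F0, baseline_sd=baseline_sd,
                frame_rate_hz=protocol.frame_rate_hz,
            ))
    return out


# --------------------------------------------------------------------- #
# trial outlier rejection

def reject_outlier_trials(trace: DffTrace, params: DffParams | None = None) -> DffTrace:
    """Remove outlier trials and average the survivors.

    A trial is rejected when the variance of its stimulus-epoch dF/F0
    deviates from the mean variance of the *other* recorded trials by more
    than ``trial_var_sd_mult`` times their SD (leave-one-out, so a single
    aberrant trial cannot mask itself by inflating the pooled spread).
    Trials whose stimulus-epoch dF/F0 never crosses ``trial_peak_sd_mult``
    x baseline SD while other trials do are annotated as sub-threshold in
    the QC reasons; on their own they are not removed.

    With fewer than 3 recorded trials no spread is estimable and all trials
    are kept.  Flags are always computed from the full recorded set, so the
    operation is idempotent.
    """
    params = params or DffParams()
    n = trace.n_trials
    stim = trace.stimulus_dff()
    reasons: dict[int, str] = {}
    keep = np.ones(n, dtype=bool)
    if n >= 3:
        variances = stim.var(axis=1, ddof=0)
        peaks = stim.max(axis=1)
        crossed = peaks > params.trial_peak_sd_mult * trace.baseline_sd
        for t in range(n):
            others = np.delete(variances, t)
            spread = others.std(ddof=0)
            if abs(variances[t] - others.mean()) > params.trial_var_sd_mult * spread:
                keep[t] = False
                reasons[t] = "stimulus-epoch variance outlier"
                if not crossed[t] and crossed[np.arange(n) != t].any():
                    reasons[t] += "; sub-threshold peak"
    kept = np.nonzero(keep)[0]
    mean_trace = trace.dff[kept].mean(axis=0) if kept.size else None
    return replace(trace, kept_trials=kept, mean_trace=mean_trace,
                   rejection_reasons=reasons)


# --------------------------------------------------------------------- #
# Gaussian smoothing

def gaussian_smooth(series: np.ndarray, window: int = 25) -> np.ndarray:
    """Smooth with a unit-mass Gaussian kernel of the given window length.

    sigma = window / 5, kernel truncated to the window, reflected
    boundaries; output length equals input length.  A window longer than
    the series is clipped with a warning.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if window < 1:
        raise ValueError("window must be >= 1")
    n = series.size
    if n == 0:
        return series.copy()
    if window > n:
        warnings.warn(
            f"smoothing window {window} exceeds series length {n}; clipping",
            stacklevel=2,
        )
        window = n
    if window == 1:
        return series.copy()
    sigma = window / 5.0
    radius = window // 2  # kernel length = 2*radius + 1 ~ window
    return ndimage.gaussian_filter1d(series, sigma=sigma, mode="reflect",
                                     radius=radius)


# --------------------------------------------------------------------- #
# iterative Grubbs

def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution quantile."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


def grubbs_iterative(values: np.ndarray, alpha: float = 1e-4
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively remove the most extreme value while Grubbs' test rejects.

    Two-sided test: G = max |x - mean| / s (sample SD).  Repeats until no
    removal is significant or fewer than 3 values remain; a zero-SD sample
    is returned unchanged.  Returns ``(kept, removed)`` with ``removed`` in
    removal order.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    kept = np.asarray(values, dtype=float).ravel().copy()
    removed: list[float] = []
    while kept.size >= 3:
        mean = kept.mean()
        sd = kept.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(kept - mean)
        i = int(np.argmax(dev))
        if dev[i] / sd > _grubbs_critical(kept.size, alpha):
            removed.append(kept[i])
            kept = np.delete(kept, i)
        else:
            break
    return kept, np.asarray(removed)
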