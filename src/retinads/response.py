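"""Response qualification, ON/OFF polarity, and latency.

An ROI counts as visually responsive when (1) its stimulus-epoch dF/F0
exceeds ``sd_mult`` x the baseline SD within a trial, (2) that happens in
at least ``min_trials`` of the repeated trials, and (3) outlier trials have
been removed upstream (:func:`retinads.preprocessing.reject_outlier_trials`).
The peak of the trial-averaged trace within the stimulus epoch is the ROI's
representative response amplitude.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocessing import DffTrace, reject_outlier_trials

__all__ = [
    "QualificationParams",
    "ResponseCall",
    "qualify_roi",
    "soma_response_amplitude",
    "classify_polarity",
    "response_latency",
]

ON = "ON"
OFF = "OFF"
ON_OFF = "ON_OFF"
NONE = "none"


@dataclass(frozen=True)
class QualificationParams:
    """sd_mult: dF threshold multiplier on baseline SD (default 5).
    min_trials: responsive-trial minimum out of the repeats (default 2 of 4).
    soma_amplitude_rule: amplitude convention for somatic ROIs (peak of the
    trial mean; the only implemented rule)."""

    sd_mult: float = 5.0
    min_trials: int = 2
    soma_amplitude_rule: str = "peak_of_mean"

    def __post_init__(self) -> None:
        if self.sd_mult <= 0:
            raise ValueError("sd_mult must be > 0")
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")
        if self.soma_amplitude_rule != "peak_of_mean":
            raise ValueError("soma_amplitude_rule must be 'peak_of_mean'")


@dataclass
class ResponseCall:
    """Qualification verdict for one ROI under one condition."""

    roi_id: str
    qualified: bool
    n_responsive_trials: int
    representative_dff: float | None = None
    polarity: str = NONE
    latencies_s: np.ndarray | None = None
    mean_latency_s: float | None = None


def _responsive_trials(trace: DffTrace, params: QualificationParams) -> np.ndarray:
    """Kept trials whose stimulus-epoch dF/F0 crosses sd_mult x baseline SD."""
    if trace.kept_trials is None:
        raise ValueError(
            "trial outliers not yet removed; run reject_outlier_trials first"
        )
    kept = trace.kept_trials
    peaks = trace.stimulus_dff()[kept].max(axis=1)
    return kept[peaks > params.sd_mult * trace.baseline_sd[kept]]


def qualify_roi(trace: DffTrace, params: QualificationParams | None = None
                ) -> ResponseCall:
    """Decide whether one ROI responded to one stimulus condition.

    Unresponsive ROIs are returned with ``qualified=False`` rather than
    raising; an all-trials-rejected trace is unresponsive by definition.
    """
    params = params or QualificationParams()
    if trace.kept_trials is not None and trace.kept_trials.size == 0:
        return ResponseCall(trace.roi_id, qualified=False, n_responsive_trials=0)
    responsive = _responsive_trials(trace, params)
    qualified = responsive.size >= params.min_trials
    rep = None
    if qualified:
        rep = float(trace.mean_trace[trace.stimulus_slice].max())
    return ResponseCall(trace.roi_id, qualified=qualified,
                        n_responsive_trials=int(responsive.size),
                        representative_dff=rep)


def soma_response_amplitude(trace: DffTrace) -> float:
    """Response amplitude of a somatic ROI: the maximum of the across-trial
    mean dF/(F0+offset) within the stimulus epoch."""
    if trace.kept_trials is None:
        trace = reject_outlier_trials(trace)
    if trace.kept_trials.size == 0:
        raise ValueError(f"ROI {trace.roi_id}: no kept trials")
    return float(trace.mean_trace[trace.stimulus_slice].max())


def classify_polarity(on_trace: DffTrace, off_trace: DffTrace,
                      params: QualificationParams | None = None) -> str:
    """ON/OFF polarity from full-field flash responses.

    ``on_trace`` must carry the light-on epoch as its stimulus window and
    ``off_trace`` the equal-length post-offset window; polarity is decided
    by running qualification independently on each.

    The indicator decays slowly, so an ON response is still relaxing when
    the light steps off; the OFF window is therefore re-anchored to its own
    first sample per trial, making the OFF criterion an *increment* above
    the light-offset level rather than absolute dF/F0.  A decaying ON tail
    then never counts as an OFF response, while a genuine post-offset rise
    does.
    """
    params = params or QualificationParams()
    on_ok = qualify_roi(on_trace, params).qualified
    anchor = off_trace.dff[:, [off_trace.stimulus_slice.start]]
    anchored = replace(off_trace, dff=off_trace.dff - anchor,
                       mean_trace=(off_trace.mean_trace - anchor.mean()
                                   if off_trace.mean_trace is not None else None))
    off_ok = qualify_roi(anchored, params).qualified
    if on_ok and off_ok:
        return ON_OFF
    if on_ok:
        return ON
    if off_ok:
        return OFF
    return NONE


def response_latency(trace: DffTrace, params: QualificationParams | None = None
                     ) -> tuple[np.ndarray, float | None]:
    """Per-trial latency from stimulus onset to the first threshold crossing.

    Latency is measured on trials that individually pass the amplitude
    criterion; a trial never crossing ``sd_mult`` x baseline SD within the
    stimulus epoch is excluded.  Returns ``(latencies_s, mean_latency_s)``;
    the mean is ``None`` when no trial qualifies.
    """
    params = params or QualificationParams()
    if trace.kept_trials is None:
        trace = reject_outlier_trials(trace)
    dt = 1.0 / trace.frame_rate_hz
    latencies = []
    for t in trace.kept_trials:
        thr = params.sd_mult * trace.baseline_sd[t]
        stim = trace.stimulus_dff(int(t))
        above = np.nonzero(stim > thr)[0]
        if above.size:
            latencies.append(above[0] * dt)
    lat = np.asarray(latencies, dtype=float)
    return lat, (float(lat.mean()) if lat.size else None)
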