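"""Synthetic-data generator: trial-structured GCaMP6s-like traces and
eye-angle recordings with known ground truth.

Every pipeline input can be generated here so each analysis stage is
testable by parameter recovery.  The generative model:

* Direction tuning is cosine, a_i = A (1 + c cos(theta_i - pd_true)); when
  pd_true lies on a sampled direction the analytic preferred direction is
  pd_true and the analytic DSI equals the contrast c (Pref = A(1+c), Null =
  A(1-c)), so downstream recovery has a closed form.
* Calcium dynamics follow a difference-of-exponentials kernel (tau_rise
  0.18 s, tau_decay 1.8 s by default, GCaMP6s-like), peak-normalized.
* Fluorescence per frame is F0_base * (1 + a_i * K(t - onset - delay)) plus
  white Gaussian noise of SD ``noise_sd * F0_base``; blank ROIs are a
  constant background plus the same noise.
* Eye traces are slow pursuit drift plus injected step saccades against the
  drift direction, with Gaussian angle noise.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import EyeTraceSet, RoiTraceSet
from .protocol import FLASH_OFF_BACKGROUND, FLASH_ON, MOVING_BAR, StimulusProtocol

__all__ = [
    "TuningGroundTruth",
    "SaccadeGroundTruth",
    "calcium_kernel",
    "cosine_tuning",
    "generate_tuned_roi",
    "generate_tuned_cohort",
    "generate_flash_roi",
    "generate_size_cohort",
    "generate_eye_trace",
]

F0_BASE = 100.0          # arbitrary grayscale units
BACKGROUND_LEVEL = 10.0  # blank-region level, same units
TAU_RISE_S = 0.18
TAU_DECAY_S = 1.8


@dataclass(frozen=True)
class TuningGroundTruth:
    """Generative parameters of one simulated ROI.

    ``contrast`` is the cosine-tuning contrast c in [0, 1]; with ``pd_true_deg``
    on a sampled direction the analytic DSI equals c.  ``noise_sd`` is the
    baseline fluorescence SD as a fraction of F0, so the peak signal-to-noise
    ratio is ``peak_amplitude / noise_sd``.
    """

    roi_id: str
    pd_true_deg: float = 0.0
    contrast: float = 0.5
    peak_amplitude: float = 1.0       # dF/F0 units at the preferred direction
    tau_rise_s: float = TAU_RISE_S
    tau_decay_s: float = TAU_DECAY_S
    noise_sd: float = 0.1             # fraction of F0
    onset_delay_s: float = 0.5
    polarity_true: str = "none"       # for flash simulations: ON/OFF/ON_OFF/none
    responsive_true: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.contrast <= 1:
            raise ValueError("contrast must lie in [0, 1]")
        if self.tau_decay_s <= self.tau_rise_s:
            raise ValueError("tau_decay_s must exceed tau_rise_s")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SaccadeGroundTruth:
    """Injected-saccade schedule for one simulated animal."""

    fish_id: str
    saccade_times_s: tuple[float, ...]
    amplitudes_deg: tuple[float, ...]
    slow_phase_deg_s: float = 5.0     # pursuit drift velocity
    noise_sd_deg: float = 0.5
    stimulus_window: tuple[float, float] = (5.0, 45.0)
    min_separation_s: float = 2.0

    def __post_init__(self) -> None:
        times = np.asarray(self.saccade_times_s)
        if len(self.amplitudes_deg) != times.size:
            raise ValueError("amplitudes must align with saccade times")
        lo, hi = self.stimulus_window
        if times.size and (times.min() < lo or times.max() >= hi):
            raise ValueError("injected saccades must fall inside the stimulus window")
        if times.size >= 2 and np.diff(np.sort(times)).min() < self.min_separation_s:
            raise ValueError(
                f"saccades closer than min_separation_s={self.min_separation_s}"
            )


def calcium_kernel(t: np.ndarray, tau_rise_s: float = TAU_RISE_S,
                   tau_decay_s: float = TAU_DECAY_S) -> np.ndarray:
    """Peak-normalized difference-of-exponentials calcium impulse response.

    K(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / K_max for t >= 0, else 0.
    """
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0,
                   np.exp(-np.clip(t, 0, None) / tau_decay_s)
                   - np.exp(-np.clip(t, 0, None) / tau_rise_s),
                   0.0)
    # analytic peak location of the difference of exponentials
    t_peak = (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)
              * np.log(tau_decay_s / tau_rise_s))
    peak = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    return raw / peak


def cosine_tuning(directions_deg: Sequence[float], pd_deg: float,
                  contrast: float, amplitude: float = 1.0) -> np.ndarray:
    """a_i = A (1 + c cos(theta_i - pd)); analytic DSI = c at sampled pd."""
    theta = np.deg2rad(np.asarray(directions_deg, dtype=float))
    return amplitude * (1 + contrast * np.cos(theta - np.deg2rad(pd_deg)))


def _signal_grid(protocol: StimulusProtocol) -> np.ndarray:
    return protocol.frame_times()


def _render_responses(protocol: StimulusProtocol, truth: TuningGroundTruth,
                      amplitude_of_epoch) -> np.ndarray:
    """Noise-free dF/F0 signal on the full sweep grid.

    ``amplitude_of_epoch(epoch) -> float`` supplies the response amplitude
    for each stimulus epoch (0 suppresses it).
    """
    t = _signal_grid(protocol)
    signal = np.zeros_like(t)
    for ep in protocol.epochs:
        if ep.kind not in (MOVING_BAR, FLASH_ON, FLASH_OFF_BACKGROUND):
            continue
        a = amplitude_of_epoch(ep)
        if a == 0:
            continue
        onset = ep.start_s + truth.onset_delay_s
        signal += a * calcium_kernel(t - onset, truth.tau_rise_s, truth.tau_decay_s)
    return signal


def _assemble(protocol: StimulusProtocol, signal: np.ndarray,
              truth: TuningGroundTruth, rng: np.random.Generator,
              n_blank: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Fluorescence cube (n_trials, n_frames) plus blank traces."""
    n_frames = signal.size
    F = np.empty((protocol.n_trials, n_frames))
    for trial in range(protocol.n_trials):
        noise = rng.normal(0.0, truth.noise_sd * F0_BASE, size=n_frames)
        F[trial] = F0_BASE * (1.0 + signal) + noise
    blank = np.empty((n_blank, protocol.n_trials, n_frames))
    for b in range(n_blank):
        for trial in range(protocol.n_trials):
            blank[b, trial] = BACKGROUND_LEVEL + rng.normal(
                0.0, truth.noise_sd * F0_BASE, size=n_frames)
    return F, blank


def generate_tuned_roi(protocol: StimulusProtocol, truth: TuningGroundTruth,
                       seed: int) -> RoiTraceSet:
    """Simulate one direction-tuned ROI under a moving-bar protocol."""
    rng = np.random.default_rng(seed)
    amps: dict[float, float] = {}
    if truth.responsive_true:
        a = cosine_tuning(protocol.directions_deg, truth.pd_true_deg,
                          truth.contrast, truth.peak_amplitude)
        amps = dict(zip(protocol.directions_deg, a))
    signal = _render_responses(
        protocol, truth, lambda ep: amps.get(ep.direction_deg, 0.0),
    )
    F, blank = _assemble(protocol, signal, truth, rng)
    return RoiTraceSet(roi_ids=[truth.roi_id], F=F[None], blank=blank,
                       protocol=protocol)


def generate_tuned_cohort(protocol: StimulusProtocol,
                          truths: Sequence[TuningGroundTruth],
                          seed: int) -> RoiTraceSet:
    """Simulate a cohort of tuned ROIs sharing one sweep grid and blanks.

    Each ROI's noise stream is drawn from a child seed so single-ROI and
    cohort simulations of the same truth record are independent but the
    cohort is reproducible as a whole.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(truths) + 1)
    Fs = []
    for truth, s in zip(truths, seeds[:-1]):
        single = generate_tuned_roi(protocol, truth, int(s))
        Fs.append(single.F[0])
    blank_rng = np.random.default_rng(int(seeds[-1]))
    n_frames = protocol.n_frames
    blank_sd = (truths[0].noise_sd if truths else 0.1) * F0_BASE
    blank = BACKGROUND_LEVEL + blank_rng.normal(
        0.0, blank_sd, size=(3, protocol.n_trials, n_frames))
    return RoiTraceSet(roi_ids=[t.roi_id for t in truths], F=np.stack(Fs),
                       blank=blank, protocol=protocol)


def generate_flash_roi(protocol: StimulusProtocol, truth: TuningGroundTruth,
                       seed: int) -> RoiTraceSet:
    """Simulate a flash-protocol ROI with the requested ON/OFF polarity."""
    rng = np.random.default_rng(seed)
    on = truth.polarity_true in {"ON", "ON_OFF"} and truth.responsive_true
    off = truth.polarity_true in {"OFF", "ON_OFF"} and truth.responsive_true

    def amp(ep):
        if ep.kind == FLASH_ON and on:
            return truth.peak_amplitude
        if ep.kind == FLASH_OFF_BACKGROUND and off:
            return truth.peak_amplitude
        return 0.0

    signal = _render_responses(protocol, truth, amp)
    F, blank = _assemble(protocol, signal, truth, rng)
    return RoiTraceSet(roi_ids=[truth.roi_id], F=F[None], blank=blank,
                       protocol=protocol)


def generate_size_cohort(
    widths_px: Sequence[float],
    amplitude_fn_by_group: dict,
    n_cells: int,
    seed: int,
    noise_sd: float = 0.1,
    n_animals: int = 3,
    responsive_threshold: float = 0.05,
) -> tuple[list[dict], dict]:
    """Per-(cell, width) amplitude records for the bar-size analysis.

    ``amplitude_fn_by_group`` maps group label -> callable(width) giving the
    true mean amplitude; each measurement adds Gaussian noise of SD
    ``noise_sd``.  Cells are assigned round-robin to ``n_animals`` animals
    per group.  Returns ``(records, truth)`` where records feed
    :func:`retinads.size_tuning.build_size_table`.
    """
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    truth: dict = {}
    for group, fn in sorted(amplitude_fn_by_group.items()):
        truth[group] = {float(w): float(fn(w)) for w in widths_px}
        for c in range(n_cells):
            cell_id = f"{group}_cell{c:03d}"
            animal = f"{group}_fish{c % n_animals}"
            for w in widths_px:
                true_amp = float(fn(w))
                amp = true_amp + rng.normal(0.0, noise_sd)
                records.append({
                    "cell_id": cell_id,
                    "group": group,
                    "animal": animal,
                    "width_px": float(w),
                    "amplitude": amp,
                    "responsive": bool(true_amp > responsive_threshold),
                })
    return records, truth


def generate_eye_trace(truth: SaccadeGroundTruth, seed: int,
                       sampling_hz: float = 30.0,
                       blank_s: float = 5.0,
                       grating_s: float = 40.0) -> EyeTraceSet:
    """Simulate a two-eye angle recording: 5 s blank + 40 s grating + 5 s
    blank at 30 Hz, slow pursuit drift with injected resetting saccades.

    During the grating the eye drifts at ``slow_phase_deg_s`` in the
    stimulus direction; at each injected time the angle steps by the
    injected amplitude against the drift within one sample interval.  Both
    eyes receive the same (conjugate) saccade schedule, independent noise.
    """
    rng = np.random.default_rng(seed)
    total_s = 2 * blank_s + grating_s
    n = int(round(total_s * sampling_hz))
    t = np.arange(n) / sampling_hz
    dt = 1.0 / sampling_hz
    lo, hi = truth.stimulus_window

    drift_v = np.where((t >= lo) & (t < hi), truth.slow_phase_deg_s, 0.0)
    base = np.concatenate([[0.0], np.cumsum(drift_v[:-1] * dt)])
    jumps = np.zeros(n)
    for ts, amp in zip(truth.saccade_times_s, truth.amplitudes_deg):
        k = int(np.searchsorted(t, ts))
        jumps[k:] -= amp * np.sign(truth.slow_phase_deg_s or 1.0)
    clean = base + jumps
    clean -= clean.mean()  # keep angles centred in the oculomotor range
    left = clean + rng.normal(0.0, truth.noise_sd_deg, size=n)
    right = clean + rng.normal(0.0, truth.noise_sd_deg, size=n)
    return EyeTraceSet(time_s=t, left_angle_deg=left, right_angle_deg=right,
                       sampling_hz=sampling_hz,
                       stimulus_window=truth.stimulus_window)
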