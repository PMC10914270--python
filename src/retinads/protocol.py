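"""Stimulus-protocol data model: the experiment timeline.

A recording is trial-structured: each trial is one sweep through a set of
stimulus conditions (moving-bar directions and/or full-field flashes), every
condition preceded by an adaptation epoch that lets the calcium response
decay back to baseline.  Frame ``k`` of a trial maps to time ``k /
frame_rate_hz`` from sweep onset; an epoch owns a frame iff its half-open
interval ``[start_s, end_s)`` contains the frame time.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "Epoch",
    "Condition",
    "ConditionWindow",
    "StimulusProtocol",
    "ProtocolError",
    "read_protocol",
    "write_protocol",
]

DEFAULT_DIRECTIONS = tuple(range(0, 360, 30))  # 0 deg = leftward motion

ADAPTATION = "adaptation"
MOVING_BAR = "moving_bar"
FLASH_ON = "flash_on"
FLASH_OFF_BACKGROUND = "flash_off_background"
EPOCH_KINDS = (ADAPTATION, MOVING_BAR, FLASH_ON, FLASH_OFF_BACKGROUND)
STIMULUS_KINDS = (MOVING_BAR, FLASH_ON, FLASH_OFF_BACKGROUND)


class ProtocolError(ValueError):
    """Raised when a protocol description violates its invariants."""


@dataclass(frozen=True)
class Epoch:
    """One contiguous segment of the trial timeline, ``[start_s, end_s)``."""

    kind: str
    start_s: float
    end_s: float
    direction_deg: float | None = None
    bar_width_px: float | None = None
    trial_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in EPOCH_KINDS:
            raise ProtocolError(f"unknown epoch kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise ProtocolError(
                f"epoch {self.kind}: end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )
        if (self.direction_deg is not None) != (self.kind == MOVING_BAR):
            raise ProtocolError(
                f"direction_deg must be present iff kind == {MOVING_BAR!r} (got kind={self.kind!r})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float | np.ndarray):
        return (self.start_s <= t) & (t < self.end_s)


@dataclass(frozen=True, order=True)
class Condition:
    """Label of one stimulus condition (what was shown, not when)."""

    kind: str
    direction_deg: float | None = None
    bar_width_px: float | None = None

    def __str__(self) -> str:  # used in CSV condition columns
        parts = [self.kind]
        if self.direction_deg is not None:
            parts.append(f"dir{self.direction_deg:g}")
        if self.bar_width_px is not None:
            parts.append(f"w{self.bar_width_px:g}")
        return "_".join(parts)


@dataclass(frozen=True)
class ConditionWindow:
    """A stimulus epoch paired with the adaptation epoch that precedes it."""

    condition: Condition
    adaptation: Epoch
    stimulus: Epoch


@dataclass(frozen=True)
class StimulusProtocol:
    """Timeline of one trial sweep plus acquisition parameters.

    Parameters
    ----------
    frame_rate_hz
        Two-photon acquisition rate; the hardware delivers roughly
        4.0-4.8 Hz, default 4.4.
    epochs
        Ordered, non-overlapping epochs of one trial sweep.
    n_trials
        Repetitions of the sweep (default 4).
    directions_deg
        Motion directions, degrees, 0 = leftward, increasing
        counterclockwise; strictly increasing, each in [0, 360).
    bar_widths_px
        Optional bar-width series (small range {2, 5, 10} or large range
        {10, 50, 250}).
    adaptation_s
        Inter-stimulus adaptation duration (response-decay window), default
        20 s.
    flash_duration_s
        Full-field flash duration for ON/OFF mapping, default 3 s.
    """

    frame_rate_hz: float = 4.4
    epochs: tuple[Epoch, ...] = ()
    n_trials: int = 4
    directions_deg: tuple[float, ...] = DEFAULT_DIRECTIONS
    bar_widths_px: tuple[float, ...] | None = None
    adaptation_s: float = 20.0
    flash_duration_s: float = 3.0

    def __post_init__(self) -> None:
        if not (4.0 <= self.frame_rate_hz <= 4.8):
            # the acquisition hardware runs in this band; outside it the
            # frame<->time registration assumptions no longer hold
            raise ProtocolError(
                f"frame_rate_hz must lie in [4.0, 4.8], got {self.frame_rate_hz}"
            )
        if self.n_trials < 1:
            raise ProtocolError("n_trials must be >= 1")
        dirs = tuple(float(d) for d in self.directions_deg)
        if any(not (0 <= d < 360) for d in dirs):
            raise ProtocolError("directions_deg must each lie in [0, 360)")
        if any(b >= a for a, b in zip(dirs[1:], dirs[:-1])):
            raise ProtocolError("directions_deg must be strictly increasing")
        object.__setattr__(self, "directions_deg", dirs)
        if self.bar_widths_px is not None:
            widths = tuple(float(w) for w in self.bar_widths_px)
            if any(b >= a for a, b in zip(widths[1:], widths[:-1])):
                raise ProtocolError("bar_widths_px must be strictly increasing")
            object.__setattr__(self, "bar_widths_px", widths)
        eps = tuple(self.epochs)
        for prev, cur in zip(eps[:-1], eps[1:]):
            if cur.start_s < prev.end_s - 1e-9:
                raise ProtocolError(
                    f"epochs overlap or are out of order at t={cur.start_s}"
                )
        object.__setattr__(self, "epochs", eps)

    # ------------------------------------------------------------------ #
    # timeline construction

    @classmethod
    def moving_bar(
        cls,
        directions_deg: Sequence[float] = DEFAULT_DIRECTIONS,
        bar_width_px: float = 50.0,
        stimulus_s: float = 8.0,
        **kwargs,
    ) -> "StimulusProtocol":
        """Build a sweep presenting a moving bar at each direction in order,
        each preceded by an adaptation epoch."""
        proto = cls(directions_deg=tuple(directions_deg), **kwargs)
        epochs: list[Epoch] = []
        t = 0.0
        for d in proto.directions_deg:
            epochs.append(Epoch(ADAPTATION, t, t + proto.adaptation_s))
            t += proto.adaptation_s
            epochs.append(
                Epoch(MOVING_BAR, t, t + stimulus_s, direction_deg=d,
                      bar_width_px=float(bar_width_px))
            )
            t += stimulus_s
        return replace(proto, epochs=tuple(epochs))

    @classmethod
    def size_series(
        cls,
        bar_widths_px: Sequence[float],
        directions_deg: Sequence[float] = DEFAULT_DIRECTIONS,
        stimulus_s: float = 8.0,
        **kwargs,
    ) -> "StimulusProtocol":
        """Sweep over every (width, direction) pair of a bar-width series."""
        proto = cls(directions_deg=tuple(directions_deg),
                    bar_widths_px=tuple(bar_widths_px), **kwargs)
        epochs: list[Epoch] = []
        t = 0.0
        for w in proto.bar_widths_px:
            for d in proto.directions_deg:
                epochs.append(Epoch(ADAPTATION, t, t + proto.adaptation_s))
                t += proto.adaptation_s
                epochs.append(
                    Epoch(MOVING_BAR, t, t + stimulus_s, direction_deg=d,
                          bar_width_px=float(w))
                )
                t += stimulus_s
        return replace(proto, epochs=tuple(epochs))

    @classmethod
    def flash(cls, **kwargs) -> "StimulusProtocol":
        """Full-field flash sweep for ON/OFF polarity mapping.

        One flash per sweep: adaptation, light on for ``flash_duration_s``,
        then an equal-length post-offset window on the black background (the
        OFF analysis epoch), then a trailing adaptation so the OFF window's
        own response can decay.
        """
        proto = cls(**kwargs)
        t = 0.0
        epochs = [Epoch(ADAPTATION, t, t + proto.adaptation_s)]
        t += proto.adaptation_s
        epochs.append(Epoch(FLASH_ON, t, t + proto.flash_duration_s))
        t += proto.flash_duration_s
        epochs.append(Epoch(FLASH_OFF_BACKGROUND, t, t + proto.flash_duration_s))
        t += proto.flash_duration_s
        epochs.append(Epoch(ADAPTATION, t, t + proto.adaptation_s))
        return replace(proto, epochs=tuple(epochs))

    # ------------------------------------------------------------------ #
    # frame/time registration

    @property
    def sweep_duration_s(self) -> float:
        if not self.epochs:
            return 0.0
        return self.epochs[-1].end_s

    @property
    def n_frames(self) -> int:
        """Frames per trial sweep (frame k at time k / frame_rate_hz)."""
        return int(math.floor(self.sweep_duration_s * self.frame_rate_hz))

    def frame_times(self, n_frames: int | None = None) -> np.ndarray:
        n = self.n_frames if n_frames is None else n_frames
        return np.arange(n) / self.frame_rate_hz

    def frames_in(self, epoch: Epoch, n_frames: int | None = None) -> np.ndarray:
        """Indices of frames whose time falls in ``[start_s, end_s)``."""
        t = self.frame_times(n_frames)
        return np.nonzero(epoch.contains(t))[0]

    def condition_windows(self) -> list[ConditionWindow]:
        """Pair every stimulus epoch with the adaptation epoch preceding it."""
        out: list[ConditionWindow] = []
        prev_adapt: Epoch | None = None
        for ep in self.epochs:
            if ep.kind == ADAPTATION:
                prev_adapt = ep
            elif ep.kind in STIMULUS_KINDS:
                if ep.kind == FLASH_OFF_BACKGROUND:
                    # the OFF window is analysed against the adaptation
                    # preceding the flash it follows
                    adapt = prev_adapt
                else:
                    adapt = prev_adapt
                if adapt is None:
                    raise ProtocolError(
                        f"stimulus epoch at t={ep.start_s} has no preceding adaptation"
                    )
                cond = Condition(ep.kind, ep.direction_deg, ep.bar_width_px)
                out.append(ConditionWindow(cond, adapt, ep))
        return out

    # ------------------------------------------------------------------ #
    # serialization

    def to_dict(self) -> dict:
        d: dict = {
            "frame_rate_hz": self.frame_rate_hz,
            "n_trials": self.n_trials,
            "directions_deg": list(self.directions_deg),
            "adaptation_s": self.adaptation_s,
            "flash_duration_s": self.flash_duration_s,
        }
        if self.bar_widths_px is not None:
            d["bar_widths_px"] = list(self.bar_widths_px)
        if self.epochs:
            d["epochs"] = [
                {k: v for k, v in {
                    "kind": e.kind, "start_s": e.start_s, "end_s": e.end_s,
                    "direction_deg": e.direction_deg,
                    "bar_width_px": e.bar_width_px,
                    "trial_index": e.trial_index,
                }.items() if v is not None}
                for e in self.epochs
            ]
        return d


_PROTOCOL_FIELDS = {
    "frame_rate_hz", "epochs", "n_trials", "directions_deg",
    "bar_widths_px", "adaptation_s", "flash_duration_s",
}


def read_protocol(path: str | Path, min_baseline_s: float = 3.5) -> StimulusProtocol:
    """Read a protocol config (YAML or JSON) with defaults for omitted fields.

    ``min_baseline_s`` is the longest baseline window any downstream analysis
    will carve out of the adaptation epoch; a config whose ``adaptation_s``
    cannot contain it is rejected.
    """
    path = Path(path)
    text = path.read_text()
    try:
        raw = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ProtocolError(f"cannot parse protocol config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ProtocolError(f"protocol config {path} must be a mapping")
    unknown = set(raw) - _PROTOCOL_FIELDS
    if unknown:
        raise ProtocolError(f"unknown protocol field(s): {sorted(unknown)}")
    if "epochs" in raw:
        raw["epochs"] = tuple(Epoch(**e) for e in raw["epochs"])
    try:
        proto = StimulusProtocol(**raw)
    except TypeError as exc:
        raise ProtocolError(str(exc)) from exc
    if proto.adaptation_s <= min_baseline_s:
        raise ProtocolError(
            f"adaptation_s ({proto.adaptation_s}) must exceed the downstream "
            f"baseline window ({min_baseline_s} s)"
        )
    return proto


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    path = Path(path)
    d = protocol.to_dict()
    if path.suffix in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True))
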