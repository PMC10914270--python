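"""Readers and writers for on-disk formats, plus ROI tiling of image stacks.

Formats
-------
Trace table
    CSV/TSV with header ``roi_id,trial,frame,value``; blank (background)
    regions are flagged by a ``blank_`` prefix on ``roi_id``.
Eye table
    CSV with header ``time_s,left_angle_deg,right_angle_deg``.
Image input
    Multi-frame grayscale TIFF (read via :mod:`tifffile`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .protocol import StimulusProtocol

__all__ = [
    "RoiTraceSet",
    "EyeTraceSet",
    "FormatError",
    "read_traces",
    "write_traces",
    "read_eye_traces",
    "write_eye_traces",
    "tile_rois",
]

BLANK_PREFIX = "blank_"


class FormatError(ValueError):
    """Raised when an input file violates the documented schema."""


@dataclass
class RoiTraceSet:
    """Raw fluorescence per (ROI, trial, frame), plus blank-region traces.

    ``F`` holds grayscale-mean fluorescence, shape ``(n_rois, n_trials,
    n_frames)``; ``blank`` holds the background-region traces used for
    background subtraction, shape ``(n_blank, n_trials, n_frames)``.  All
    ROIs share one frame grid registered to ``protocol``.
    """

    roi_ids: list[str]
    F: np.ndarray
    blank: np.ndarray | None = None
    protocol: StimulusProtocol | None = None
    roi_geometry: pd.DataFrame | None = None  # optional tile coords, um

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 3:
            raise FormatError("F must have shape (n_rois, n_trials, n_frames)")
        if len(self.roi_ids) != self.F.shape[0]:
            raise FormatError("roi_ids length must match F.shape[0]")
        if not np.all(np.isfinite(self.F)):
            raise FormatError("F contains non-finite values")
        if self.blank is not None:
            self.blank = np.asarray(self.blank, dtype=float)
            if self.blank.shape[1:] != self.F.shape[1:]:
                raise FormatError("blank traces must share the (trial, frame) grid of F")
            if not np.all(np.isfinite(self.blank)):
                raise FormatError("blank traces contain non-finite values")

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]

    @property
    def n_trials(self) -> int:
        return self.F.shape[1]

    @property
    def n_frames(self) -> int:
        return self.F.shape[2]


@dataclass
class EyeTraceSet:
    """Left/right eye visual-angle traces for the optokinetic reflex assay.

    The default record covers 5 s blank, 40 s grating, 5 s blank at 30 Hz;
    ``stimulus_window`` bounds the grating presentation in seconds.
    """

    time_s: np.ndarray
    left_angle_deg: np.ndarray
    right_angle_deg: np.ndarray
    sampling_hz: float = 30.0
    stimulus_window: tuple[float, float] = (5.0, 45.0)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.left_angle_deg = np.asarray(self.left_angle_deg, dtype=float)
        self.right_angle_deg = np.asarray(self.right_angle_deg, dtype=float)
        if not (self.time_s.shape == self.left_angle_deg.shape == self.right_angle_deg.shape):
            raise FormatError("time and angle arrays must share one shape")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise FormatError("time_s must be strictly increasing")
        for name, a in (("time_s", self.time_s),
                        ("left_angle_deg", self.left_angle_deg),
                        ("right_angle_deg", self.right_angle_deg)):
            if not np.all(np.isfinite(a)):
                raise FormatError(f"{name} contains non-finite values")

    def angle(self, eye: str) -> np.ndarray:
        if eye == "left":
            return self.left_angle_deg
        if eye == "right":
            return self.right_angle_deg
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")


# --------------------------------------------------------------------- #
# trace tables

_TRACE_COLUMNS = ["roi_id", "trial", "frame", "value"]


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_traces(path: str | Path, protocol: StimulusProtocol | None = None) -> RoiTraceSet:
    """Read a ``roi_id,trial,frame,value`` table into a :class:`RoiTraceSet`."""
    path = Path(path)
    df = _read_table(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df[["trial", "frame", "value"]].isna().any().any() or \
            not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise FormatError(f"{path}: NaN/inf in mandatory numeric columns")
    if df.duplicated(subset=["roi_id", "trial", "frame"]).any():
        raise FormatError(f"{path}: duplicated (roi_id, trial, frame) rows")

    trials = np.sort(df["trial"].unique())
    frames = np.sort(df["frame"].unique())
    if not np.array_equal(trials, np.arange(len(trials))) or \
            not np.array_equal(frames, np.arange(len(frames))):
        raise FormatError(f"{path}: trial/frame indices must form complete 0-based grids")

    wide = df.pivot_table(index="roi_id", columns=["trial", "frame"],
                          values="value", sort=False)
    if wide.isna().any().any():
        raise FormatError(f"{path}: incomplete (roi, trial, frame) grid")
    wide = wide.sort_index(axis=1)
    all_ids = list(wide.index)
    blank_ids = [r for r in all_ids if str(r).startswith(BLANK_PREFIX)]
    roi_ids = [r for r in all_ids if not str(r).startswith(BLANK_PREFIX)]
    cube = wide.to_numpy().reshape(len(all_ids), len(trials), len(frames))
    idx = {r: i for i, r in enumerate(all_ids)}
    F = cube[[idx[r] for r in roi_ids]]
    blank = cube[[idx[r] for r in blank_ids]] if blank_ids else None
    return RoiTraceSet(roi_ids=[str(r) for r in roi_ids], F=F, blank=blank,
                       protocol=protocol)


def write_traces(trace_set: RoiTraceSet, path: str | Path) -> None:
    """Write a :class:`RoiTraceSet` as a long-format trace table (round-trips
    with :func:`read_traces`)."""
    path = Path(path)
    n_rois, n_trials, n_frames = trace_set.F.shape
    blocks = [(trace_set.roi_ids, trace_set.F)]
    if trace_set.blank is not None:
        blank_ids = [f"{BLANK_PREFIX}{i}" for i in range(trace_set.blank.shape[0])]
        blocks.append((blank_ids, trace_set.blank))
    frames = []
    trial_col = np.repeat(np.arange(n_trials), n_frames)
    frame_col = np.tile(np.arange(n_frames), n_trials)
    for ids, cube in blocks:
        for i, rid in enumerate(ids):
            frames.append(pd.DataFrame({
                "roi_id": rid,
                "trial": trial_col,
                "frame": frame_col,
                "value": cube[i].ravel(),
            }))
    df = pd.concat(frames, ignore_index=True)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------- #
# eye tables

_EYE_COLUMNS = ["time_s", "left_angle_deg", "right_angle_deg"]


def read_eye_traces(path: str | Path,
                    stimulus_window: tuple[float, float] = (5.0, 45.0)) -> EyeTraceSet:
    path = Path(path)
    df = _read_table(path)
    missing = [c for c in _EYE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    arr = df[_EYE_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{path}: NaN/inf in mandatory numeric columns")
    t = arr[:, 0]
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time_s must be strictly increasing")
    dt = np.median(np.diff(t)) if t.size >= 2 else 1.0 / 30.0
    return EyeTraceSet(time_s=t, left_angle_deg=arr[:, 1], right_angle_deg=arr[:, 2],
                       sampling_hz=1.0 / dt, stimulus_window=stimulus_window)


def write_eye_traces(eyes: EyeTraceSet, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": eyes.time_s,
        "left_angle_deg": eyes.left_angle_deg,
        "right_angle_deg": eyes.right_angle_deg,
    }).to_csv(Path(path), index=False)


# --------------------------------------------------------------------- #
# ROI tiling

def tile_rois(
    stack: np.ndarray | str | Path,
    tile_size_um: float = 1.9,
    pixel_size_um: float = 0.636,
    mask: np.ndarray | None = None,
    min_coverage: float = 0.5,
    protocol: StimulusProtocol | None = None,
    n_trials: int = 1,
) -> RoiTraceSet:
    """Segment an image stack into non-overlapping square tile ROIs.

    Each tile's fluorescence trace is the mean grayscale within the tile per
    frame.  Tiles are laid on a regular grid from the image origin; edge
    tiles may be truncated.  Tiles whose masked-pixel fraction is below
    ``min_coverage`` are dropped.

    Parameters
    ----------
    stack
        Array of shape ``(n_frames, height, width)`` or path to a
        multi-frame grayscale TIFF.
    tile_size_um, pixel_size_um
        Tile edge and pixel pitch in micrometres; the tile edge in pixels is
        ``round(tile_size_um / pixel_size_um)`` and must be >= 1.
    mask
        Optional boolean (height, width) mask restricting tiling; default all
        pixels.
    n_trials
        The frame axis is split evenly into this many trials (frames must
        divide evenly).
    """
    if isinstance(stack, (str, Path)):
        stack = tifffile.imread(str(stack))
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError("stack must be (n_frames, height, width)")
    n_frames, h, w = stack.shape
    tile_px = int(round(tile_size_um / pixel_size_um))
    if tile_px < 1:
        raise ValueError(
            f"tile_size_um={tile_size_um} is below one pixel at "
            f"pixel_size_um={pixel_size_um}"
        )
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (h, w):
        raise FormatError("mask shape must match frame shape")
    if n_frames % n_trials != 0:
        raise FormatError(f"{n_frames} frames do not split into {n_trials} trials")

    roi_ids: list[str] = []
    traces: list[np.ndarray] = []
    geom: list[dict] = []
    for r0 in range(0, h, tile_px):
        for c0 in range(0, w, tile_px):
            r1, c1 = min(r0 + tile_px, h), min(c0 + tile_px, w)
            sub_mask = mask[r0:r1, c0:c1]
            coverage = sub_mask.mean()
            if coverage < min_coverage or not sub_mask.any():
                continue
            sub = stack[:, r0:r1, c0:c1]
            trace = sub[:, sub_mask].mean(axis=1)
            rid = f"tile_r{r0}_c{c0}"
            roi_ids.append(rid)
            traces.append(trace)
            geom.append({
                "roi_id": rid,
                "row_px": r0, "col_px": c0,
                "row_um": r0 * pixel_size_um, "col_um": c0 * pixel_size_um,
                "height_px": r1 - r0, "width_px": c1 - c0,
                "coverage": coverage,
            })
    F = np.stack(traces) if traces else np.empty((0, n_frames))
    F = F.reshape(len(roi_ids), n_trials, n_frames // n_trials)
    return RoiTraceSet(roi_ids=roi_ids, F=F, protocol=protocol,
                       roi_geometry=pd.DataFrame(geom))
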