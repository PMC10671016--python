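"""Baseline estimation and per-pixel dF/F0 % computation.

Normalisation follows the standard dF/F0 % = (F - F0) / F0 * 100 with a
per-pixel baseline F0, here the temporal mean over a pre-injection window
(default: the 15 min immediately before the injection).  Interval averaging
tiles time into end-labelled bins ((k-1)*w, k*w] anchored at the injection,
mirrored pre-injection, so "the 30-min mark" is the mean over (15, 30].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SessionRecording

__all__ = [
    "BaselineImage",
    "DffStack",
    "IntervalSeries",
    "subtract_background",
    "compute_f0",
    "compute_dff",
    "average_intervals",
    "bin_series",
    "whole_image_trace",
]

_LABEL_EPS = 1e-9  # tolerance when assigning frames to interval boundaries


@dataclass
class BaselineImage:
    """Per-pixel baseline fluorescence F0 and the window it came from.

    Pixels whose baseline mean is <= 0 (e.g. fully removed by background
    subtraction) are flagged invalid rather than clipped: dividing by a
    near-zero baseline would produce unbounded dF/F0.
    """

    f0: np.ndarray                 # (n_rows, n_cols) counts
    window: tuple[float, float]    # min
    valid: np.ndarray              # bool mask, True where f0 > 0


@dataclass
class DffStack:
    """Per-pixel dF/F0 time series, in percent.

    ``values`` is NaN wherever ``valid_mask`` is False; timestamps are
    inherited from the source recording.
    """

    values: np.ndarray            # (n_frames, n_rows, n_cols) percent
    timestamps: np.ndarray        # min
    valid_mask: np.ndarray        # (n_rows, n_cols) bool
    injection_time: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def frame_interval_min(self) -> float:
        if len(self.timestamps) > 1:
            return float(self.timestamps[1] - self.timestamps[0])
        return np.nan


@dataclass
class IntervalSeries:
    """Interval-averaged images and/or scalars, labelled by interval end time."""

    interval_width: float         # min
    labels: np.ndarray            # signed interval end-times, strictly increasing
    images: np.ndarray | None = None   # (n_intervals, n_rows, n_cols)
    values: np.ndarray | None = None   # (n_intervals,) trace mode


def subtract_background(recording: SessionRecording, background_level) -> SessionRecording:
    """Subtract a dark/background level (scalar or per-pixel), clipping at 0."""
    level = np.asarray(background_level, dtype=float)
    if level.ndim not in (0, 2):
        raise ValueError("background_level must be a scalar or a 2-D image")
    if level.ndim == 2 and level.shape != recording.geometry.shape:
        raise ValueError(
            f"background image shape {level.shape} does not match sensor "
            f"shape {recording.geometry.shape}")
    if np.any(level < 0):
        raise ValueError("background_level must be >= 0")
    if level.ndim == 0 and level == 0:
        return recording
    frames = np.clip(recording.frames - level, 0.0, None)
    return SessionRecording(frames=frames, timestamps=recording.timestamps,
                            geometry=recording.geometry,
                            injection_time=recording.injection_time,
                            label=recording.label)


def compute_f0(recording: SessionRecording, window: tuple[float, float],
               scalar: bool = False) -> BaselineImage:
    """Per-pixel mean over frames with timestamps in ``[start, end)``.

    The window must lie before the injection and contain at least one frame.
    ``scalar=True`` replaces the per-pixel baseline with one whole-image
    mean (every pixel normalised by the same F0).
    """
    start, end = window
    if end <= start:
        raise ValueError(f"empty baseline window ({start}, {end})")
    if end > recording.injection_time + _LABEL_EPS:
        raise ValueError(
            f"baseline window end ({end}) must not exceed the injection time "
            f"({recording.injection_time})")
    in_window = (recording.timestamps >= start) & (recording.timestamps < end)
    if not in_window.any():
        raise ValueError(f"no frames inside the baseline window ({start}, {end})")
    f0 = recording.frames[in_window].mean(axis=0)
    if scalar:
        f0 = np.full_like(f0, f0.mean())
    return BaselineImage(f0=f0, window=(float(start), float(end)), valid=f0 > 0)


def compute_dff(recording: SessionRecording, f0: BaselineImage) -> DffStack:
    """dF/F0 % = (F - F0) / F0 * 100 per pixel per frame."""
    if f0.f0.shape != recording.geometry.shape:
        raise ValueError(
            f"baseline shape {f0.f0.shape} does not match sensor shape "
            f"{recording.geometry.shape}")
    safe_f0 = np.where(f0.valid, f0.f0, 1.0)
    values = (recording.frames - f0.f0[None]) / safe_f0[None] * 100.0
    values[:, ~f0.valid] = np.nan
    return DffStack(values=values, timestamps=recording.timestamps.copy(),
                    valid_mask=f0.valid.copy(),
                    injection_time=recording.injection_time)


def _interval_index(timestamps: np.ndarray, width: float) -> np.ndarray:
    # frame t belongs to ((k-1)*w, k*w]; the nudge keeps exact multiples in bin k
    return np.ceil(timestamps / width - _LABEL_EPS).astype(int)


def bin_series(timestamps: np.ndarray, values: np.ndarray, width: float,
               frame_interval: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Average ``values`` (first axis = frames) into end-labelled intervals.

    Intervals tile time as ((k-1)*width, k*width] anchored at the injection
    (t = 0) and mirrored pre-injection.  A trailing interval that the
    recording does not fully cover is dropped; every returned interval
    averages at least one frame.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values)
    if width <= 0:
        raise ValueError("interval width must be > 0")
    if len(timestamps) == 0:
        raise ValueError("cannot bin an empty series")
    if frame_interval is None:
        frame_interval = float(np.median(np.diff(timestamps))) if len(timestamps) > 1 else width
    cover_start = timestamps[0] - frame_interval / 2.0
    cover_end = timestamps[-1] + frame_interval / 2.0
    if width > (cover_end - cover_start) + _LABEL_EPS:
        raise ValueError(
            f"interval width ({width}) exceeds the recording span "
            f"({cover_end - cover_start:g} min)")

    idx = _interval_index(timestamps, width)
    uniq = np.unique(idx)
    # drop the trailing interval if the recording stops before its end
    if uniq[-1] * width > cover_end + _LABEL_EPS:
        uniq = uniq[:-1]
    if len(uniq) == 0:
        raise ValueError("no complete interval inside the recording span")
    means = np.stack([values[idx == k].mean(axis=0) for k in uniq])
    labels = uniq.astype(float) * width
    return labels, means


def average_intervals(dff: DffStack, width: float, mode: str = "images") -> IntervalSeries:
    """Interval-average a dF/F0 stack.

    ``mode="images"`` returns one averaged frame per interval; ``mode="trace"``
    additionally averages over valid pixels, giving one scalar per interval.
    """
    if mode not in ("images", "trace"):
        raise ValueError(f"mode must be 'images' or 'trace', got {mode!r}")
    if dff.n_frames == 0:
        raise ValueError("empty dF/F0 stack")
    if mode == "trace":
        trace = whole_image_trace(dff)
        labels, means = bin_series(dff.timestamps, trace, width,
                                   frame_interval=dff.frame_interval_min)
        return IntervalSeries(interval_width=float(width), labels=labels,
                              values=means)
    labels, means = bin_series(dff.timestamps, dff.values, width,
                               frame_interval=dff.frame_interval_min)
    return IntervalSeries(interval_width=float(width), labels=labels,
                          images=means)


def whole_image_trace(dff: DffStack) -> np.ndarray:
    """Per-frame mean dF/F0 % over all valid pixels (the heatmap's "W" row)."""
    if not dff.valid_mask.any():
        raise ValueError("no valid pixels to average")
    return dff.values[:, dff.valid_mask].mean(axis=1)
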