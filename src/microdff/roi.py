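"""ROI detection by adaptive binarization + morphology, traces and profiles.

Detection runs frame by frame over the post-injection stack: each dF/F0
frame is thresholded against its local mean (adaptive binarization), the
binary map is cleaned by morphological opening then closing, and a per-pixel
occupancy map (fraction of frames active) is accumulated.  Pixels active in
at least ``occupancy_min`` of the frames form connected components, which
become the numbered ROIs after an area filter.  Because occupancy is a
fraction, the rule is frame-rate invariant.

Thresholding operates on dF/F0 frames rather than raw counts so ``offset``
has physical units (percent dF/F0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .dff import DffStack, bin_series, whole_image_trace

__all__ = [
    "RoiParams",
    "Roi",
    "RoiSet",
    "RoiTraceMatrix",
    "ProfileMetrics",
    "binarize_frame",
    "morph_clean",
    "detect_rois",
    "extract_traces",
    "profile_metrics",
]


@dataclass(frozen=True)
class RoiParams:
    """Tunable knobs of the detection pipeline.

    ``block_size`` is the (odd) side of the local-mean neighbourhood;
    ``offset`` (percent dF/F0) is added to the local mean to form the
    threshold; ``occupancy_min`` is the fraction of analysed frames a pixel
    must be active to enter an ROI.  ``max_area=None`` means a quarter of
    the frame, resolved at detection time.
    """

    block_size: int = 11
    offset: float = 1.0
    open_radius: int = 1
    close_radius: int = 1
    occupancy_min: float = 0.05
    min_area: int = 6
    max_area: int | None = None
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError(f"block_size must be odd and >= 3, got {self.block_size}")
        if not 0 <= self.occupancy_min <= 1:
            raise ValueError("occupancy_min must lie in [0, 1]")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_area is not None and self.max_area < self.min_area:
            raise ValueError("max_area must be >= min_area")
        if self.open_radius < 0 or self.close_radius < 0:
            raise ValueError("structuring radii must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class Roi:
    id: int                       # 1-based, raster order of centroids
    mask: np.ndarray              # (n_rows, n_cols) bool
    centroid: tuple[float, float]
    area: int

    def pixel_list(self) -> list[list[int]]:
        rr, cc = np.nonzero(self.mask)
        return [[int(r), int(c)] for r, c in zip(rr, cc)]


@dataclass
class RoiSet:
    rois: list[Roi]
    source_params: RoiParams

    def __len__(self) -> int:
        return len(self.rois)

    def label_image(self) -> np.ndarray:
        """0 = background, i = pixels of ROI i."""
        if not self.rois:
            raise ValueError("empty RoiSet has no label image shape")
        out = np.zeros(self.rois[0].mask.shape, dtype=int)
        for roi in self.rois:
            out[roi.mask] = roi.id
        return out

    def to_json_dict(self) -> dict:
        return {
            "params": {k: getattr(self.source_params, k)
                       for k in ("block_size", "offset", "open_radius",
                                 "close_radius", "occupancy_min", "min_area",
                                 "max_area", "connectivity")},
            "rois": [{"id": r.id, "centroid": [float(r.centroid[0]), float(r.centroid[1])],
                      "area": r.area, "pixels": r.pixel_list()}
                     for r in self.rois],
        }


@dataclass
class RoiTraceMatrix:
    """Interval-averaged dF/F0 % per ROI, plus a final whole-image "W" row."""

    row_ids: list[str]            # "1", "2", ..., "W"
    labels: np.ndarray            # interval end-times, min
    values: np.ndarray            # (n_rois + 1, n_intervals) percent

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=pd.Index(self.row_ids, name="roi_id"),
                            columns=pd.Index(self.labels, name="time_min"))


@dataclass
class ProfileMetrics:
    """Shape descriptors of a post-injection interval trace."""

    peak_label: float             # interval with the maximal value
    peak_value: float             # percent dF/F0
    time_to_half_rise: float      # first label reaching >= 50 % of the peak
    baseline_crossing: float | None  # first post-peak label <= 0
    undershoot_min: float         # minimal post-peak value


def _local_mean(frame: np.ndarray, valid: np.ndarray, block_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Masked local mean with edge-replicated padding (normalised convolution)."""
    filled = np.where(valid, frame, 0.0)
    num = ndimage.uniform_filter(filled, size=block_size, mode="nearest")
    den = ndimage.uniform_filter(valid.astype(float), size=block_size, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num / den
    return mean, den > 0


def binarize_frame(frame: np.ndarray, params: RoiParams,
                   valid: np.ndarray | None = None) -> np.ndarray:
    """Pixel active iff value > local_mean(block) + offset; invalid pixels inactive."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("binarize_frame expects a single 2-D frame")
    if params.block_size > min(frame.shape):
        raise ValueError(
            f"block_size ({params.block_size}) exceeds the image extent {frame.shape}")
    if valid is None:
        valid = np.isfinite(frame)
    mean, covered = _local_mean(frame, valid, params.block_size)
    with np.errstate(invalid="ignore"):
        active = np.where(valid & covered, frame > mean + params.offset, False)
    return active


def _footprint(radius: int) -> np.ndarray | None:
    return disk(radius) if radius > 0 else None


def morph_clean(binary: np.ndarray, params: RoiParams) -> np.ndarray:
    """Opening (radius ``open_radius``) then closing (``close_radius``).

    Outside the frame counts as inactive for the opening and for the closing
    dilation, and as active for the closing erosion (so closing never eats
    the border).  The combined open-close filter is idempotent.

    Accepts a 2-D image or a 3-D stack (frames cleaned independently).
    """
    binary = np.asarray(binary, dtype=bool)
    stacked = binary.ndim == 3
    fp_open = _footprint(params.open_radius)
    fp_close = _footprint(params.close_radius)
    out = binary
    if fp_open is not None:
        st = fp_open[None] if stacked else fp_open
        out = ndimage.binary_erosion(out, structure=st, border_value=0)
        out = ndimage.binary_dilation(out, structure=st, border_value=0)
    if fp_close is not None:
        st = fp_close[None] if stacked else fp_close
        out = ndimage.binary_dilation(out, structure=st, border_value=0)
        out = ndimage.binary_erosion(out, structure=st, border_value=1)
    return out


def occupancy_map(dff: DffStack, params: RoiParams,
                  average_width: float | None = None) -> np.ndarray:
    """Fraction of analysed post-injection frames in which each pixel is active."""
    post = dff.timestamps > dff.injection_time
    if not post.any():
        raise ValueError("no post-injection frames to analyse")
    if average_width is not None:
        from .dff import average_intervals
        series = average_intervals(
            DffStack(values=dff.values[post], timestamps=dff.timestamps[post],
                     valid_mask=dff.valid_mask, injection_time=dff.injection_time),
            average_width, mode="images")
        frames = series.images
    else:
        frames = dff.values[post]

    valid = dff.valid_mask
    filled = np.where(valid[None], frames, 0.0)
    num = ndimage.uniform_filter(filled, size=(1, params.block_size, params.block_size),
                                 mode="nearest")
    den = ndimage.uniform_filter(valid.astype(float), size=params.block_size,
                                 mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = num / den[None]
    active = np.where((valid & (den > 0))[None],
                      filled > mean + params.offset, False)
    cleaned = morph_clean(active, params)
    return cleaned.mean(axis=0)


def detect_rois(dff: DffStack, params: RoiParams | None = None,
                average_width: float | None = None) -> RoiSet:
    """Run the full detection pipeline on the post-injection stack.

    ``average_width`` switches the analysed frames from raw frames (default)
    to interval-averaged images of that width in minutes.
    """
    params = params or RoiParams()
    if dff.n_frames == 0:
        raise ValueError("empty dF/F0 stack")
    if params.block_size > min(dff.valid_mask.shape):
        raise ValueError(
            f"block_size ({params.block_size}) exceeds the image extent "
            f"{dff.valid_mask.shape}")
    occ = occupancy_map(dff, params, average_width=average_width)
    mask = occ >= params.occupancy_min
    labels = cc_label(mask, connectivity=2 if params.connectivity == 8 else 1)
    max_area = params.max_area
    if max_area is None:
        max_area = mask.size // 4

    candidates = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        area = int(m.sum())
        if not params.min_area <= area <= max_area:
            continue
        rr, cc = np.nonzero(m)
        candidates.append((float(rr.mean()), float(cc.mean()), m, area))
    candidates.sort(key=lambda t: (t[0], t[1]))
    rois = [Roi(id=i + 1, mask=m, centroid=(r, c), area=a)
            for i, (r, c, m, a) in enumerate(candidates)]
    return RoiSet(rois=rois, source_params=params)


def extract_traces(dff: DffStack, rois: RoiSet, interval_width: float) -> RoiTraceMatrix:
    """Per-ROI interval-averaged dF/F0 traces with the whole-image "W" row."""
    per_frame = []
    for roi in rois.rois:
        if roi.mask.shape != dff.valid_mask.shape:
            raise ValueError(f"ROI {roi.id} mask does not fit the frame")
        sel = roi.mask & dff.valid_mask
        if not sel.any():
            raise ValueError(f"ROI {roi.id} has an empty (or fully invalid) mask")
        per_frame.append(dff.values[:, sel].mean(axis=1))
    per_frame.append(whole_image_trace(dff))

    stacked = np.stack(per_frame, axis=1)   # (n_frames, n_rois + 1)
    labels, means = bin_series(dff.timestamps, stacked, interval_width,
                               frame_interval=dff.frame_interval_min)
    row_ids = [str(r.id) for r in rois.rois] + ["W"]
    return RoiTraceMatrix(row_ids=row_ids, labels=labels, values=means.T)


def profile_metrics(labels: np.ndarray, values: np.ndarray,
                    injection_time: float = 0.0) -> ProfileMetrics:
    """Peak, half-rise, zero-crossing and undershoot of an interval trace.

    Ties in the peak go to the earliest interval.  For an all-equal trace
    the half-rise degenerates to the first post-injection label.  If the
    peak is the final interval there is no post-peak span: the crossing is
    None and the undershoot equals the peak value.
    """
    labels = np.asarray(labels, dtype=float)
    values = np.asarray(values, dtype=float)
    post = labels > injection_time
    if post.sum() < 2:
        raise ValueError("need at least two post-injection intervals")
    lab, val = labels[post], values[post]
    i_peak = int(np.argmax(val))           # argmax takes the earliest tie
    peak_label, peak_value = float(lab[i_peak]), float(val[i_peak])

    half = 0.5 * peak_value
    reach = np.nonzero(val >= half)[0]
    half_rise = float(lab[reach[0]]) if len(reach) else float(lab[0])

    after = val[i_peak + 1:]
    after_lab = lab[i_peak + 1:]
    crossing = None
    if len(after):
        below = np.nonzero(after <= 0)[0]
        if len(below):
            crossing = float(after_lab[below[0]])
        undershoot = float(after.min())
    else:
        undershoot = peak_value
    return ProfileMetrics(peak_label=peak_label, peak_value=peak_value,
                          time_to_half_rise=half_rise,
                          baseline_crossing=crossing,
                          undershoot_min=undershoot)
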