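"""Reading angiogram recordings, flap ROI gridding, per-box series extraction and QC.

An angiogram recording is an ordered stack of 8-bit grayscale frames (grey
units, "g.u.", 0-255) acquired at a fixed frame rate.  The mastectomy flap is
annotated as a single region of interest (ROI) which is partitioned into
square analysis boxes (14x14 px by default); the mean intensity of each box's
in-ROI pixels over time is the fluorescence time series fed to milestone
extraction.

Quality control mirrors the exclusion criteria used when cleaning clinical
datasets: signal saturation, missed arterial inflow (no observable baseline
because recording started too late) and excessive camera motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage


class QFlapError(Exception):
    """Base class for qflap errors."""


class GeometryError(QFlapError):
    """Raised when frame/mask/grid geometries are inconsistent or degenerate."""


DEFAULT_FRAME_RATE = 30.0
DEFAULT_BOX_SIZE = 14


@dataclass
class FrameStack:
    """An angiogram video: frames indexed (t, row, col), values in g.u."""

    frames: np.ndarray  # (T, H, W), uint8 or float
    frame_rate: float = DEFAULT_FRAME_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise GeometryError(
                f"frame stack must be 3-D (T, H, W), got shape {self.frames.shape}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.frame_rate


@dataclass
class FlapROI:
    """Binary flap mask plus the breast's laterality ('left' or 'right')."""

    mask: np.ndarray
    laterality: str = "right"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise GeometryError("ROI mask must be 2-D")
        if not self.mask.any():
            raise GeometryError("ROI mask is empty")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        _, n_comp = ndimage.label(self.mask)
        if n_comp > 1:
            warnings.warn(
                f"ROI mask has {n_comp} connected components; expected a single flap",
                stacklevel=2,
            )

    @property
    def centroid(self) -> tuple[float, float]:
        """(row, col) centroid of the mask, in pixel coordinates."""
        r, c = ndimage.center_of_mass(self.mask)
        return float(r), float(c)


@dataclass(frozen=True)
class Box:
    """One analysis box: nominal extent [row0, row0+size) x [col0, col0+size)."""

    box_id: int
    row0: int
    col0: int
    size: int

    @property
    def center(self) -> tuple[float, float]:
        h = (self.size - 1) / 2.0
        return self.row0 + h, self.col0 + h


@dataclass
class BoxGrid:
    """The flap ROI partitioned into square analysis boxes.

    Column tiling is anchored at the *lateral* edge of the ROI bounding box
    (the image-left edge for a right breast viewed from the front, image-right
    for a left breast) so that mirroring the mask and toggling laterality maps
    boxes onto boxes exactly.  A box is kept iff the mask covers all pixels of
    its central block (the 2x2 central pixels for an even box size, the single
    centre pixel for an odd one).
    """

    box_size: int
    boxes: list[Box]
    centroid: tuple[float, float]
    mask_shape: tuple[int, int]
    laterality: str

    @property
    def box_ids(self) -> list[int]:
        return [b.box_id for b in self.boxes]

    def label_image(self, mask: np.ndarray) -> np.ndarray:
        """Map each in-ROI pixel to its box id + 1 (0 = unassigned/background)."""
        lab = np.zeros(self.mask_shape, dtype=np.int32)
        h, w = self.mask_shape
        for b in self.boxes:
            r0, r1 = max(b.row0, 0), min(b.row0 + self.box_size, h)
            c0, c1 = max(b.col0, 0), min(b.col0 + self.box_size, w)
            lab[r0:r1, c0:c1] = b.box_id + 1
        lab[~np.asarray(mask, dtype=bool)] = 0
        return lab


def _central_block(start: int, size: int) -> list[int]:
    if size % 2 == 0:
        return [start + size // 2 - 1, start + size // 2]
    return [start + (size - 1) // 2]


def build_box_grid(roi: FlapROI, box_size: int = DEFAULT_BOX_SIZE) -> BoxGrid:
    """Tile the ROI bounding box with square boxes and keep the in-ROI ones."""
    if box_size < 2:
        raise ValueError("box_size must be >= 2")
    mask = roi.mask
    rows, cols = np.nonzero(mask)
    rmin, rmax = int(rows.min()), int(rows.max())
    cmin, cmax = int(cols.min()), int(cols.max())
    bh, bw = rmax - rmin + 1, cmax - cmin + 1
    if bh < box_size or bw < box_size:
        raise GeometryError(
            f"ROI bounding box {bh}x{bw} is smaller than one {box_size}x{box_size} box"
        )
    n_rows = -(-bh // box_size)
    n_cols = -(-bw // box_size)
    row_starts = [rmin + i * box_size for i in range(n_rows)]
    if roi.laterality == "right":  # lateral edge = image left
        col_starts = [cmin + j * box_size for j in range(n_cols)]
    else:  # left breast: lateral edge = image right, tile leftward
        col_starts = [cmax - box_size + 1 - j * box_size for j in range(n_cols)]
    col_starts.sort()

    h, w = mask.shape
    boxes: list[Box] = []
    for r0 in row_starts:
        for c0 in col_starts:
            rc = _central_block(r0, box_size)
            cc = _central_block(c0, box_size)
            ok = all(
                0 <= r < h and 0 <= c < w and mask[r, c] for r in rc for c in cc
            )
            if ok:
                boxes.append(Box(len(boxes), r0, c0, box_size))
    if not boxes:
        raise GeometryError("no analysis box has its central block inside the ROI")
    return BoxGrid(
        box_size=box_size,
        boxes=boxes,
        centroid=roi.centroid,
        mask_shape=mask.shape,
        laterality=roi.laterality,
    )


# ---------------------------------------------------------------------------
# I/O


def write_frame_stack(path, stack: FrameStack) -> None:
    tifffile.imwrite(
        path,
        np.asarray(stack.frames),
        metadata={"frame_rate": stack.frame_rate, "start_time": stack.start_time},
    )


def read_frame_stack(path, frame_rate: float | None = None) -> FrameStack:
    """Read a multi-page grayscale TIFF, preserving intensities bit-exactly.

    The frame rate is taken from the TIFF metadata written by
    :func:`write_frame_stack` when present, else from ``frame_rate``, else the
    acquisition default of 30 fps.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            meta = tf.shaped_metadata
    except QFlapError:
        raise
    except Exception as exc:
        raise QFlapError(f"unreadable frame stack {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise GeometryError(f"unsupported stack shape {frames.shape} in {path}")
    fr = frame_rate
    start = 0.0
    if meta:
        fr = fr if fr is not None else meta[0].get("frame_rate")
        start = float(meta[0].get("start_time", 0.0))
    return FrameStack(frames, float(fr or DEFAULT_FRAME_RATE), start)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path, laterality: str = "right") -> FlapROI:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return FlapROI(arr > 0, laterality)


# ---------------------------------------------------------------------------
# Series extraction


def extract_box_series(stack: FrameStack, grid: BoxGrid, roi: FlapROI) -> pd.DataFrame:
    """Per-box mean fluorescence over time.

    Returns a DataFrame indexed by time (seconds) with one column per box id;
    each value is the mean over the box's in-ROI pixels in that frame.
    """
    if roi.mask.shape != stack.shape:
        raise GeometryError(
            f"mask shape {roi.mask.shape} does not match frames {stack.shape}"
        )
    if grid.mask_shape != stack.shape:
        raise GeometryError("grid was built for a different geometry")
    lab = grid.label_image(roi.mask).ravel()
    sel = lab > 0
    lab_sel = lab[sel]
    n_boxes = len(grid.boxes)
    counts = np.bincount(lab_sel, minlength=n_boxes + 1)[1:]
    frames = stack.frames.reshape(stack.n_frames, -1)
    out = np.empty((stack.n_frames, n_boxes))
    for t in range(stack.n_frames):
        sums = np.bincount(
            lab_sel, weights=frames[t, sel].astype(np.float64), minlength=n_boxes + 1
        )[1:]
        out[t] = sums / counts
    return pd.DataFrame(out, index=pd.Index(stack.times, name="time_s"),
                        columns=grid.box_ids)


# ---------------------------------------------------------------------------
# Quality control


@dataclass
class QCConfig:
    saturation_level: int = 254
    saturation_frac: float = 0.01
    missed_inflow_frac: float = 0.9
    missed_inflow_window_s: float = 1.0
    motion_threshold_px_s: float = 2.0
    motion_min_intensity: float = 10.0  # g.u.; frames below carry no signal


@dataclass
class QCReport:
    saturated: bool
    missed_inflow: bool
    excessive_motion: bool
    fraction_saturated_pixels: float
    motion_score: float

    @property
    def any_flag(self) -> bool:
        return self.saturated or self.missed_inflow or self.excessive_motion

    @property
    def reasons(self) -> list[str]:
        out = []
        if self.saturated:
            out.append("saturation")
        if self.missed_inflow:
            out.append("missed_inflow")
        if self.excessive_motion:
            out.append("excessive_motion")
        return out

    def to_dict(self) -> dict:
        return {
            "saturated": self.saturated,
            "missed_inflow": self.missed_inflow,
            "excessive_motion": self.excessive_motion,
            "fraction_saturated_pixels": self.fraction_saturated_pixels,
            "motion_score": self.motion_score,
        }


def qc_flags(stack: FrameStack, roi: FlapROI, config: QCConfig | None = None) -> QCReport:
    """Screen a recording for the failure modes that preclude quantification.

    saturated
        In some frame, more than ``saturation_frac`` of ROI pixels sit at or
        above ``saturation_level`` g.u. (the sensor ceiling region), so the
        dynamic signal is clipped.
    missed_inflow
        The ROI-mean series reaches >= ``missed_inflow_frac`` of its maximum
        within the first second: there is no observable pre-inflow baseline,
        i.e. the recording started after the arterial inflow.
    excessive_motion
        The intensity-weighted ROI centroid drifts faster than
        ``motion_threshold_px_s`` pixels/second on average.
    """
    cfg = config or QCConfig()
    if roi.mask.shape != stack.shape:
        raise GeometryError("mask does not match frame geometry")
    mask = roi.mask
    n_roi = int(mask.sum())
    frames = stack.frames

    roi_vals = frames[:, mask].astype(np.float64)  # (T, Nroi)
    sat_frac = (roi_vals >= cfg.saturation_level).sum(axis=1) / n_roi
    fraction_saturated = float(sat_frac.max())
    saturated = bool(fraction_saturated > cfg.saturation_frac)

    mean_series = roi_vals.mean(axis=1)
    n_win = max(1, int(round(cfg.missed_inflow_window_s * stack.frame_rate)))
    peak = mean_series.max()
    missed = bool(mean_series[:n_win].max() >= cfg.missed_inflow_frac * peak)

    rr, cc = np.nonzero(mask)
    w = roi_vals  # weights per ROI pixel
    tot = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cen_r = np.where(tot > 0, (w * rr).sum(axis=1) / tot, rr.mean())
        cen_c = np.where(tot > 0, (w * cc).sum(axis=1) / tot, cc.mean())
    # the intensity centroid is only localisable once fluorescence is present;
    # dark pre-inflow frames would contribute pure noise jitter
    bright = mean_series >= cfg.motion_min_intensity
    if bright.sum() > max(2, stack.frame_rate):
        # ~1 s trajectory smoothing suppresses residual sensor-noise jitter
        # of the centroid while camera wobble survives
        k = max(1, int(round(stack.frame_rate)))
        cr = ndimage.uniform_filter1d(cen_r[bright], k, mode="nearest")
        cc_ = ndimage.uniform_filter1d(cen_c[bright], k, mode="nearest")
        dt = np.diff(stack.times[bright])
        speed = np.hypot(np.diff(cr), np.diff(cc_)) / dt
        motion_score = float(speed.mean())  # px per second
    else:
        motion_score = 0.0
    excessive = bool(motion_score > cfg.motion_threshold_px_s)

    return QCReport(saturated, missed, excessive, fraction_saturated, motion_score)


# ---------------------------------------------------------------------------
# Outcomes

PRC_COMPONENTS = ("necrosis", "dehiscence", "infection", "implant_loss")
NON_PRC_OUTCOMES = ("haematoma", "seroma", "reoperation")
OUTCOME_FLAGS = PRC_COMPONENTS + NON_PRC_OUTCOMES


def derive_prc_label(flags: dict) -> bool:
    """Composite perfusion-related-complication label.

    True iff any of necrosis (partial or full thickness), wound dehiscence,
    infection or implant loss occurred.  Haematoma, seroma and reoperation are
    recorded but never contribute to the composite.
    """
    return any(bool(flags.get(k, False)) for k in PRC_COMPONENTS)


@dataclass
class CaseRecord:
    """One breast's metadata and outcomes."""

    case_id: str
    laterality: str
    arm: str  # IBR | delayed-first | delayed-second
    outcomes: dict = field(default_factory=dict)
    assessment: int = 1

    @property
    def prc(self) -> bool:
        return derive_prc_label(self.outcomes)
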