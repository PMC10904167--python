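"""Milestone heatmaps.

Any curve milestone can be rendered as a colour map, either at box
resolution (one cell per 14x14 analysis box) or at pixel resolution (the
milestone extractor run on every ROI pixel's own time series).  Brightness
milestones map larger values to the "better" (bright) end of the colour
scale; time milestones use a reversed scale so that *faster* perfusion also
maps to the better end.  Colour limits default to each map's own data range;
a fixed scale can be supplied for cross-case comparison, since per-image
ranges make visually similar maps incomparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ingest import BoxGrid, FlapROI, FrameStack, QFlapError
from .metrics import MILESTONE_COLUMNS, SmoothingConfig, extract_milestones_batch

#: metrics whose natural unit is seconds (smaller = better perfusion)
TIME_METRICS = {"latency", "peak_time", "T_max", "nT_max", "T50"}
METRIC_UNITS = {
    "latency": "s", "peak_time": "s", "T_max": "s", "nT_max": "s", "T50": "s",
    "F_max": "g.u.", "nF_max": "g.u.", "F50": "g.u.", "onset_value": "g.u.",
    "upslope": "g.u./s", "upslope50": "g.u./s",
}


class HeatmapError(QFlapError):
    pass


@dataclass
class MetricMap:
    """A 2-D field of one milestone's values; NaN marks invalid cells."""

    values: np.ndarray
    metric: str
    units: str
    resolution: str  # 'box' | 'pixel'
    vmin: float
    vmax: float
    n_positions: int = 0  # positions where extraction ran (incl. invalid)

    @property
    def n_evaluated(self) -> int:
        """Positions with a finite (valid) milestone value."""
        return int(np.isfinite(self.values).sum())


def _check_metric(metric: str) -> None:
    if metric not in MILESTONE_COLUMNS or metric == "valid":
        raise HeatmapError(f"unknown milestone {metric!r}")


def build_metric_map(
    milestones: pd.DataFrame, grid: BoxGrid, metric: str
) -> MetricMap:
    """Box-resolution map: one cell per grid box (NaN where no box)."""
    _check_metric(metric)
    boxes = grid.boxes
    r0s = sorted({b.row0 for b in boxes})
    c0s = sorted({b.col0 for b in boxes})
    ri = {r: i for i, r in enumerate(r0s)}
    ci = {c: j for j, c in enumerate(c0s)}
    arr = np.full((len(r0s), len(c0s)), np.nan)
    vals = milestones[metric].where(milestones["valid"].astype(bool), np.nan)
    for b in boxes:
        if b.box_id in vals.index:
            arr[ri[b.row0], ci[b.col0]] = vals.loc[b.box_id]
    finite = arr[np.isfinite(arr)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    return MetricMap(arr, metric, METRIC_UNITS.get(metric, ""), "box", vmin, vmax,
                     n_positions=len(boxes))


def pixel_metric_map(
    stack: FrameStack,
    roi: FlapROI,
    metric: str,
    config: SmoothingConfig | None = None,
    chunk: int = 20000,
) -> MetricMap:
    """Pixel-resolution map: the milestone extractor run per ROI pixel.

    Every in-ROI pixel's own time series is smoothed and summarised, so a
    frame of H x W pixels yields up to H*W evaluated positions.  Work is
    chunked over pixels to bound memory.
    """
    _check_metric(metric)
    mask = roi.mask
    if mask.shape != stack.shape:
        raise HeatmapError("mask does not match frame geometry")
    rr, cc = np.nonzero(mask)
    n_pix = len(rr)
    out = np.full(mask.shape, np.nan)
    frames = stack.frames.reshape(stack.n_frames, -1)
    flat_idx = rr * mask.shape[1] + cc
    for s in range(0, n_pix, chunk):
        sel = flat_idx[s:s + chunk]
        series = frames[:, sel].T.astype(np.float64)
        df = extract_milestones_batch(series, stack.frame_rate, config)
        vals = df[metric].where(df["valid"].astype(bool), np.nan).to_numpy()
        out[rr[s:s + chunk], cc[s:s + chunk]] = vals
    finite = out[np.isfinite(out)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    return MetricMap(out, metric, METRIC_UNITS.get(metric, ""), "pixel", vmin, vmax,
                     n_positions=n_pix)


def render_heatmap(
    metric_map: MetricMap,
    out_path,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
    sidecar_csv=None,
) -> None:
    """Write the map as a PNG with an annotated colourbar.

    Time-like metrics are drawn with the reversed colormap so that faster
    (smaller) values take the "better" colour end.  Invalid cells render in a
    dedicated no-data grey, never as a data colour.  If ``sidecar_csv`` is
    given the raw value matrix is written alongside, unrounded.
    """
    values = metric_map.values
    lo = metric_map.vmin if vmin is None else vmin
    hi = metric_map.vmax if vmax is None else vmax
    if not np.isfinite(lo) or not np.isfinite(hi):
        lo, hi = 0.0, 1.0
    if hi <= lo:  # degenerate range: pad so the single value is mid-scale
        eps = max(abs(lo) * 1e-3, 0.5)
        lo, hi = lo - eps, hi + eps
    cm = plt.get_cmap(cmap + "_r" if metric_map.metric in TIME_METRICS else cmap).copy()
    cm.set_bad("#bbbbbb")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.ma.masked_invalid(values), cmap=cm, vmin=lo, vmax=hi,
                   interpolation="nearest")
    unit = f" ({metric_map.units})" if metric_map.units else ""
    fig.colorbar(im, ax=ax, label=f"{metric_map.metric}{unit}")
    ax.set_title(f"{metric_map.metric}, {metric_map.resolution} resolution "
                 f"[{lo:.3g}, {hi:.3g}]")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    if sidecar_csv is not None:
        np.savetxt(sidecar_csv, values, delimiter=",", fmt="%.17g")


def read_sidecar(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
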