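"""Anatomical region assignment and per-region milestone aggregation.

Three segregation strategies are supported, matching how regional
fluorescence metrics are tabulated clinically:

quadrants
    upper/lower x inner/outer, split by horizontal and vertical lines through
    the ROI centroid.  "Inner" (medial) depends on laterality: for a right
    breast viewed from the front the medial side is at larger column indices,
    mirrored for a left breast.  Labels: UIQ, UOQ, LIQ, LOQ.
halves / thirds
    concentric rings.  Each box centre gets a normalised radial position
    u = (distance to centroid) / (distance from centroid to the ROI boundary
    along the same ray); the radius is bisected (inner/outer halves) or
    divided in three (inner/middle/outer thirds).

Boundary ties go to the inner/upper/medial label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ingest import BoxGrid, FlapROI, QFlapError

QUADRANT_LABELS = ("UIQ", "UOQ", "LIQ", "LOQ")
HALF_LABELS = ("inner", "outer")
THIRD_LABELS = ("inner", "middle", "outer")
WHOLE_BREAST = "whole_breast"

#: region columns reported in the results tables, in display order
REGION_ORDER = [
    WHOLE_BREAST, "LOQ", "LIQ", "UOQ", "UIQ",
    "inner_half", "outer_half", "inner_third", "middle_third", "outer_third",
]


class RegionError(QFlapError):
    pass


def assign_quadrants(grid: BoxGrid, laterality: str | None = None) -> pd.Series:
    """Quadrant label per box (index = box id)."""
    lat = laterality or grid.laterality
    if lat not in ("left", "right"):
        raise ValueError(f"unknown laterality {lat!r}")
    cen_r, cen_c = grid.centroid
    labels = {}
    for b in grid.boxes:
        r, c = b.center
        upper = r <= cen_r  # ties go up
        if lat == "right":
            inner = c >= cen_c  # medial = larger columns; ties go medial
        else:
            inner = c <= cen_c
        labels[b.box_id] = ("U" if upper else "L") + ("I" if inner else "O") + "Q"
    return pd.Series(labels, name="quadrant")


def _ray_boundary_distance(
    mask: np.ndarray, origin: np.ndarray, direction: np.ndarray, step: float = 0.25
) -> float:
    """Distance from origin to the first mask exit along ``direction``.

    Marches in sub-pixel steps with nearest-pixel sampling and returns the
    midpoint between the last inside and first outside sample.
    """
    h, w = mask.shape
    max_d = float(np.hypot(h, w)) + 1.0
    d = step
    last_inside = 0.0
    while d <= max_d:
        p = origin + d * direction
        r = int(np.round(p[0]))
        c = int(np.round(p[1]))
        if r < 0 or r >= h or c < 0 or c >= w or not mask[r, c]:
            return 0.5 * (last_inside + d)
        last_inside = d
        d += step
    return last_inside


def radial_positions(grid: BoxGrid, roi: FlapROI) -> pd.Series:
    """Normalised radial position u in [0, ~1] of each box centre."""
    mask = roi.mask
    cen = np.array(grid.centroid)
    ri, ci = int(np.round(cen[0])), int(np.round(cen[1]))
    if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1] and mask[ri, ci]):
        raise RegionError(
            "ROI centroid falls outside the mask (non-convex flap outline); "
            "concentric segregation is undefined for this geometry"
        )
    out = {}
    for b in grid.boxes:
        p = np.array(b.center)
        v = p - cen
        d = float(np.hypot(*v))
        if d == 0.0:
            out[b.box_id] = 0.0
            continue
        bd = _ray_boundary_distance(mask, cen, v / d)
        out[b.box_id] = d / bd if bd > 0 else np.inf
    return pd.Series(out, name="u")


def assign_concentric(grid: BoxGrid, roi: FlapROI, scheme: str) -> pd.Series:
    """Concentric-ring label per box: scheme 'halves' or 'thirds'."""
    u = radial_positions(grid, roi)
    if scheme == "halves":
        lab = np.where(u <= 0.5, "inner", "outer")
    elif scheme == "thirds":
        lab = np.where(u <= 1 / 3, "inner", np.where(u <= 2 / 3, "middle", "outer"))
    else:
        raise ValueError(f"unknown concentric scheme {scheme!r}")
    return pd.Series(lab, index=u.index, name=scheme[:-1] if scheme.endswith("s") else scheme)


def assign_all(grid: BoxGrid, roi: FlapROI) -> pd.DataFrame:
    """Region table: one row per box with quadrant, half and third labels."""
    df = pd.DataFrame(
        {
            "quadrant": assign_quadrants(grid),
            "half": assign_concentric(grid, roi, "halves"),
            "third": assign_concentric(grid, roi, "thirds"),
        }
    )
    df.index.name = "box_id"
    return df


def aggregate_region_metrics(
    milestones: pd.DataFrame, assignment: pd.DataFrame
) -> pd.DataFrame:
    """Unweighted mean of each milestone over the valid boxes of each region.

    ``milestones`` is indexed by box id (as from ``milestones_for_boxes``);
    ``assignment`` as from :func:`assign_all`.  Returns one row per region
    (whole breast first) with metric means and the member-box count
    ``n_boxes``; regions with no valid boxes yield NaN, not zero.
    """
    common = milestones.index.intersection(assignment.index)
    if len(common) == 0:
        raise RegionError("milestone table and region assignment share no box ids")
    mil = milestones.loc[common]
    asg = assignment.loc[common]
    valid = mil["valid"].astype(bool)
    vals = mil.loc[valid, mil.columns.drop("valid")]

    metric_cols = list(vals.columns)
    rows = {}

    def _region_row(sel_index) -> dict:
        sub = vals.loc[vals.index.intersection(sel_index)]
        row = {m: (sub[m].mean() if len(sub) else np.nan) for m in metric_cols}
        row["n_boxes"] = len(sub)
        return row

    rows[WHOLE_BREAST] = _region_row(vals.index)
    for q in QUADRANT_LABELS:
        rows[q] = _region_row(asg.index[asg["quadrant"] == q])
    for h in HALF_LABELS:
        rows[f"{h}_half"] = _region_row(asg.index[asg["half"] == h])
    for t in THIRD_LABELS:
        rows[f"{t}_third"] = _region_row(asg.index[asg["third"] == t])

    out = pd.DataFrame.from_dict(rows, orient="index").loc[REGION_ORDER]
    out.index.name = "region"
    return out


def case_feature_vector(region_metrics: pd.DataFrame,
                        metrics: list[str] | None = None) -> pd.Series:
    """Flatten a region-metrics table to one feature vector ('metric|region')."""
    cols = metrics or [c for c in region_metrics.columns if c != "n_boxes"]
    data = {}
    for region, row in region_metrics.iterrows():
        for m in cols:
            data[f"{m}|{region}"] = row[m]
    return pd.Series(data)
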