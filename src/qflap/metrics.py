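"""Perfusion curve milestones.

Each fluorescence time series is summarised by the standard inflow
milestones, in both raw (``n``-prefixed, non-smoothed) and Savitzky-Golay
smoothed variants:

latency
    time from recording start to inflow initiation.  Recordings begin when
    fluorescence is first detected, so the injection-to-onset interval is not
    observable; latency is measured from the start of the recording.
Fmax / nFmax
    peak brightness of the smoothed / raw series (g.u.).
Tmax / nTmax
    time from the end of latency to peak brightness (s); its chord gradient
    (Fmax - onset value) / Tmax is the ``upslope`` (g.u./s).
peak time
    time from recording start to peak brightness; equals latency + Tmax.
T50 / F50 / upslope50
    time from end of latency to the half-maximal rise, the intensity there,
    and the chord gradient up to that point.

Onset ("inflow initiation") is detected on the smoothed series: the baseline
is the median of the first 2 s, and onset is the first sample exceeding
baseline + max(3*MAD, 2 g.u.) that stays above threshold for at least 1 s.
If the series is already rising within the baseline window (missed baseline),
latency is 0.  Detected times are reported at frame resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .ingest import QFlapError


class MilestoneError(QFlapError):
    pass


@dataclass
class SmoothingConfig:
    """Savitzky-Golay smoothing and onset-detection parameters."""

    window_s: float = 1.0  # smoothing window; ~1 s removes sensor noise and
    # fine hand-held motion while preserving respiration-scale drift
    polyorder: int = 3
    baseline_window_s: float = 2.0
    onset_floor_gu: float = 2.0  # minimum rise over baseline to call onset
    onset_k_mad: float = 3.0
    persistence_s: float = 1.0

    def window_frames(self, frame_rate: float) -> int:
        w = int(round(self.window_s * frame_rate))
        if w % 2 == 0:
            w += 1
        return max(w, self.polyorder + 2 if (self.polyorder + 2) % 2 == 1 else self.polyorder + 3)


MILESTONE_COLUMNS = [
    "latency", "peak_time", "F_max", "nF_max", "T_max", "nT_max",
    "upslope", "T50", "F50", "upslope50", "onset_value", "valid",
]


@dataclass
class CurveMilestones:
    latency: float
    peak_time: float
    F_max: float
    nF_max: float
    T_max: float
    nT_max: float
    upslope: float
    T50: float
    F50: float
    upslope50: float
    onset_value: float
    valid: bool

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def smooth_series(values: np.ndarray, window: int, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay least-squares local-polynomial smoothing."""
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    return savgol_filter(values, window, polyorder, axis=-1)


def _first_sustained(above: np.ndarray, n_persist: int) -> np.ndarray:
    """Per row: first index where ``above`` holds for ``n_persist`` samples.

    Samples beyond the end of the series count as above, so a rise that
    starts near the end still registers.  Returns -1 where no such index.
    """
    n_rows, n = above.shape
    padded = np.concatenate(
        [above, np.ones((n_rows, n_persist - 1), dtype=bool)], axis=1
    ).astype(np.int32)
    c = np.cumsum(padded, axis=1)
    zero = np.zeros((n_rows, 1), dtype=np.int64)
    c = np.concatenate([zero, c], axis=1)
    win = c[:, n_persist:n_persist + n] - c[:, :n]  # count of above in [i, i+P)
    sustained = win == n_persist
    idx = np.argmax(sustained, axis=1)
    idx[~sustained.any(axis=1)] = -1
    return idx


def extract_milestones_batch(
    raw: np.ndarray,
    frame_rate: float,
    config: SmoothingConfig | None = None,
) -> pd.DataFrame:
    """Milestones for a batch of raw series (rows = curves, columns = frames).

    Invalid curves (no detectable onset, or a degenerate peak) have NaN
    milestones and ``valid`` False.
    """
    cfg = config or SmoothingConfig()
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    n_rows, n = raw.shape
    if n < 2 * int(cfg.baseline_window_s * frame_rate):
        raise MilestoneError("series shorter than twice the baseline window")

    w = cfg.window_frames(frame_rate)
    if w > n:
        raise MilestoneError(f"smoothing window {w} exceeds series length {n}")
    sm = savgol_filter(raw, w, cfg.polyorder, axis=1)

    nb = max(2, int(round(cfg.baseline_window_s * frame_rate)))
    base = np.median(sm[:, :nb], axis=1)
    mad = np.median(np.abs(sm[:, :nb] - base[:, None]), axis=1)
    thr = base + np.maximum(cfg.onset_k_mad * mad, cfg.onset_floor_gu)

    # no observable baseline: the series rises across the baseline window
    third = max(1, nb // 3)
    early = np.median(sm[:, :third], axis=1)
    late = np.median(sm[:, nb - third:nb], axis=1)
    no_baseline = (late - early) > cfg.onset_floor_gu

    n_persist = max(1, int(round(cfg.persistence_s * frame_rate)))
    onset_idx = _first_sustained(sm > thr[:, None], n_persist)
    onset_idx[no_baseline] = 0
    valid = onset_idx >= 0
    oi = np.where(valid, onset_idx, 0)

    rows = np.arange(n_rows)
    cols = np.arange(n)
    after_onset = cols[None, :] >= oi[:, None]

    sm_m = np.where(after_onset, sm, -np.inf)
    ipk = np.argmax(sm_m, axis=1)
    f_max = sm[rows, ipk]
    peak_time = ipk / frame_rate
    onset_value = sm[rows, oi]
    latency = oi / frame_rate
    t_max = peak_time - latency

    raw_m = np.where(after_onset, raw, -np.inf)
    nipk = np.argmax(raw_m, axis=1)
    nf_max = raw[rows, nipk]
    nt_max = nipk / frame_rate - latency

    # degenerate: no rise above onset, or instant peak
    valid &= f_max > onset_value
    level = onset_value + 0.5 * (f_max - onset_value)
    crossed = after_onset & (sm >= level[:, None])
    i50 = np.argmax(crossed, axis=1)
    has50 = crossed.any(axis=1)
    valid &= has50
    f50 = sm[rows, i50]
    t50 = i50 / frame_rate - latency

    with np.errstate(divide="ignore", invalid="ignore"):
        upslope = np.where(t_max > 0, (f_max - onset_value) / t_max, np.nan)
        upslope50 = np.where(t50 > 0, (f50 - onset_value) / t50, np.nan)
    valid &= t_max > 0

    out = pd.DataFrame(
        {
            "latency": latency,
            "peak_time": peak_time,
            "F_max": f_max,
            "nF_max": nf_max,
            "T_max": t_max,
            "nT_max": nt_max,
            "upslope": upslope,
            "T50": t50,
            "F50": f50,
            "upslope50": upslope50,
            "onset_value": onset_value,
            "valid": valid,
        }
    )
    num = out.columns.drop("valid")
    out.loc[~valid, num] = np.nan
    return out


def extract_milestones(
    raw_series: np.ndarray,
    frame_rate: float,
    config: SmoothingConfig | None = None,
) -> CurveMilestones:
    """Milestones for a single raw series."""
    df = extract_milestones_batch(np.asarray(raw_series)[None, :], frame_rate, config)
    row = df.iloc[0]
    return CurveMilestones(**{k: (bool(row[k]) if k == "valid" else float(row[k]))
                              for k in MILESTONE_COLUMNS})


def milestones_for_boxes(
    series: pd.DataFrame, frame_rate: float, config: SmoothingConfig | None = None
) -> pd.DataFrame:
    """Milestones for a box-series table (index time, columns box ids)."""
    out = extract_milestones_batch(series.to_numpy().T, frame_rate, config)
    out.index = pd.Index(series.columns, name="box_id")
    return out


def detect_onset(
    series: np.ndarray, frame_rate: float, config: SmoothingConfig | None = None
) -> tuple[float, float, bool]:
    """(latency_s, onset_value, valid) of a series, by the onset rule.

    The series is taken as already smoothed; only the threshold/persistence
    logic runs.  Used directly for diagnostics; the milestone extractor
    applies the same rule to the Savitzky-Golay smoothed series.
    """
    cfg = config or SmoothingConfig()
    x = np.atleast_2d(np.asarray(series, dtype=float))
    n = x.shape[1]
    nb = max(2, int(round(cfg.baseline_window_s * frame_rate)))
    if n < nb:
        raise MilestoneError("series shorter than the baseline window")
    base = np.median(x[:, :nb], axis=1)
    mad = np.median(np.abs(x[:, :nb] - base[:, None]), axis=1)
    thr = base + np.maximum(cfg.onset_k_mad * mad, cfg.onset_floor_gu)
    third = max(1, nb // 3)
    if np.median(x[0, nb - third:nb]) - np.median(x[0, :third]) > cfg.onset_floor_gu:
        return 0.0, float(x[0, 0]), True
    n_persist = max(1, int(round(cfg.persistence_s * frame_rate)))
    idx = _first_sustained(x > thr[:, None], n_persist)[0]
    if idx < 0:
        return float("nan"), float("nan"), False
    return idx / frame_rate, float(x[0, idx]), True


def baseline_intensity_rule(
    series: np.ndarray,
    frame_rate: float,
    t_eval: float = 90.0,
    threshold: float = 14.0,
) -> bool:
    """Intraoperative decision rule on absolute fluorescence intensity.

    Returns False (do not proceed with reconstruction) iff the intensity at
    ``t_eval`` seconds is strictly below ``threshold`` g.u.
    """
    x = np.asarray(series, dtype=float)
    idx = int(round(t_eval * frame_rate))
    if idx >= len(x):
        raise MilestoneError(
            f"series of {len(x)} frames does not cover t={t_eval} s at {frame_rate} fps"
        )
    return bool(x[idx] >= threshold)
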