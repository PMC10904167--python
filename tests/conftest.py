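"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive expected values by a different route
than the package: closed-form root finding on the continuous inflow curve,
explicit per-window least-squares polynomial smoothing, and plain-loop
milestone scanning.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

from qflap.metrics import SmoothingConfig


def smoothstep(u):
    u = min(max(u, 0.0), 1.0)
    return u * u * (3 - 2 * u)


def ideal_curve_fn(b, lat, rise, peak, w):
    """Continuous noiseless inflow curve as a scalar function of time."""

    def f(t):
        if t <= lat + rise:
            return b + (peak - b) * smoothstep((t - lat) / rise)
        return peak - w * (t - lat - rise)

    return f


def closed_form_milestones(b, lat, rise, peak, w, floor_gu=2.0):
    """Milestones of the documented extraction rules on the continuous curve.

    The onset rule's threshold on a noiseless series is baseline + floor
    (the MAD term vanishes); every crossing is found by root bracketing on
    the analytic curve, not by scanning samples.
    """
    f = ideal_curve_fn(b, lat, rise, peak, w)
    onset_level = b + floor_gu
    latency = brentq(lambda t: f(t) - onset_level, lat, lat + rise, xtol=1e-12)
    onset_value = onset_level
    f_max = peak
    peak_time = lat + rise  # argmax of the continuous curve
    t_max = peak_time - latency
    level50 = onset_value + 0.5 * (f_max - onset_value)
    t_cross = brentq(lambda t: f(t) - level50, latency, peak_time, xtol=1e-12)
    return {
        "latency": latency,
        "onset_value": onset_value,
        "F_max": f_max,
        "peak_time": peak_time,
        "T_max": t_max,
        "T50": t_cross - latency,
        "F50": level50,
        "upslope": (f_max - onset_value) / t_max,
        "nF_max": peak,
        "nT_max": peak_time - latency,
    }


def savgol_oracle(x: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Savitzky-Golay smoothing by explicit per-window least-squares fits.

    Interior point i: fit a degree-``polyorder`` polynomial to the window
    centred on i and evaluate at the centre.  Edges: fit one polynomial to
    the first (last) full window and evaluate it at the edge positions.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = window // 2
    out = np.empty(n)
    rel = np.arange(-h, h + 1)
    for i in range(h, n - h):
        coef = np.polyfit(rel, x[i - h:i + h + 1], polyorder)
        out[i] = np.polyval(coef, 0.0)
    head = np.polyfit(np.arange(window), x[:window], polyorder)
    for i in range(h):
        out[i] = np.polyval(head, i)
    tail = np.polyfit(np.arange(window), x[-window:], polyorder)
    for i in range(n - h, n):
        out[i] = np.polyval(tail, i - (n - window))
    return out


def milestones_oracle(raw: np.ndarray, frame_rate: float,
                      cfg: SmoothingConfig | None = None) -> dict:
    """Plain-loop implementation of the milestone extraction rules."""
    cfg = cfg or SmoothingConfig()
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    w = cfg.window_frames(frame_rate)
    sm = savgol_oracle(raw, w, cfg.polyorder)

    nb = max(2, int(round(cfg.baseline_window_s * frame_rate)))
    base = float(np.median(sm[:nb]))
    mad = float(np.median(np.abs(sm[:nb] - base)))
    thr = base + max(cfg.onset_k_mad * mad, cfg.onset_floor_gu)
    third = max(1, nb // 3)
    no_baseline = (np.median(sm[nb - third:nb]) - np.median(sm[:third])
                   ) > cfg.onset_floor_gu

    n_persist = max(1, int(round(cfg.persistence_s * frame_rate)))
    onset_idx = -1
    if no_baseline:
        onset_idx = 0
    else:
        for i in range(n):
            stop = min(i + n_persist, n)
            if all(sm[j] > thr for j in range(i, stop)):
                onset_idx = i
                break
    if onset_idx < 0:
        return {"valid": False}

    onset_value = sm[onset_idx]
    latency = onset_idx / frame_rate
    ipk = onset_idx
    for i in range(onset_idx, n):
        if sm[i] > sm[ipk]:
            ipk = i
    f_max = sm[ipk]
    if f_max <= onset_value:
        return {"valid": False}
    nipk = onset_idx
    for i in range(onset_idx, n):
        if raw[i] > raw[nipk]:
            nipk = i
    level = onset_value + 0.5 * (f_max - onset_value)
    i50 = None
    for i in range(onset_idx, n):
        if sm[i] >= level:
            i50 = i
            break
    if i50 is None:
        return {"valid": False}
    peak_time = ipk / frame_rate
    t_max = peak_time - latency
    t50 = i50 / frame_rate - latency
    return {
        "valid": t_max > 0,
        "latency": latency,
        "onset_value": onset_value,
        "F_max": f_max,
        "peak_time": peak_time,
        "T_max": t_max,
        "nF_max": raw[nipk],
        "nT_max": nipk / frame_rate - latency,
        "T50": t50,
        "F50": sm[i50],
        "upslope": (f_max - onset_value) / t_max if t_max > 0 else np.nan,
        "upslope50": (sm[i50] - onset_value) / t50 if t50 > 0 else np.nan,
    }


def disc_mask(height: int, width: int, radius: float,
              center: tuple[float, float] | None = None) -> np.ndarray:
    cy, cx = center or ((height - 1) / 2.0, (width - 1) / 2.0)
    rr, cc = np.mgrid[0:height, 0:width]
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2


def random_blob_mask(rng: np.random.Generator, height: int = 120,
                     width: int = 160, min_pixels: int = 2500) -> np.ndarray:
    """A single-component flap-like blob with its centroid inside the mask."""
    from scipy import ndimage

    for _ in range(100):
        field = ndimage.gaussian_filter(rng.normal(size=(height, width)), 12)
        mask = field > np.quantile(field, 0.6)
        lab, n = ndimage.label(mask)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + np.argmax(sizes))
        if mask.sum() < min_pixels:
            continue
        r, c = ndimage.center_of_mass(mask)
        if mask[int(np.round(r)), int(np.round(c))]:
            return mask
    raise RuntimeError("failed to draw a usable blob mask")


@pytest.fixture
def rng():
    return np.random.default_rng(20240126)
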