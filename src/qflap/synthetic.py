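"""Synthetic angiogram generation.

No clinical ICG angiography videos are publicly deposited, so every stage of
the pipeline is exercised on synthetic recordings whose statistical structure
matches the published cohort summaries: per-box bolus-inflow curves with
group-level means and SDs of peak brightness (Fmax), latency and rise time
taken from the reported whole-breast tables, a centre-brighter spatial
gradient, respiratory drift, sensor noise, and the artifact modes (signal
saturation, missed inflow, camera motion) that the clinical datasets were
screened for.

The inflow curve is a smoothstep ramp with linear washout::

    F(t) = b                                    t <  L
    F(t) = b + (P - b) * S((t - L) / R)         L <= t <= L + R
    F(t) = P - w * (t - L - R)                  t >  L + R

with S(u) = u^2 (3 - 2u), baseline ``b``, latency ``L`` (s), rise time ``R``
(s), peak ``P`` (g.u.) and washout rate ``w`` (g.u./s); intensities clip to
the 8-bit sensor range [0, 255].  The smoothstep is chosen because every
curve milestone then has a closed form, giving analytic oracles for the
extraction code.  ``R`` corresponds to the Tmax milestone (time from end of
latency to peak) and ``P`` to Fmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .ingest import (
    DEFAULT_BOX_SIZE,
    FlapROI,
    FrameStack,
    GeometryError,
    build_box_grid,
    write_frame_stack,
    write_mask,
)

SENSOR_MAX = 255.0


@dataclass
class InflowParams:
    """Parameters of one bolus-inflow curve (one box or one whole flap)."""

    baseline_b: float = 2.0  # pre-inflow intensity, g.u.
    latency_s: float = 15.0  # delay from recording start to inflow, s
    rise_time_s: float = 30.0  # inflow duration (end of latency to peak), s
    peak_f: float = 80.0  # peak brightness, g.u.
    washout_rate: float = 0.1  # linear post-peak decay, g.u./s
    noise_sd: float = 0.0  # additive white noise on the curve, g.u.
    drift_amp: float = 0.0  # respiratory artifact amplitude, g.u.
    drift_period_s: float = 4.0  # respiratory period, s

    def validate(self) -> None:
        if not (self.peak_f >= self.baseline_b >= 0):
            raise ValueError("require peak_f >= baseline_b >= 0")
        if self.latency_s < 0:
            raise ValueError("latency_s must be >= 0")
        if self.rise_time_s <= 0:
            raise ValueError("rise_time_s must be > 0")
        if self.washout_rate < 0:
            raise ValueError("washout_rate must be >= 0")
        if self.noise_sd < 0 or self.drift_amp < 0:
            raise ValueError("noise_sd and drift_amp must be >= 0")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be > 0")


def smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def inflow_curve_ideal(params: InflowParams, times: np.ndarray) -> np.ndarray:
    """Noiseless, unclipped inflow curve evaluated at ``times``."""
    t = np.asarray(times, dtype=float)
    b, lat, rise, peak, w = (
        params.baseline_b,
        params.latency_s,
        params.rise_time_s,
        params.peak_f,
        params.washout_rate,
    )
    vals = b + (peak - b) * smoothstep((t - lat) / rise)
    after = t > lat + rise
    vals[after] = peak - w * (t[after] - lat - rise)
    return vals


def generate_inflow_curve(
    params: InflowParams, times: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Inflow curve with drift and noise, clipped to the sensor range.

    ``times`` must be strictly increasing and uniformly spaced.  The same
    (params, times, seed) triple always yields the identical series.
    """
    params.validate()
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("times must be a 1-D array with at least 2 samples")
    dt = np.diff(t)
    if (dt <= 0).any() or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("times must be strictly increasing and uniformly spaced")
    vals = inflow_curve_ideal(params, t)
    if params.drift_amp > 0:
        vals = vals + params.drift_amp * np.sin(2 * np.pi * t / params.drift_period_s)
    if params.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, params.noise_sd, size=len(t))
    return np.clip(vals, 0.0, SENSOR_MAX)


# ---------------------------------------------------------------------------
# Cohort specification

#: Whole-breast group summaries (mean, SD) of the reported fluorescence
#: metrics, used as generator targets.  Keys of each inner dict: metric name.
WHOLE_BREAST_TARGETS = {
    # reconstructions without / with perfusion-related complications
    "no_prc": {"Fmax": (79.10, 37.47), "latency": (16.59, 8.49), "Tmax": (29.31, 14.01)},
    "prc": {"Fmax": (59.38, 25.47), "latency": (20.76, 11.31), "Tmax": (39.69, 20.47)},
    # immediate reconstruction vs delayed at the index procedure
    "ibr": {"Fmax": (73.61, 32.21), "latency": (17.80, 9.80), "Tmax": (34.43, 17.01)},
    "delayed_first": {"Fmax": (57.60, 23.79), "latency": (17.31, 6.99), "Tmax": (29.65, 12.83)},
    # delayed cases re-assessed one week later
    "delayed_second": {"Fmax": (109.28, 40.27), "latency": (15.22, 8.71), "Tmax": (21.43, 7.38)},
}

#: Full whole-breast metric summaries for the PRC comparison (mean, SD),
#: used when drawing per-case metric vectors directly (e.g. for classifier
#: studies that do not need rendered video).
PRC_METRIC_TABLE = {
    "no_prc": {
        "latency": (16.59, 8.49),
        "peak_time": (45.87, 17.90),
        "Fmax": (79.10, 37.47),
        "Tmax": (29.31, 14.01),
        "upslope": (3.57, 3.14),
        "nTmax": (40.11, 26.29),
        "nFmax": (72.57, 36.67),
    },
    "prc": {
        "latency": (20.76, 11.31),
        "peak_time": (58.84, 18.61),
        "Fmax": (59.38, 25.47),
        "Tmax": (39.69, 20.47),
        "upslope": (2.06, 2.03),
        "nTmax": (50.12, 26.79),
        "nFmax": (56.71, 24.57),
    },
}


@dataclass
class CohortSpec:
    """Generative description of one study group."""

    group: str
    n_cases: int = 10
    metrics: dict = field(default_factory=lambda: dict(WHOLE_BREAST_TARGETS["no_prc"]))
    prc: bool = False
    baseline_mean: float = 2.0
    baseline_sd: float = 1.0
    washout_rate: float = 0.1
    noise_sd: float = 2.0
    drift_amp: float = 1.0
    drift_period_s: float = 4.0
    centre_multiplier: float = 1.3  # centre-vs-periphery peak brightness ratio
    box_cv: float = 0.10  # per-box fractional parameter variation
    correlation_length: float = 2.0  # Gaussian smoothing of box draws, in boxes
    p_saturation: float = 0.0
    p_missed_inflow: float = 0.0
    p_motion: float = 0.0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for name, (m, s) in self.metrics.items():
            if s < 0:
                raise ValueError(f"negative SD for metric {name}")
        for p in (self.p_saturation, self.p_missed_inflow, self.p_motion):
            if not 0 <= p <= 1:
                raise ValueError("artifact probabilities must be in [0, 1]")


def prc_cohort_specs(n_no_prc: int = 103, n_prc: int = 13, **overrides) -> list[CohortSpec]:
    """The two-arm cohort matching the reported PRC / no-PRC group targets."""
    return [
        CohortSpec("no_prc", n_no_prc, dict(WHOLE_BREAST_TARGETS["no_prc"]),
                   prc=False, **overrides),
        CohortSpec("prc", n_prc, dict(WHOLE_BREAST_TARGETS["prc"]),
                   prc=True, **overrides),
    ]


@dataclass
class Geometry:
    """Acquisition geometry; defaults match the clinical recordings."""

    width: int = 1024
    height: int = 768
    frame_rate: float = 30.0
    duration_s: float = 90.0
    box_size: int = DEFAULT_BOX_SIZE

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class SyntheticCase:
    """One rendered recording plus its generating ground truth."""

    case_id: str
    stack: FrameStack
    roi: FlapROI
    truth: pd.DataFrame  # one row per box: generating InflowParams fields
    metadata: dict


def _ellipse_mask(height: int, width: int, fill: float = 0.84) -> np.ndarray:
    """Centred elliptical flap mask occupying ``fill`` of each dimension."""
    rr, cc = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry, rx = fill * height / 2.0, fill * width / 2.0
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Normal draw, redrawn (up to 100x) into [lo, hi], then clipped."""
    x = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
    return np.clip(x, lo, hi)


def _correlated_field(rng, n: int, sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially correlated draw along the box list.

    Boxes are ordered row-major, so 1-D Gaussian smoothing gives short-range
    correlation between neighbouring boxes; the field is re-standardised so
    the marginal variance stays 1.
    """
    z = rng.normal(0.0, 1.0, size=n)
    if sigma <= 0 or n < 3:
        return z
    f = ndimage.gaussian_filter1d(z, sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def draw_case_params(spec: CohortSpec, rng: np.random.Generator) -> InflowParams:
    """Draw one case's whole-flap inflow parameters from the group targets."""
    fm, fs = spec.metrics.get("Fmax", (80.0, 0.0))
    lm, ls = spec.metrics.get("latency", (15.0, 0.0))
    tm, ts = spec.metrics.get("Tmax", (30.0, 0.0))
    peak = float(_truncated_normal(rng, fm, fs, 10.0, 250.0))
    lat = float(_truncated_normal(rng, lm, ls, 0.0, 60.0))
    rise = float(_truncated_normal(rng, tm, ts, 3.0, 70.0))
    base = float(_truncated_normal(rng, spec.baseline_mean, spec.baseline_sd, 0.0, 10.0))
    base = min(base, peak - 1.0)
    return InflowParams(
        baseline_b=base,
        latency_s=lat,
        rise_time_s=rise,
        peak_f=peak,
        washout_rate=spec.washout_rate,
        noise_sd=spec.noise_sd,
        drift_amp=spec.drift_amp,
        drift_period_s=spec.drift_period_s,
    )


def draw_metric_table(spec: CohortSpec, rng: np.random.Generator,
                      metrics: dict | None = None) -> pd.DataFrame:
    """Per-case whole-breast metric vectors drawn from group (mean, SD) targets.

    Each metric is drawn independently; the implicit inter-metric correlation
    of rendered recordings is absent here.  Used for classifier studies.
    """
    targets = metrics or spec.metrics
    data = {
        name: rng.normal(m, s, size=spec.n_cases) for name, (m, s) in targets.items()
    }
    df = pd.DataFrame(data)
    df.insert(0, "group", spec.group)
    df["prc"] = spec.prc
    return df


def generate_case(
    spec: CohortSpec,
    case_index: int,
    seed: int,
    geometry: Geometry | None = None,
) -> SyntheticCase:
    """Render one synthetic recording.

    Per-box parameters are the case-level draw modulated by a centre-brighter
    radial gradient (peak only) and a spatially correlated fractional field;
    each box's in-ROI pixels carry its curve plus shared box noise plus
    independent pixel noise, quantised to 8 bits.  Identical (spec,
    case_index, seed) triples render bit-identical stacks.
    """
    spec.validate()
    geom = geometry or Geometry()
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(case_index,))
    rng = np.random.default_rng(ss)

    if geom.height < geom.box_size or geom.width < geom.box_size:
        raise GeometryError("frame geometry too small to contain one analysis box")

    laterality = "right" if case_index % 2 == 0 else "left"
    mask = _ellipse_mask(geom.height, geom.width)
    roi = FlapROI(mask, laterality)
    grid = build_box_grid(roi, geom.box_size)
    n_boxes = len(grid.boxes)

    case = draw_case_params(spec, rng)

    # artifact switches for this case
    saturated = bool(rng.random() < spec.p_saturation)
    missed = bool(rng.random() < spec.p_missed_inflow)
    motion = bool(rng.random() < spec.p_motion)

    centers = np.array([b.center for b in grid.boxes])
    cen = np.array(grid.centroid)
    d = np.hypot(centers[:, 0] - cen[0], centers[:, 1] - cen[1])
    u = d / d.max() if d.max() > 0 else d
    radial = 1.0 + (spec.centre_multiplier - 1.0) * (1.0 - u**2)
    radial /= radial.mean()  # keep the flap-mean peak at the case draw

    sig = spec.correlation_length
    peak_field = case.peak_f * radial * (1.0 + spec.box_cv * _correlated_field(rng, n_boxes, sig))
    lat_field = case.latency_s * (1.0 + 0.5 * spec.box_cv * _correlated_field(rng, n_boxes, sig))
    rise_field = case.rise_time_s * (1.0 + spec.box_cv * _correlated_field(rng, n_boxes, sig))

    peak_field = np.clip(peak_field, case.baseline_b + 1.0, 320.0)
    if not saturated:
        peak_field = np.minimum(peak_field, 250.0)
    lat_field = np.clip(lat_field, 0.0, geom.duration_s * 0.7)
    rise_field = np.clip(rise_field, 2.0, geom.duration_s * 0.8)

    if saturated:
        # push the central 10% of boxes beyond the sensor ceiling
        k = max(1, int(0.1 * n_boxes))
        peak_field[np.argsort(d)[:k]] = 300.0
    if missed:
        lat_field[:] = 0.0
        rise_field[:] = 0.5

    times = geom.times
    t_grid = times[None, :]
    base = case.baseline_b
    curves = base + (peak_field[:, None] - base) * smoothstep(
        (t_grid - lat_field[:, None]) / rise_field[:, None]
    )
    end = lat_field[:, None] + rise_field[:, None]
    after = t_grid > end
    washout = peak_field[:, None] - case.washout_rate * (t_grid - end)
    curves = np.where(after, washout, curves)
    if case.drift_amp > 0:
        curves = curves + case.drift_amp * np.sin(2 * np.pi * t_grid / case.drift_period_s)
    if case.noise_sd > 0:
        curves = curves + rng.normal(0.0, case.noise_sd, size=curves.shape)

    lab = grid.label_image(mask)
    n_frames = geom.n_frames
    frames = np.empty((n_frames, geom.height, geom.width), dtype=np.uint8)
    lut = np.zeros(n_boxes + 1)
    in_roi = lab > 0
    for t in range(n_frames):
        lut[1:] = curves[:, t]
        img = lut[lab]
        if case.noise_sd > 0:
            px = rng.normal(0.0, case.noise_sd, size=img.shape)
            img = img + np.where(in_roi, px, 0.0)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if motion:
        # hand-held camera wobble: slow sinusoidal whole-frame translation
        amp_px = max(4, int(0.04 * geom.width))
        period = 4.0
        for t in range(n_frames):
            dx = int(round(amp_px * np.sin(2 * np.pi * times[t] / period)))
            dy = int(round(0.6 * amp_px * np.cos(2 * np.pi * times[t] / period)))
            frames[t] = np.roll(np.roll(frames[t], dy, axis=0), dx, axis=1)

    truth = pd.DataFrame(
        {
            "box_id": grid.box_ids,
            "row0": [b.row0 for b in grid.boxes],
            "col0": [b.col0 for b in grid.boxes],
            "baseline_b": base,
            "latency_s": lat_field,
            "rise_time_s": rise_field,
            "peak_f": peak_field,
            "washout_rate": case.washout_rate,
        }
    )
    case_id = f"{spec.group}_{case_index:03d}"
    outcomes = _draw_outcomes(spec, rng)
    metadata = {
        "case_id": case_id,
        "group": spec.group,
        "laterality": laterality,
        "arm": spec.group,
        **outcomes,
        "prc": spec.prc,
        "artifact_saturation": saturated,
        "artifact_missed_inflow": missed,
        "artifact_motion": motion,
    }
    stack = FrameStack(frames, geom.frame_rate)
    return SyntheticCase(case_id, stack, roi, truth, metadata)


def _draw_outcomes(spec: CohortSpec, rng: np.random.Generator) -> dict:
    """Outcome flags consistent with the group's composite-PRC label.

    PRC cases receive at least one composite component (relative frequencies
    follow the reported component mix); non-PRC cases may still have the
    non-contributing complications (haematoma/seroma) at low rates.
    """
    flags = {k: False for k in
             ("necrosis", "dehiscence", "infection", "implant_loss",
              "haematoma", "seroma", "reoperation")}
    if spec.prc:
        components = ["necrosis", "infection", "dehiscence", "implant_loss"]
        probs = np.array([11.0, 7.0, 2.0, 4.0])
        probs = probs / probs.sum()
        primary = components[int(rng.choice(4, p=probs))]
        flags[primary] = True
        for c in components:  # occasional second component
            if c != primary and rng.random() < 0.15:
                flags[c] = True
        flags["reoperation"] = bool(rng.random() < 0.5)
        flags["seroma"] = bool(rng.random() < 0.3)
        flags["haematoma"] = bool(rng.random() < 0.15)
    else:
        flags["seroma"] = bool(rng.random() < 0.03)
        flags["haematoma"] = bool(rng.random() < 0.01)
    return flags


def generate_cohort(
    specs: list[CohortSpec],
    out_dir,
    seed: int = 0,
    geometry: Geometry | None = None,
) -> pd.DataFrame:
    """Render every case of every group and write the file set.

    Writes per case ``<case_id>.tif`` (frame stack), ``<case_id>_mask.png``
    and ``<case_id>_truth.csv``, plus one ``cohort.csv`` with metadata and
    outcome flags.  Returns the cohort table.
    """
    if not specs:
        raise ValueError("at least one cohort spec is required")
    for s in specs:
        s.validate()
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    offset = 0
    for spec in specs:
        for i in range(spec.n_cases):
            case = generate_case(spec, offset + i, seed, geometry)
            write_frame_stack(out / f"{case.case_id}.tif", case.stack)
            write_mask(out / f"{case.case_id}_mask.png", case.roi.mask)
            case.truth.to_csv(out / f"{case.case_id}_truth.csv", index=False)
            row = dict(case.metadata)
            row["stack"] = f"{case.case_id}.tif"
            row["mask"] = f"{case.case_id}_mask.png"
            row["truth"] = f"{case.case_id}_truth.csv"
            rows.append(row)
        offset += spec.n_cases
    table = pd.DataFrame(rows)
    table.to_csv(out / "cohort.csv", index=False)
    return table
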