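"""End-to-end pipeline: simulate -> QC/extract -> milestones -> regions -> stats -> train.

Stages hand data over as plain files (TIFF stacks, PNG masks, CSV tables,
JSON reports) so every intermediate is inspectable, and each run writes a
manifest recording the configuration hash, seeds, package version and any
QC exclusions with their reasons.  Re-running with the same configuration
and seed reproduces every numeric output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .heatmaps import build_metric_map, render_heatmap
from .ingest import (
    QCConfig,
    QFlapError,
    build_box_grid,
    extract_box_series,
    qc_flags,
    read_frame_stack,
    read_mask,
)
from .metrics import SmoothingConfig, milestones_for_boxes
from .model import rank_features, repeated_balanced_evaluation
from .regions import aggregate_region_metrics, assign_all, case_feature_vector
from .stats import GROUPINGS, build_results_tables, render_report
from .synthetic import CohortSpec, Geometry, WHOLE_BREAST_TARGETS, generate_cohort

log = logging.getLogger("qflap")

ALL_STAGES = ["simulate", "extract", "stats", "train", "heatmap"]


@dataclass
class RunConfig:
    out_dir: str = "qflap_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    geometry: Geometry = field(default_factory=Geometry)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    qc_auto_exclude: bool = True
    cohort: list = field(default_factory=list)  # list[CohortSpec]
    groupings: list = field(default_factory=lambda: ["prc"])
    n_repeats: int = 30
    model: str = "naive_bayes"
    heatmap_metric: str = "nF_max"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = Geometry(**d["geometry"])
        if "smoothing" in d:
            d["smoothing"] = SmoothingConfig(**d["smoothing"])
        if "qc" in d:
            d["qc"] = QCConfig(**d["qc"])
        specs = []
        for s in d.get("cohort", []):
            s = dict(s)
            targets = s.pop("targets", None)
            if targets is not None:
                s["metrics"] = dict(WHOLE_BREAST_TARGETS[targets])
            specs.append(CohortSpec(**s))
        d["cohort"] = specs
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_canonical_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in dependency order; return the manifest."""
    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise QFlapError(f"unknown stage {stage!r}")
    if "simulate" in config.stages and not config.cohort:
        raise QFlapError("empty cohort: the simulate stage needs at least one group spec")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw_dir = out / "raw"
    manifest: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": list(config.stages),
        "exclusions": [],
        "outputs": [],
        "notes": [],
    }

    def record(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(out)))
        return path

    if "simulate" in config.stages:
        log.info("stage=simulate groups=%d", len(config.cohort))
        table = generate_cohort(config.cohort, raw_dir, config.seed, config.geometry)
        record(raw_dir / "cohort.csv")
        log.info("stage=simulate cases=%d", len(table))

    cohort_csv = raw_dir / "cohort.csv"
    if "extract" in config.stages:
        if not cohort_csv.exists():
            raise QFlapError("extract stage requires raw/cohort.csv (run simulate first)")
        table = pd.read_csv(cohort_csv)
        feat_rows = []
        qc_rows = []
        for _, case in table.iterrows():
            cid = case["case_id"]
            stack = read_frame_stack(raw_dir / case["stack"],
                                     frame_rate=config.geometry.frame_rate)
            roi = read_mask(raw_dir / case["mask"], laterality=case["laterality"])
            report = qc_flags(stack, roi, config.qc)
            qc_rows.append({"case_id": cid, **report.to_dict()})
            if config.qc_auto_exclude and report.any_flag:
                reasons = ",".join(report.reasons)
                manifest["exclusions"].append({"case_id": cid, "reason": reasons})
                log.info("case=%s stage=qc outcome=excluded reason=%s", cid, reasons)
                continue
            grid = build_box_grid(roi, config.geometry.box_size)
            series = extract_box_series(stack, grid, roi)
            mil = milestones_for_boxes(series, stack.frame_rate, config.smoothing)
            asg = assign_all(grid, roi)
            reg = aggregate_region_metrics(mil, asg)
            feats = case_feature_vector(reg)
            meta = {k: case[k] for k in case.index if k not in ("stack", "mask", "truth")}
            feat_rows.append({**meta, **feats.to_dict()})
            log.info("case=%s stage=extract outcome=ok boxes=%d", cid, len(grid.boxes))
        if not feat_rows:
            raise QFlapError("no case survived QC; nothing to analyse")
        features = pd.DataFrame(feat_rows)
        features.to_csv(record(out / "features.csv"), index=False)
        pd.DataFrame(qc_rows).to_csv(record(out / "qc_report.csv"), index=False)

    features_csv = out / "features.csv"
    if "stats" in config.stages:
        if not features_csv.exists():
            raise QFlapError("stats stage requires features.csv (run extract first)")
        features = pd.read_csv(features_csv)
        tables_dir = out / "tables"
        tables_dir.mkdir(exist_ok=True)
        for grouping in config.groupings:
            col, v1, v2, _paired = GROUPINGS[grouping]
            if col == "prc":
                ok = features["prc"].nunique() == 2
            else:
                ok = {v1, v2} <= set(features[col])
            if not ok:
                manifest["notes"].append(f"grouping {grouping}: groups not present, skipped")
                continue
            tab = build_results_tables(features, grouping)
            tab.to_csv(record(tables_dir / f"{grouping}.csv"), index=False)
            (tables_dir / f"{grouping}.md").write_text(
                render_report(tab, f"Group comparison: {grouping}") + "\n")
            record(tables_dir / f"{grouping}.md")

    if "train" in config.stages:
        if not features_csv.exists():
            raise QFlapError("train stage requires features.csv (run extract first)")
        features = pd.read_csv(features_csv)
        y = features["prc"].astype(bool).astype(int).to_numpy()
        feat_cols = [c for c in features.columns if "|" in c]
        X = features[feat_cols]
        X = X.loc[:, X.notna().all() & (X.std() > 0)]
        if y.sum() < 2 or (1 - y).sum() < 2:
            manifest["notes"].append("train: fewer than 2 cases in a class, skipped")
        else:
            train_dir = out / "train"
            train_dir.mkdir(exist_ok=True)
            ranking = rank_features(X, y)
            ranking.to_csv(record(train_dir / "feature_ranking.csv"), index=False)
            reps = repeated_balanced_evaluation(
                X, y, n_repeats=config.n_repeats, model=config.model, seed=config.seed)
            reps.to_csv(record(train_dir / "repeats.csv"), index=False)
            summary = {
                "model": config.model,
                "n_repeats": config.n_repeats,
                "mean": reps[["sensitivity", "specificity", "ppv", "npv",
                              "accuracy", "auc"]].mean().to_dict(),
                "sd": reps[["sensitivity", "specificity", "ppv", "npv",
                            "accuracy", "auc"]].std().to_dict(),
            }
            _write_json(record(train_dir / "report.json"), summary)
            log.info("stage=train mean_auc=%.3f", summary["mean"]["auc"])

    if "heatmap" in config.stages:
        if not cohort_csv.exists():
            raise QFlapError("heatmap stage requires simulated cases")
        table = pd.read_csv(cohort_csv)
        excluded = {e["case_id"] for e in manifest["exclusions"]}
        keep = table[~table["case_id"].isin(excluded)]
        if len(keep) == 0:
            manifest["notes"].append("heatmap: no included case, skipped")
        else:
            case = keep.iloc[0]
            stack = read_frame_stack(raw_dir / case["stack"],
                                     frame_rate=config.geometry.frame_rate)
            roi = read_mask(raw_dir / case["mask"], laterality=case["laterality"])
            grid = build_box_grid(roi, config.geometry.box_size)
            series = extract_box_series(stack, grid, roi)
            mil = milestones_for_boxes(series, stack.frame_rate, config.smoothing)
            mmap = build_metric_map(mil, grid, config.heatmap_metric)
            hm_dir = out / "heatmaps"
            hm_dir.mkdir(exist_ok=True)
            name = f"{case['case_id']}_{config.heatmap_metric}"
            render_heatmap(mmap, hm_dir / f"{name}.png",
                           sidecar_csv=record(hm_dir / f"{name}.csv"))
            record(hm_dir / f"{name}.png")

    _write_json(out / "manifest.json", manifest)
    return manifest
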