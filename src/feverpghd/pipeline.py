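"""One-command pipeline: filter -> episodes -> cases -> AUC -> reports.

The pipeline either reads the three input CSVs or generates a synthetic
cohort, then applies child-level eligibility filters, segments fever
episodes, builds 72-hour antipyretic cases, computes baseline-anchored AUCs
for the two threshold populations, and renders descriptive and AUC
comparison reports. Every run writes a manifest with the seed, a config
hash, and row counts at each stage (an attrition flow).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .case_builder import attach_episodes, build_cases_from_frames, cases_to_frame
from .efficacy_stats import (
    STANDARD_HORIZONS,
    STANDARD_THRESHOLDS,
    case_table,
    compute_aucs,
    delta_curve,
    table1_report,
    table2_report,
)
from .episode_builder import (
    TemperatureSeries,
    detect_episodes,
    episodes_to_frame,
    to_hours,
)
from .io_model import Cohort, filter_children, read_cohort, write_cohort
from .synthetic_cohort import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; the defaults are the analysis' reference settings
    (38.0 C fever threshold, 38/39 C AUC populations, 6/8/10/12 h horizons,
    72 h case windows, 1 h baseline tolerance, equal-weight Cohen d)."""

    children_csv: str | None = None
    temperatures_csv: str | None = None
    antipyretics_csv: str | None = None
    simulate: SimulationConfig | None = None
    fever_threshold_c: float = 38.0
    auc_thresholds: tuple[float, ...] = STANDARD_THRESHOLDS
    horizons: tuple[int, ...] = STANDARD_HORIZONS
    window_h: float = 72.0
    baseline_tolerance_h: float = 1.0
    max_imputation_gap_h: float | None = None
    cohen_d_variant: str = "equal"
    out_dir: str = "runs/latest"
    seed: int = 0

    def validate(self) -> None:
        has_files = all([self.children_csv, self.temperatures_csv,
                         self.antipyretics_csv])
        if not has_files and self.simulate is None:
            raise ValueError("provide the three input CSVs or a simulate config")
        if self.cohen_d_variant not in ("equal", "pooled"):
            raise ValueError("cohen_d_variant must be 'equal' or 'pooled'")
        if self.window_h <= 0 or self.baseline_tolerance_h < 0:
            raise ValueError("window_h > 0 and baseline_tolerance_h >= 0 required")


def _config_hash(config: PipelineConfig) -> str:
    def default(o: Any):
        return getattr(o, "__dict__", str(o))
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunArtifacts:
    cohort: Cohort
    ground_truth: pd.DataFrame | None
    episodes: pd.DataFrame
    cases: list
    case_frame: pd.DataFrame
    auc: pd.DataFrame
    table1: dict
    table2: dict
    delta_curves: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig,
                 write: bool = True) -> RunArtifacts:
    """Execute all stages and (optionally) write the run artifacts.

    Artifacts: the canonical cohort CSVs (synthetic runs only), episodes.csv,
    cases.csv, auc.csv, delta_curves.csv, table1.json, table2.json and
    manifest.json under ``config.out_dir``.
    """
    config.validate()
    from . import __version__

    manifest: dict = {"feverpghd_version": __version__, "seed": config.seed,
                      "config_hash": _config_hash(config), "stages": {}}
    stages = manifest["stages"]

    ground_truth = None
    if config.simulate is not None:
        sim = config.simulate
        cohort, ground_truth = generate_cohort(sim)
        stages["simulated_children"] = int(cohort.n_children)
    else:
        cohort = read_cohort(config.children_csv, config.temperatures_csv,
                             config.antipyretics_csv)
        stages["rows_rejected"] = sum(cohort.read_report.n_rejected.values())
    stages["input_children"] = int(cohort.n_children)
    stages["input_temperature_records"] = int(len(cohort.temperatures))
    stages["input_antipyretic_records"] = int(len(cohort.antipyretics))

    cohort, filt = filter_children(cohort, config.fever_threshold_c)
    stages["excluded_children"] = dict(filt.first_reason)
    stages["retained_children"] = filt.n_retained
    stages["retained_temperature_records"] = int(len(cohort.temperatures))
    stages["retained_antipyretic_records"] = int(len(cohort.antipyretics))

    all_episodes = []
    episodes_by_child: dict[str, list] = {}
    for cid, grp in cohort.temperatures.groupby("child_id", sort=True):
        series = TemperatureSeries.from_frame(cid, grp)
        eps = detect_episodes(series, config.fever_threshold_c,
                              config.max_imputation_gap_h)
        all_episodes.extend(eps)
        keyed = []
        for e in eps:
            on_h = float(to_hours([e.onset_time])[0])
            off_h = (float(to_hours([e.offset_time])[0])
                     if e.offset_time is not None else None)
            keyed.append((e, (on_h, off_h)))
        episodes_by_child[cid] = keyed
    episodes = episodes_to_frame(all_episodes)
    stages["fever_episodes"] = int(len(episodes))

    cases, series_by_child = build_cases_from_frames(
        cohort.antipyretics, cohort.temperatures,
        window_h=config.window_h,
        baseline_tolerance_h=config.baseline_tolerance_h)
    attach_episodes(cases, episodes_by_child)
    stages["cases"] = len(cases)
    stages["cases_single"] = sum(c.group == "single" for c in cases)
    stages["cases_combination"] = sum(c.group == "combination" for c in cases)
    stages["cases_baseline_missing"] = sum(c.baseline_missing for c in cases)

    auc = compute_aucs(cases, series_by_child,
                       thresholds=config.auc_thresholds,
                       horizons=config.horizons)
    stages["auc_rows"] = int(len(auc))

    frame = case_table(cases, series_by_child, cohort.children)
    table1 = table1_report(frame, d_variant=config.cohen_d_variant)
    table2 = table2_report(auc, d_variant=config.cohen_d_variant)
    curves_group = delta_curve(cases, series_by_child, "group")
    curves_pattern = delta_curve(cases, series_by_child, "pattern")
    curves = pd.concat([curves_group, curves_pattern], ignore_index=True)

    artifacts = RunArtifacts(cohort, ground_truth, episodes, cases, frame,
                             auc, table1, table2, curves, manifest)
    if write:
        _write_artifacts(config, artifacts)
    return artifacts


def _write_artifacts(config: PipelineConfig, art: RunArtifacts) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        write_cohort(art.cohort, out / "children.csv",
                     out / "temperatures.csv", out / "antipyretics.csv")
        if art.ground_truth is not None and len(art.ground_truth):
            gt = art.ground_truth.drop(columns=["case_start_h"],
                                       errors="ignore")
            gt.to_csv(out / "ground_truth.csv", index=False,
                      lineterminator="\n", float_format="%.6f")
    ep = art.episodes.copy()
    for col in ("onset_time", "offset_time"):
        ep[col] = pd.to_datetime(ep[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    ep.to_csv(out / "episodes.csv", index=False, lineterminator="\n")
    cf = cases_to_frame(art.cases)
    cf["window_start"] = pd.to_datetime(
        cf["window_start"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    cf.to_csv(out / "cases.csv", index=False, lineterminator="\n")
    art.auc.to_csv(out / "auc.csv", index=False, lineterminator="\n",
                   float_format="%.6f")
    art.delta_curves.to_csv(out / "delta_curves.csv", index=False,
                            lineterminator="\n", float_format="%.6f")
    with open(out / "table1.json", "w", encoding="utf-8") as fh:
        json.dump(art.table1, fh, indent=2, default=_jsonable)
    with open(out / "table2.json", "w", encoding="utf-8") as fh:
        json.dump(art.table2, fh, indent=2, default=_jsonable)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(art.manifest, fh, indent=2, default=_jsonable)
    logger.info("artifacts written to %s", out)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
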