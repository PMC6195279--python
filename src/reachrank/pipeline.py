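"""End-to-end orchestration: simulate -> extract -> assemble -> fit -> rank.

Each stage reads and writes only the documented CSV/JSON artifacts in the
run's output directory, so stages can be re-run or replaced individually
(e.g. supplying a precomputed feature table and skipping kinematics).
A manifest records the configuration hash, seeds, and row/column counts
at every stage boundary; a rerun with the same configuration and seed is
byte-identical.

By default the outcome stage simulates changes in clinical score
(final minus baseline) from a sparse linear ground truth over the feature
table. Higher change = more improvement for an ability score; for a timed
score the sign is interpreted inversely (no sign flip is applied).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import reachrank

from . import io as rio
from .features import assemble_first_order, expand_second_order, summarize_subjects
from .kinematics import KinematicsConfig, extract_trial_metrics
from .models import repeated_cv_evaluate
from .ranking import plot_rank_chart, rank_features
from .simulate import (
    GroundTruth,
    SimConfig,
    noise_sd_for_signal_fraction,
    simulate_cohort,
    simulate_outcomes,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "assemble", "fit", "rank")

#: Default generating process: a handful of consequential covariates
#: spanning clinical state, demographics, and movement quality.
DEFAULT_TRUTH = {
    "initial_uefm": -3.0,
    "age": -2.0,
    "height": 2.0,
    "max_max_perpendicular_distance": -2.0,
    "mean_pre_movement_speed": -1.5,
}


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML-loadable)."""

    out_dir: str = "runs/run0"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    # outcome-generating process
    truth_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUTH)
    )
    truth_intercept: float = 2.0
    signal_fraction: float = 0.7
    # design options
    second_order: bool = False
    include_treatment: bool = False
    # model evaluation
    families: tuple[str, ...] = ("lasso",)
    enet_alpha: float = 0.5
    cv_k: int = 4
    cv_repeats: int = 100
    inner_k: int = 4
    n_lambdas: int = 100
    rf_trees: int = 500
    # ranking
    rank_repeats: int = 100
    rank_features_subset: tuple[str, ...] | None = None
    # external inputs for partially skipped runs
    feature_table_path: str | None = None
    outcomes_path: str | None = None
    trajectories_dir: str | None = None
    cohort_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        kin = KinematicsConfig(**raw.pop("kinematics", {}))
        for key in ("stages", "families", "rank_features_subset"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "n_submovements_range" in raw:
            raise ValueError("n_submovements_range belongs under 'sim:'")
        return cls(sim=sim, kinematics=kin, **raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """What a run did: enough to re-execute it bit-identically."""

    config_hash: str
    seed: int
    stages_run: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    warnings: int = 0
    failed_stage: str | None = None
    failure: str | None = None
    versions: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))
        tmp.replace(path)


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the enabled stages in order and write the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest = RunManifest(
        config_hash=chash,
        seed=cfg.seed,
        versions={
            "reachrank": reachrank.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )
    counter = _WarningCounter()
    logging.getLogger("reachrank").addHandler(counter)
    try:
        _run_stages(cfg, out, manifest)
    except Exception as exc:
        manifest.failed_stage = manifest.stages_run[-1] if manifest.stages_run else None
        manifest.failure = f"{type(exc).__name__}: {exc}"
        manifest.warnings = counter.count
        manifest.write(out / "manifest.json")
        raise
    finally:
        logging.getLogger("reachrank").removeHandler(counter)
    manifest.warnings = counter.count
    manifest.write(out / "manifest.json")
    return manifest


def _run_stages(cfg: RunConfig, out: Path, manifest: RunManifest) -> None:
    chash = manifest.config_hash
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)

    subjects = trajectories = None
    if "simulate" in cfg.stages:
        manifest.stages_run.append("simulate")
        subjects, trajectories = simulate_cohort(sim)
        rio.write_cohort(subjects, out / "cohort.csv")
        tdir = out / "trajectories"
        for traj in trajectories:
            rio.write_trajectory(traj, tdir)
        manifest.counts["subjects"] = len(subjects)
        manifest.counts["trajectories"] = len(trajectories)

    trial_metrics = None
    if "extract" in cfg.stages:
        manifest.stages_run.append("extract")
        if trajectories is None:
            tdir = Path(cfg.trajectories_dir or out / "trajectories")
            trajectories = [rio.read_trajectory(p) for p in sorted(tdir.glob("*.csv"))]
        rows = [extract_trial_metrics(t, cfg.kinematics).to_dict() for t in trajectories]
        trial_metrics = pd.DataFrame(rows)[list(rio.TRIAL_METRIC_COLUMNS)]
        rio.write_trial_metrics(trial_metrics, out / "trial_metrics.csv")
        manifest.counts["trial_metric_rows"] = len(trial_metrics)

    table = y = None
    if "assemble" in cfg.stages:
        manifest.stages_run.append("assemble")
        if trial_metrics is None:
            trial_metrics = rio.read_trial_metrics(out / "trial_metrics.csv")
        if subjects is None:
            subjects = rio.read_cohort(cfg.cohort_path or out / "cohort.csv")
        summaries = summarize_subjects(trial_metrics)
        table = assemble_first_order(summaries, subjects, cfg.include_treatment)
        rio.write_feature_table(table, out / "features_first_order.csv", chash)
        manifest.counts["feature_rows"] = table.shape[0]
        manifest.counts["feature_cols"] = table.shape[1]
        if cfg.second_order:
            table2 = expand_second_order(table)
            rio.write_feature_table(table2, out / "features_second_order.csv", chash)
            manifest.counts["feature_cols_second_order"] = table2.shape[1]
        if cfg.outcomes_path:
            y = rio.read_outcomes(cfg.outcomes_path)
        else:
            truth = GroundTruth(dict(cfg.truth_coefficients), cfg.truth_intercept, 0.0)
            truth.noise_sd = noise_sd_for_signal_fraction(
                table, truth, cfg.signal_fraction
            )
            y = simulate_outcomes(table, truth, seed=cfg.seed + 1)
            (out / "ground_truth.json").write_text(json.dumps(
                {"coefficients": truth.coefficients,
                 "intercept": truth.intercept, "noise_sd": truth.noise_sd},
                indent=1, sort_keys=True,
            ))
        rio.write_outcomes(y, out / "outcomes.csv")
        manifest.counts["outcomes"] = len(y)

    if table is None and set(cfg.stages) & {"fit", "rank"}:
        path = cfg.feature_table_path or out / "features_first_order.csv"
        table = rio.read_feature_table(path)
        y = rio.read_outcomes(cfg.outcomes_path or out / "outcomes.csv")
    if table is not None:
        y = y.loc[table.index]

    design = table
    if cfg.second_order and design is not None:
        design = expand_second_order(design)

    if "fit" in cfg.stages:
        manifest.stages_run.append("fit")
        summaries_json = {}
        for family in cfg.families:
            cv = repeated_cv_evaluate(
                design, y, family=family,
                alpha=cfg.enet_alpha if family == "enet" else None,
                k=cfg.cv_k, repeats=cfg.cv_repeats, master_seed=cfg.seed,
                inner_k=cfg.inner_k, n_lambdas=cfg.n_lambdas,
                rf_trees=cfg.rf_trees,
            )
            cv.to_frame().to_csv(out / f"cv_{family}.csv", index=False)
            summaries_json[family] = cv.summary()
        (out / "cv_summary.json").write_text(
            json.dumps(summaries_json, indent=1, sort_keys=True)
        )
        manifest.counts["cv_repeats"] = cfg.cv_repeats

    if "rank" in cfg.stages:
        manifest.stages_run.append("rank")
        subset = (list(cfg.rank_features_subset)
                  if cfg.rank_features_subset else None)
        rank_table, delta_long = rank_features(
            design, y, k=cfg.cv_k, repeats=cfg.rank_repeats,
            master_seed=cfg.seed, features=subset,
            inner_k=cfg.inner_k, n_lambdas=cfg.n_lambdas,
        )
        rank_table.to_csv(out / "rank_table.csv", index=False)
        delta_long.to_csv(out / "delta_distributions.csv", index=False)
        plot_rank_chart(
            rank_table, delta_long,
            rank_table.attrs["full_model_adj_r2_median"],
            path=str(out / "rank_chart.png"),
        )
        manifest.counts["rank_rows"] = len(rank_table)
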