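"""End-to-end orchestration: simulate -> align -> select -> train -> estimate
-> monitor -> compare, with persisted stage artifacts and one consolidated
report.

The default configuration reproduces the study design: a non-transfected
4-day batch triplicate for training and a transfected 4+5-day triplicate as
the external test set.  Every stage writes its inputs/outputs under the
output directory so any stage can be re-run from the persisted files, and
the structured report is byte-identical for a fixed master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .depletion import (
    CapacitanceConfig,
    DetectorConfig,
    capacitance_events_for_run,
    compare_indicators,
    monitor_run,
)
from .errors import VocSenseError
from .selection import SelectionConfig, run_selection
from .sensor import (
    DEFAULT_WINDOW,
    aggregate,
    aligned_training_data,
    estimate_run,
    evaluate_on_runs,
    loo_batch_cv,
    select_members,
)
from .simulate import SimulationConfig, save_truth, simulate_run
from .timeseries import CultivationRun, save_run

logger = logging.getLogger(__name__)


@dataclass
class SensorConfig:
    hidden_grid: tuple[tuple[int, ...], ...] = ((8,),)
    ensemble_size: int = 2
    window: int = DEFAULT_WINDOW
    n_restarts: int = 3
    max_iter: int = 300


@dataclass
class PipelineConfig:
    train_template: SimulationConfig = field(default_factory=SimulationConfig.batch)
    test_template: SimulationConfig = field(default_factory=SimulationConfig.transfected)
    n_train: int = 3
    n_test: int = 3
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    capacitance: CapacitanceConfig = field(default_factory=CapacitanceConfig)
    burst_channel: int = 45
    seed: int = 0

    def validate(self) -> None:
        if self.n_train < 2:
            raise VocSenseError("n_train: need >= 2 training runs for cross-validation")
        if self.n_test < 1:
            raise VocSenseError("n_test: need >= 1 test run")
        self.train_template.validate()
        self.test_template.validate()


def _config_digest(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items()}
        return str(o)

    blob = json.dumps(config, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    seed: int
    config_digest: str
    version: str
    selected_channels: list[int]
    n_step1: int
    n_step2: int
    n_step3: int
    cv_table: list[dict]
    best_hidden: list[int]
    train_nrmse_pct: float
    test_nrmse_pct: float
    benchmark_train_nrmse_pct: float
    benchmark_test_nrmse_pct: float
    indicator_table: list[dict]
    indicator_summary: list[dict]
    ensemble_size: int
    notes: list[str]

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True,
                       allow_nan=True, default=float) + "\n")
        lines = [
            f"vocsense pipeline report (seed {self.seed}, config {self.config_digest})",
            f"selected channels: {self.selected_channels} "
            f"(steps I-III kept {self.n_step1}/{self.n_step2}/{self.n_step3})",
            f"best architecture: {tuple(self.best_hidden)} hidden units",
            f"training NRMSE: {self.train_nrmse_pct:.1f} %",
            f"test NRMSE: {self.test_nrmse_pct:.1f} %",
            f"capacitance benchmark NRMSE (test runs): {self.benchmark_test_nrmse_pct:.1f} %",
        ]
        for note in self.notes:
            lines.append(f"note: {note}")
        (directory / "report.txt").write_text("\n".join(lines) + "\n")


def run_end_to_end(config: PipelineConfig, outdir) -> PipelineReport:
    """Run the whole workflow; persists all stage artifacts under ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []
    master = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in master.spawn(config.n_train + config.n_test + 1)]
    cv_seed = seeds[-1]

    stage = "simulate"
    try:
        train_runs: list[CultivationRun] = []
        test_runs: list[CultivationRun] = []
        for i in range(config.n_train):
            cfg = replace(config.train_template, seed=seeds[i])
            run, truth = simulate_run(cfg, run_id=f"train_{i + 1}")
            rundir = outdir / "runs" / run.run_id
            save_run(run, rundir)
            save_truth(truth, rundir / "truth")
            train_runs.append(run)
        for i in range(config.n_test):
            cfg = replace(config.test_template, seed=seeds[config.n_train + i])
            run, truth = simulate_run(cfg, run_id=f"test_{i + 1}")
            rundir = outdir / "runs" / run.run_id
            save_run(run, rundir)
            save_truth(truth, rundir / "truth")
            test_runs.append(run)

        stage = "select"
        report = run_selection(train_runs, config.selection)
        report.save(outdir / "selection")
        channels = report.step4_channels
        if not channels:
            raise VocSenseError("selection returned no channels")

        stage = "train"
        datasets = aligned_training_data(train_runs, channels)
        cv_results, best_hidden = loo_batch_cv(
            datasets, hidden_grid=config.sensor.hidden_grid, seed=cv_seed,
            channels=channels,
            n_restarts=config.sensor.n_restarts, max_iter=config.sensor.max_iter,
        )
        best_cv = next(r for r in cv_results if r.hidden == best_hidden)
        members = select_members(best_cv, k=config.sensor.ensemble_size)
        if len(members) == 1:
            notes.append("single-member ensemble: SD reported as 0 throughout")
        ensemble = aggregate(members, window=config.sensor.window)
        ensemble.save(outdir / "model")

        stage = "estimate"
        for run in train_runs + test_runs:
            est = estimate_run(ensemble, run)
            est.to_frame().to_csv(outdir / "runs" / run.run_id / "estimates.csv",
                                  index=False)
        train_eval = evaluate_on_runs(ensemble, train_runs)
        test_eval = evaluate_on_runs(ensemble, test_runs)
        train_eval.scatter.to_csv(outdir / "scatter_train.csv", index=False)
        test_eval.scatter.to_csv(outdir / "scatter_test.csv", index=False)

        stage = "monitor"
        per_run = []
        for run in train_runs + test_runs:
            events = monitor_run(run, config.burst_channel, config.detector)
            cap = capacitance_events_for_run(run, config.capacitance)
            per_run.append((run.run_id, events, cap))
        comparison = compare_indicators(per_run)
        comparison.table.to_csv(outdir / "indicator_comparison.csv", index=False)
        comparison.summary.to_csv(outdir / "indicator_summary.csv", index=False)
    except VocSenseError as err:
        raise VocSenseError(f"pipeline stage {stage!r} failed: {err}") from err

    cv_table = [
        {"hidden": list(r.hidden), "mean_val_nrmse": r.mean_val_nrmse,
         "folds": [{"held_out": f.held_out, "val_nrmse": f.val_nrmse,
                    "train_nrmse": f.train_nrmse} for f in r.folds]}
        for r in cv_results
    ]
    pipeline_report = PipelineReport(
        seed=config.seed,
        config_digest=_config_digest(config),
        version=__version__,
        selected_channels=[int(c) for c in channels],
        n_step1=len(report.step1_channels),
        n_step2=len(report.step2_channels),
        n_step3=sum(1 for n in report.step3_assignments.values()
                    if n != "unassigned/excluded"),
        cv_table=cv_table,
        best_hidden=list(best_hidden),
        train_nrmse_pct=train_eval.nrmse_pct,
        test_nrmse_pct=test_eval.nrmse_pct,
        benchmark_train_nrmse_pct=train_eval.benchmark_nrmse_pct,
        benchmark_test_nrmse_pct=test_eval.benchmark_nrmse_pct,
        indicator_table=json.loads(comparison.table.to_json(orient="records")),
        indicator_summary=json.loads(comparison.summary.to_json(orient="records")),
        ensemble_size=len(members),
        notes=notes,
    )
    pipeline_report.save(outdir)
    return pipeline_report
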