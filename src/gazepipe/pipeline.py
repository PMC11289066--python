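"""End-to-end driver: simulate/load -> preprocess -> exclude -> analyze.

A single :class:`PipelineConfig` governs a run; the effective configuration
is echoed into the :class:`RunReport` for provenance.  Outputs are plain
delimited text and JSON; log messages go to the logging system, never into
the machine-readable artifacts.  Given a fixed config (and seed, when
simulating) the machine-readable outputs are byte-identical across runs;
wall-clock time appears only in the human-readable log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import GazeDataset
from .exclusion import ExclusionCriteria, ExclusionReport, apply_exclusions
from .io import read_dataset, write_dataset
from .paradigms import (
    aggregate_participants,
    cascade_trial_results,
    compare_conditions,
    decision_locked_timecourse,
    novelty_trial_results,
    stimulus_locked_timecourse,
    vwp_trial_results,
)
from .preprocess import calibration_scores, correction_summary, preprocess_dataset
from .simulate import SimulationConfig, simulate_study
from . import stats as gstats

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "CHANCE_LEVEL", "STUDY_MODE"]

logger = logging.getLogger(__name__)

CHANCE_LEVEL = {"cascade": 0.5, "novelty": 0.5, "vwp": 0.25}
STUDY_MODE = {"cascade": "two_aoi", "novelty": "two_aoi", "vwp": "four_aoi"}
_DEFAULT_AXES = {"cascade": "x", "novelty": "x", "vwp": "xy"}


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    Either ``simulate`` (a :class:`SimulationConfig`) or ``input_dir``
    (tables written by :func:`gazepipe.io.write_dataset`) must be set.
    ``axes`` defaults to x-only correction for the two-AOI paradigms and
    two-axis correction for the four-quadrant paradigm.
    """

    paradigm: str = "cascade"
    simulate: Optional[SimulationConfig] = None
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None
    tail_fraction: float = 0.8
    axes: Optional[str] = None
    statistic: str = "mean"
    window_ms: float = 100.0
    bin_ms: float = 100.0
    span_ms: float = 2000.0
    vwp_latency_ms: float = 200.0
    vwp_window_ms: float = 400.0
    sensitivity_level: str = "base"
    criteria: ExclusionCriteria = field(default_factory=ExclusionCriteria)
    alpha: float = 0.05
    rscale: float = 0.707
    compute_bf: bool = True
    calibration_half_width_px: float = 200.0

    def __post_init__(self) -> None:
        if self.paradigm not in CHANCE_LEVEL:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.axes is None:
            self.axes = _DEFAULT_AXES[self.paradigm]
        if self.simulate is None and self.input_dir is None:
            self.simulate = SimulationConfig()

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            from .simulate import LabSpec, OffsetSpec

            sim = dict(sim)
            if "offset" in sim:
                sim["offset"] = OffsetSpec(**sim["offset"])
            if "lab" in sim:
                lab = dict(sim["lab"])
                if "offset" in lab:
                    lab["offset"] = OffsetSpec(**lab["offset"])
                sim["lab"] = LabSpec(**lab)
            sim = SimulationConfig(**sim)
        crit = raw.pop("criteria", None)
        if crit is not None:
            crit = ExclusionCriteria(**crit)
        kwargs = dict(raw)
        if sim is not None:
            kwargs["simulate"] = sim
        if crit is not None:
            kwargs["criteria"] = crit
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunReport:
    """Provenance and results of one pipeline run."""

    paradigm: str
    config: dict
    input_checksums: dict
    retention: pd.DataFrame
    sensitivity: pd.DataFrame
    bias_summary: pd.DataFrame
    sample_counts: dict
    results: dict
    trial_results: pd.DataFrame
    participant_summary: pd.DataFrame
    timecourse: Optional[pd.DataFrame]
    calibration: pd.DataFrame
    version: str
    wall_clock_s: float

    def to_json_dict(self) -> dict:
        """Deterministic machine-readable summary (no timestamps)."""
        return {
            "paradigm": self.paradigm,
            "version": self.version,
            "config": _jsonify(self.config),
            "input_checksums": self.input_checksums,
            "retention": self.retention.to_dict(orient="records"),
            "sensitivity": self.sensitivity.to_dict(orient="records"),
            "bias_summary": self.bias_summary.reset_index(names="axis").to_dict(orient="records"),
            "sample_counts": _jsonify(self.sample_counts),
            "results": _jsonify(self.results),
        }

    def summary_text(self) -> str:
        lines = [
            f"gazepipe {self.version} - paradigm: {self.paradigm}",
            f"wall clock: {self.wall_clock_s:.1f} s",
            "",
            "retention:",
            self.retention.to_string(index=False),
            "",
            "bias correction summary (|px|):",
            self.bias_summary.to_string(),
            "",
            "results:",
        ]
        for name, r in self.results.items():
            lines.append(f"  {name}: " + json.dumps(_jsonify(r), default=str))
        return "\n".join(lines) + "\n"


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _checksums(in_dir: Optional[str]) -> dict:
    if in_dir is None:
        return {}
    out = {}
    for p in sorted(Path(in_dir).glob("*.csv")):
        out[p.name] = hashlib.md5(p.read_bytes()).hexdigest()
    return out


def run_pipeline(config: PipelineConfig, dataset: Optional[GazeDataset] = None) -> RunReport:
    """Execute all stages and (optionally) write every intermediate table.

    A pre-built dataset can be passed directly to skip simulation/IO.  Any
    stage error propagates annotated with the stage name.
    """
    t_start = time.perf_counter()
    stage = "load"
    try:
        if dataset is not None:
            ds = dataset
        elif config.input_dir is not None:
            ds = read_dataset(config.input_dir, paradigm=config.paradigm)
        else:
            stage = "simulate"
            ds = simulate_study(config.paradigm, config.simulate)

        stage = "preprocess"
        pre = preprocess_dataset(
            ds, tail_fraction=config.tail_fraction, axes=config.axes,
            statistic=config.statistic,
        )
        bias_summary = correction_summary(pre.biases)

        stage = "exclude"
        gaze_f, report = apply_exclusions(
            pre,
            criteria=config.criteria,
            study_mode=STUDY_MODE[config.paradigm],
            sensitivity_level=config.sensitivity_level,
        )
        _, _, sens_table = _sensitivity_table(pre, config)

        stage = "analyze"
        chance = CHANCE_LEVEL[config.paradigm]
        retained_trials = ds.task_trials.merge(
            report.trials.loc[~report.trials["excluded"], ["participant_id", "trial_id"]],
            on=["participant_id", "trial_id"],
        )
        results: dict = {}
        timecourse = None
        if config.paradigm == "cascade":
            trial_res = cascade_trial_results(gaze_f, retained_trials, config.window_ms)
            summary = aggregate_participants(trial_res)
            timecourse = decision_locked_timecourse(
                gaze_f, retained_trials, config.bin_ms, config.span_ms
            ).to_frame()
        elif config.paradigm == "novelty":
            trial_res = novelty_trial_results(gaze_f, retained_trials)
            summary = aggregate_participants(trial_res)
        else:
            trial_res = vwp_trial_results(
                gaze_f, retained_trials, config.vwp_latency_ms, config.vwp_window_ms
            )
            summary = aggregate_participants(trial_res)
            timecourse = stimulus_locked_timecourse(
                gaze_f, retained_trials, config.bin_ms
            ).to_frame()

        stage = "stats"
        if config.paradigm == "vwp":
            online = summary[summary["condition"] == "online"]
            lab = summary[summary["condition"] == "lab"]
            if len(online) >= 2:
                results["online_vs_chance"] = gstats.one_sample_t(
                    online["mean_proportion"], mu0=chance, alternative="greater",
                    compute_bf=config.compute_bf, rscale=config.rscale,
                ).as_dict()
                results["group_mean_online"] = float(online["mean_proportion"].mean())
            if len(lab) >= 2:
                results["lab_vs_chance"] = gstats.one_sample_t(
                    lab["mean_proportion"], mu0=chance, alternative="greater",
                    compute_bf=config.compute_bf, rscale=config.rscale,
                ).as_dict()
                results["group_mean_lab"] = float(lab["mean_proportion"].mean())
            both = set(online["participant_id"]) & set(lab["participant_id"])
            if len(both) >= 2:
                comp = compare_conditions(
                    online[online["participant_id"].isin(both)],
                    lab[lab["participant_id"].isin(both)],
                    chance=chance, compute_bf=config.compute_bf, rscale=config.rscale,
                )
                results["lab_vs_online"] = {
                    **comp.result.as_dict(),
                    "numerator_ratio": comp.numerator_ratio,
                    "sd_ratio": comp.sd_ratio,
                    "n_pairs": comp.n_pairs,
                }
        else:
            if len(summary) >= 2:
                results["group_vs_chance"] = gstats.one_sample_t(
                    summary["mean_proportion"], mu0=chance, alternative="greater",
                    compute_bf=config.compute_bf, rscale=config.rscale,
                ).as_dict()
            results["group_mean"] = float(summary["mean_proportion"].mean())

        stage = "calibration"
        cal = calibration_scores(ds, half_width_px=config.calibration_half_width_px)
        if len(cal) and len(summary) >= 3:
            cal_cond = cal[cal["condition"] == "online"] if "condition" in cal else cal
            eff = summary[summary.get("condition", "online") == "online"] if "condition" in summary else summary
            merged = cal_cond.merge(eff, on="participant_id", how="inner")
            if len(merged) >= 3 and merged["calibration_score"].std() > 0 and merged["mean_proportion"].std() > 0:
                r, p = gstats.pearson_r(
                    merged["calibration_score"], merged["mean_proportion"]
                )
                results["calibration_effect_correlation"] = {"r": r, "p": p, "n": len(merged)}
            results["mean_calibration_score"] = {
                str(c): float(g["calibration_score"].mean())
                for c, g in cal.groupby("condition")
            }

        report_obj = RunReport(
            paradigm=config.paradigm,
            config=config.to_dict(),
            input_checksums=_checksums(config.input_dir),
            retention=report.retention,
            sensitivity=sens_table,
            bias_summary=bias_summary,
            sample_counts=report.sample_counts,
            results=results,
            trial_results=trial_res,
            participant_summary=summary,
            timecourse=timecourse,
            calibration=cal,
            version=__version__,
            wall_clock_s=time.perf_counter() - t_start,
        )

        stage = "write"
        if config.output_dir is not None:
            _write_outputs(config, ds, report_obj, report)
        return report_obj
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e


def _sensitivity_table(pre, config):
    from .exclusion import sensitivity_filter

    return sensitivity_filter(pre, config.sensitivity_level, config.criteria)


def _write_outputs(config, ds, report_obj: RunReport, excl: ExclusionReport) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(ds, out / "dataset")
    report_obj.trial_results.to_csv(out / "trial_results.csv", index=False)
    report_obj.participant_summary.to_csv(out / "participant_summary.csv", index=False)
    if report_obj.timecourse is not None:
        report_obj.timecourse.to_csv(out / "timecourse.csv", index=False)
    excl.participants.to_csv(out / "exclusion_participants.csv", index=False)
    excl.trials.to_csv(out / "exclusion_trials.csv", index=False)
    report_obj.retention.to_csv(out / "retention.csv", index=False)
    report_obj.bias_summary.to_csv(out / "bias_summary.csv")
    if len(report_obj.calibration):
        report_obj.calibration.to_csv(out / "calibration_scores.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(report_obj.to_json_dict(), indent=2, sort_keys=True, default=str) + "\n"
    )
    (out / "report.txt").write_text(report_obj.summary_text())
    logger.info("outputs written to %s", out)
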