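"""CSV input/output and run configuration.

All tabular I/O is plain CSV; configs and filter reports are JSON.  Every
output directory carries the exact configuration and seed that produced it,
so a run can be reproduced bit-identically from its own outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .data import FitConfig, ModelFit, SchemaError, TaskDataset

__all__ = ["StudyConfig", "read_trials_csv", "write_fit", "write_truth"]

MANDATORY = ("participant_id", "trial_label", "rt_ms")


class StudyConfig(BaseModel):
    """Per-task analysis configuration, serialised alongside every output."""

    task_name: str = "task"
    mode: Literal["binary", "continuous"] = "binary"
    label_spec: Optional[list[str]] = None
    rt_low_ms: float = Field(default=200.0, gt=0)
    rt_high_ms: float = Field(default=60000.0, gt=0)
    span_cap: Optional[float] = None
    max_iter: int = Field(default=10, ge=1)
    tol: float = Field(default=1e-6, gt=0)
    seed: int = 0
    outdir: Optional[str] = None

    @field_validator("rt_high_ms")
    @classmethod
    def _order(cls, v, info):
        low = info.data.get("rt_low_ms")
        if low is not None and v <= low:
            raise ValueError("rt_high_ms must exceed rt_low_ms")
        return v

    def fit_config(self) -> FitConfig:
        return FitConfig(max_iter=self.max_iter, tol=self.tol)

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


def read_trials_csv(path: str | Path,
                    config: StudyConfig | None = None) -> TaskDataset:
    """Read a long-format trial table into a validated TaskDataset.

    Required columns: participant_id, trial_label, rt_ms and (per mode)
    correct or acc.  An explicit ``order`` column is preferred; otherwise
    file row order within each participant is used.  Empty cells are
    missing values — no numeric sentinels.
    """
    config = config or StudyConfig()
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    if "correct" in df.columns and df["correct"].dtype == object:
        df["correct"] = df["correct"].map(
            {"True": True, "False": False, True: True, False: False})
    return TaskDataset(df, mode=config.mode)


def write_trials_csv(dataset: TaskDataset, path: str | Path) -> None:
    cols = ["participant_id", "trial_label", "rt_ms", "correct", "acc",
            "order", "timepoint"]
    out = dataset.records[[c for c in cols if c in dataset.records.columns]]
    out.to_csv(path, index=False)


def write_fit(fit: ModelFit, outdir: str | Path,
              config: StudyConfig | None = None) -> dict[str, Path]:
    """Write a fitted model: per-participant estimates, per-label difficulty
    scale, iteration traces and the run config.  Column order is fixed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    parts = fit.participants.reset_index()
    parts = parts[["participant_id", "a", "as_", "dt", "dt_max", "q"]]
    paths["participants"] = outdir / "participants.csv"
    parts.to_csv(paths["participants"], index=False, float_format="%.12g")

    diff = fit.difficulty.as_frame()
    paths["difficulty"] = outdir / "difficulty.csv"
    diff.to_csv(paths["difficulty"], index=False, float_format="%.12g")

    trace = pd.DataFrame({
        "stage": (["difficulty"] * len(fit.difficulty.trace)
                  + ["ability"] * len(fit.ability_trace)),
        "iteration": (list(range(1, len(fit.difficulty.trace) + 1))
                      + list(range(1, len(fit.ability_trace) + 1))),
        "mean_abs_change": np.concatenate(
            [fit.difficulty.trace, fit.ability_trace]),
    })
    paths["trace"] = outdir / "trace.csv"
    trace.to_csv(paths["trace"], index=False, float_format="%.12g")

    summary = {
        "mode": fit.mode,
        "rt_max": fit.rt_max,
        "at_max": fit.at_max,
        "difficulty_n_iter": fit.difficulty.n_iter,
        "difficulty_converged": fit.difficulty.converged,
        "ability_n_iter": fit.ability_n_iter,
        "ability_converged": fit.ability_converged,
        "max_iter": fit.config.max_iter,
        "tol": fit.config.tol,
    }
    paths["summary"] = outdir / "fit_summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")
    if config is not None:
        paths["config"] = outdir / "config.json"
        config.to_json(paths["config"])
    return paths


def read_fit_participants(outdir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "participants.csv",
                       index_col="participant_id")


def read_fit_difficulty(outdir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "difficulty.csv",
                       index_col="trial_label")


def write_truth(truth, outdir: str | Path) -> dict[str, Path]:
    """Write simulation ground truth: per-participant ability/delay and
    per-label difficulty."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    pt = pd.DataFrame({"true_ability": truth.true_ability,
                       "true_delay_ms": truth.true_delay})
    paths["truth_participants"] = outdir / "truth_participants.csv"
    pt.to_csv(paths["truth_participants"], float_format="%.12g")
    paths["truth_difficulty"] = outdir / "truth_difficulty.csv"
    truth.true_difficulty.to_frame().to_csv(
        paths["truth_difficulty"], float_format="%.12g")
    return paths
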