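"""Core containers for trial-level task data and model output.

A task dataset is a long-format table with one row per trial presentation:
``participant_id``, ``trial_label`` (the task's difficulty-dimension
descriptor, e.g. the word shown, or the span length), ``rt_ms`` (reaction
time in milliseconds), a score column (``correct`` for binary-accuracy
tasks, ``acc`` in [0, 1] for graded-accuracy tasks), a ``timepoint`` and a
per-participant presentation ``order``.  All model arithmetic is done on
float64 views of this table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

Mode = Literal["binary", "continuous"]

#: Mandatory columns of a trial-level table, in canonical output order.
TRIAL_COLUMNS = ("participant_id", "trial_label", "rt_ms", "correct", "acc",
                 "order", "timepoint")


class SchemaError(ValueError):
    """Raised when a trial-level table violates the input contract."""


@dataclass
class TaskDataset:
    """All retained trial presentations of one task plus the RT scaling constant.

    Parameters
    ----------
    records
        Long-format trial table.  Required columns: ``participant_id``,
        ``trial_label``, ``rt_ms`` and, depending on ``mode``, ``correct``
        (binary) or ``acc`` (continuous).  ``order`` defaults to row order
        within each participant; ``timepoint`` defaults to 1.
    mode
        ``"binary"`` scores each trial right/wrong; ``"continuous"`` uses a
        graded accuracy in [0, 1].

    The global scaling constant ``rt_max`` (maximum RT across all trials and
    all participants) is computed on construction.  ``at_max`` is populated
    by the model after the ability stage.
    """

    records: pd.DataFrame
    mode: Mode = "binary"
    rt_max: float = field(init=False)
    at_max: float | None = field(default=None, init=False)

    def __post_init__(self) -> None:
        df = self.records
        if self.mode not in ("binary", "continuous"):
            raise SchemaError(f"unknown accuracy mode {self.mode!r}")
        for col in ("participant_id", "trial_label", "rt_ms"):
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        score_col = "correct" if self.mode == "binary" else "acc"
        if score_col not in df.columns or df[score_col].isna().all():
            raise SchemaError(
                f"mode {self.mode!r} requires a populated {score_col!r} column")
        if len(df) == 0:
            raise SchemaError("empty dataset")

        df = df.copy()
        df["rt_ms"] = df["rt_ms"].astype(float)
        if not np.all(df["rt_ms"].to_numpy() > 0):
            raise SchemaError("rt_ms must be strictly positive")
        if self.mode == "continuous":
            acc = df["acc"].astype(float).to_numpy()
            if np.any(np.isnan(acc)):
                raise SchemaError("continuous mode: acc missing on some rows")
            if acc.min() < 0 or acc.max() > 1:
                raise SchemaError("acc must lie in [0, 1]")
        else:
            if df["correct"].isna().any():
                raise SchemaError("binary mode: correct missing on some rows")
            df["correct"] = df["correct"].astype(bool)
        if "timepoint" not in df.columns:
            df["timepoint"] = 1
        if "order" not in df.columns or df["order"].isna().all():
            # row order within participant is the documented fallback
            df["order"] = df.groupby("participant_id", sort=False).cumcount()
        else:
            dup = df.duplicated(subset=["participant_id", "order"])
            if dup.any():
                raise SchemaError("order must be unique within a participant")
        self.records = df
        self.rt_max = float(df["rt_ms"].max())

    @property
    def n_participants(self) -> int:
        return self.records["participant_id"].nunique()

    @property
    def n_labels(self) -> int:
        return self.records["trial_label"].nunique()

    def score_values(self) -> np.ndarray:
        """Per-row accuracy in [0, 1]: the 0/1 correctness indicator in
        binary mode, the graded score in continuous mode."""
        if self.mode == "binary":
            return self.records["correct"].to_numpy(dtype=float)
        return self.records["acc"].to_numpy(dtype=float)


@dataclass
class FitConfig:
    """Fixed-point iteration controls.

    ``max_iter`` defaults to the ten-iteration depth at which the procedure
    is reported to converge on population-scale data; ``tol`` is the mean
    absolute between-iteration change below which a stage is declared
    converged early.
    """

    max_iter: int = 10
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class DifficultyScale:
    """Per-trial-label difficulty estimates with the iteration trace.

    ``d`` is the unscaled data-driven difficulty in (0, 1]; ``ds`` is the
    ability-scaled difficulty (populated by the scaling stage); ``trace``
    holds the mean absolute change in ``d`` at each iteration.
    """

    labels: np.ndarray
    d: np.ndarray
    trace: np.ndarray
    n_iter: int
    converged: bool
    presentation_counts: np.ndarray
    ds: np.ndarray | None = None

    @property
    def d_map(self) -> dict:
        return dict(zip(self.labels.tolist(), self.d.tolist()))

    @property
    def ds_map(self) -> dict:
        if self.ds is None:
            raise ValueError("scaled difficulty not computed yet")
        return dict(zip(self.labels.tolist(), self.ds.tolist()))

    def as_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "trial_label": self.labels,
            "d": self.d,
            "ds": self.ds if self.ds is not None else np.nan,
            "n_presentations": self.presentation_counts,
        })
        return out

    def iterations_to(self, threshold: float) -> int | None:
        """First iteration (1-based) at which mean |ΔD| drops below
        ``threshold``, or None if it never does within the recorded trace."""
        hit = np.nonzero(np.asarray(self.trace) < threshold)[0]
        return int(hit[0]) + 1 if hit.size else None


@dataclass
class AbilityEstimates:
    """Output of the answer-time/delay-time stage (plus the AS stage).

    ``participants`` is indexed by participant_id with columns
    ``a`` (ability), ``as_`` (specific ability; NaN until the AS stage),
    ``dt`` (delay time, ms), ``dt_max`` (the participant's minimum RT, ms)
    and ``q`` (retained trial count).  ``at`` holds the per-presentation
    answer times aligned with the model's internal record order.
    """

    participants: pd.DataFrame
    at: np.ndarray
    at_max: float
    trace: np.ndarray
    n_iter: int
    converged: bool

    def iterations_to(self, threshold: float) -> int | None:
        hit = np.nonzero(np.asarray(self.trace) < threshold)[0]
        return int(hit[0]) + 1 if hit.size else None


@dataclass
class ModelFit:
    """Complete decomposition of one task dataset.

    The four headline estimates: per-label difficulty ``difficulty.d`` and
    scaled difficulty ``difficulty.ds``; per-participant specific ability
    ``participants['as_']`` and delay time ``participants['dt']``.
    """

    difficulty: DifficultyScale
    participants: pd.DataFrame
    at_max: float
    ability_trace: np.ndarray
    ability_n_iter: int
    ability_converged: bool
    config: FitConfig
    mode: Mode
    rt_max: float
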