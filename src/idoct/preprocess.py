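"""Cleaning rules applied to raw trial-level records before fitting.

Three filters: implausibly fast or slow reaction times (signs of cheating or
disengagement), participants who completed the same task at more than one
timepoint (dropped to avoid learning-curve contamination), and span-type
trials above the task's maximum target length (a sign of writing the
sequence down).  Filters are idempotent and commute, and every filter
returns a report whose counts reconcile with the output size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


@dataclass
class FilterReport:
    n_input: int = 0
    n_output: int = 0
    n_removed_fast: int = 0
    n_removed_slow: int = 0
    n_participants_dropped_repeat: int = 0
    n_removed_repeat: int = 0
    n_removed_span_cap: int = 0
    thresholds_ms: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


class EmptyTaskError(ValueError):
    """Raised when a filter removes every record of a task."""


def filter_rt_outliers(records: pd.DataFrame, low_ms: float,
                       high_ms: float) -> tuple[pd.DataFrame, FilterReport]:
    """Retain records with low_ms <= rt_ms <= high_ms.

    Too-fast answers suggest random responding or cheating; too-slow ones
    suggest disengagement.  Both tails are counted separately.
    """
    if not low_ms < high_ms:
        raise ValueError("low_ms must be below high_ms")
    rt = records["rt_ms"].to_numpy(dtype=float)
    fast = rt < low_ms
    slow = rt > high_ms
    out = records.loc[~fast & ~slow]
    if len(out) == 0:
        raise EmptyTaskError("RT filtering removed every record")
    report = FilterReport(
        n_input=len(records), n_output=len(out),
        n_removed_fast=int(fast.sum()), n_removed_slow=int(slow.sum()),
        thresholds_ms={"low": float(low_ms), "high": float(high_ms)})
    return out, report


def drop_repeat_participants(records: pd.DataFrame
                             ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove all records of participants seen at more than one timepoint."""
    if "timepoint" not in records.columns:
        raise ValueError("timepoint column required")
    n_tp = records.groupby("participant_id")["timepoint"].nunique()
    repeat = set(n_tp.index[n_tp > 1])
    mask = records["participant_id"].isin(repeat)
    out = records.loc[~mask]
    if len(out) == 0:
        raise EmptyTaskError("repeat-participant filter removed every record")
    report = FilterReport(
        n_input=len(records), n_output=len(out),
        n_participants_dropped_repeat=len(repeat),
        n_removed_repeat=int(mask.sum()))
    return out, report


def cap_span_trials(records: pd.DataFrame, max_len: float
                    ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove span-type trials whose target length exceeds ``max_len``.

    The trial label must encode the numeric span length (e.g. "7").
    Lengths above the task's design maximum indicate cheating (writing the
    digits or locations down).
    """
    try:
        spans = records["trial_label"].astype(float)
    except (TypeError, ValueError) as e:
        raise ValueError(f"non-numeric trial labels in span mode: {e}")
    mask = spans > max_len
    out = records.loc[~mask]
    if len(out) == 0:
        raise EmptyTaskError("span cap removed every record")
    report = FilterReport(n_input=len(records), n_output=len(out),
                          n_removed_span_cap=int(mask.sum()))
    return out, report


def build_trial_labels(raw: pd.DataFrame,
                       label_spec: list[str]) -> pd.DataFrame:
    """Compose ``trial_label`` by concatenating the named raw fields.

    The difficulty dimension is task-specific: a single word, a start/end
    configuration pair, a span length, a moves/drops combination, ...  The
    named columns are joined with underscores, deterministically.
    """
    if not label_spec:
        raise ValueError("label_spec must name at least one field")
    missing = [c for c in label_spec if c not in raw.columns]
    if missing:
        raise KeyError(f"label fields absent from input: {missing}")
    out = raw.copy()
    parts = [out[c].astype(str) for c in label_spec]
    label = parts[0]
    for p in parts[1:]:
        label = label + "_" + p
    out["trial_label"] = label
    return out


def bin_numeric_labels(raw: pd.DataFrame, column: str,
                       n_bins: int = 20) -> pd.DataFrame:
    """Bin a continuous difficulty dimension (e.g. distance from the
    previous target) into ``n_bins`` equal-width bins and use the bin index
    as the trial label."""
    if column not in raw.columns:
        raise KeyError(f"column {column!r} absent from input")
    out = raw.copy()
    x = out[column].astype(float)
    binned = pd.cut(x, bins=n_bins, labels=False, include_lowest=True)
    out["trial_label"] = binned.astype(int).astype(str).str.zfill(2)
    return out
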