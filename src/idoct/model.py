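"""Fixed-point decomposition of trial timecourses.

The model splits each reaction time into an answer time AT (the portion
spent on the targeted cognitive process) and a participant-level delay time
DT (device latency, visuomotor and non-specific processing):

    RT(i, t) = AT(i, t) + DT(i)

Two fixed-point iterations are run in sequence.

1. *Difficulty stage.*  Trial performance P(i, t) combines speed and
   accuracy: zero for a wrong answer, otherwise (1 - RT/RTmax) scaled by the
   current difficulty D(t).  Difficulty is the group mean of (1 - P) over
   every presentation of the label, starting from D = 1, iterated until D
   and P converge.  Because the update is affine per label,
   D_{n+1} = 1 - m_t * D_n with m_t the label's mean of score*(1 - RT/RTmax),
   the fixed point is 1/(1 + m_t); the iteration is kept because its trace
   is part of the model's output contract (and the closed form serves as an
   independent oracle in the tests).

2. *Ability/delay stage.*  With D fixed, the answer time is modelled as
   AT(i, t) = (1 - A(i)) * D(t) * (RT(i, t) - DTmax(i)) where
   DTmax(i) = RTmin(i) is the participant's smallest RT, performance is
   re-expressed in terms of AT and DT, and the ability A(i) is the mean of
   cumulative means of P in presentation order — a weighting that counts
   early trials more.  A and P are mutually recursive, so the stage iterates
   from AT = RT - DTmax (equivalently "ability is maximal") to a fixed point.

Afterwards the specific performance PA(i, t) replaces the RT term with
AT/ATmax, giving the specific ability AS(i), and the difficulty scale is
corrected for who actually saw each trial: DS(t) = mean_i AS(i) * D(t) over
the participants presented t, affinely rescaled onto the range of D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (AbilityEstimates, DifficultyScale, FitConfig, Mode,
                   ModelFit, TaskDataset)

__all__ = [
    "compute_performance",
    "estimate_difficulty",
    "closed_form_difficulty",
    "estimate_ability_delay",
    "compute_specific_ability",
    "compute_scaled_difficulty",
    "fit",
]


# ---------------------------------------------------------------------------
# internal index structure

@dataclass
class _Indexed:
    """Dataset flattened to aligned arrays, sorted by (participant, order)."""

    rt: np.ndarray            # per record, ms
    score: np.ndarray         # per record, in [0, 1]
    label_codes: np.ndarray   # per record
    part_codes: np.ndarray    # per record, contiguous within segments
    labels: np.ndarray        # unique labels, sorted
    participants: np.ndarray  # unique ids, sorted
    starts: np.ndarray        # first record index of each participant
    q: np.ndarray             # records per participant
    dtmax: np.ndarray         # per participant: min rt
    rt_max: float

    @property
    def dtmax_rec(self) -> np.ndarray:
        return self.dtmax[self.part_codes]


def _index(dataset: TaskDataset) -> _Indexed:
    df = dataset.records.sort_values(
        ["participant_id", "order"], kind="stable")
    participants, part_codes = np.unique(
        df["participant_id"].to_numpy(), return_inverse=True)
    # rows are sorted by participant, so part_codes is piecewise constant
    labels, label_codes = np.unique(
        df["trial_label"].to_numpy(), return_inverse=True)
    rt = df["rt_ms"].to_numpy(dtype=float)
    if dataset.mode == "binary":
        score = df["correct"].to_numpy(dtype=float)
    else:
        score = df["acc"].to_numpy(dtype=float)
    q = np.bincount(part_codes, minlength=len(participants))
    starts = np.concatenate([[0], np.cumsum(q)[:-1]])
    dtmax = np.full(len(participants), np.inf)
    np.minimum.at(dtmax, part_codes, rt)
    return _Indexed(rt=rt, score=score, label_codes=label_codes,
                    part_codes=part_codes, labels=labels,
                    participants=participants, starts=starts, q=q,
                    dtmax=dtmax, rt_max=dataset.rt_max)


def _segment_cummean(x: np.ndarray, idx: _Indexed) -> np.ndarray:
    """Cumulative mean of x within each participant segment, per record."""
    cs = np.cumsum(x)
    offset = np.repeat(cs[idx.starts] - x[idx.starts], idx.q)
    pos = np.arange(len(x)) - np.repeat(idx.starts, idx.q) + 1
    return (cs - offset) / pos


def _mean_cummean(x: np.ndarray, idx: _Indexed) -> np.ndarray:
    """Per participant: mean over N of the cumulative mean of x up to N.

    This is the cumulative-performance average defining ability: with
    presentations x_1..x_Q in order, it equals sum_N (1/N sum_{t<=N} x_t)/Q,
    a weighted mean of the x_t whose weights sum to one and decrease with t.
    """
    cm = _segment_cummean(x, idx)
    return np.bincount(idx.part_codes, weights=cm,
                       minlength=len(idx.participants)) / idx.q


def _participant_mean(x: np.ndarray, idx: _Indexed) -> np.ndarray:
    return np.bincount(idx.part_codes, weights=x,
                       minlength=len(idx.participants)) / idx.q


# ---------------------------------------------------------------------------
# stage 1: difficulty

def compute_performance(rt: float, score: float, d_value: float,
                        rt_max: float, mode: Mode = "binary") -> float:
    """Speed-accuracy performance of a single presentation.

    ``score`` is the correctness indicator (binary mode) or the graded
    accuracy in [0, 1] (continuous mode).  Zero for a wrong answer — a wrong
    answer's RT carries no information about ability; otherwise the scaled
    speed term (1 - rt/rt_max) times the accuracy times the trial's current
    difficulty.  Clamped to [0, 1].
    """
    if rt > rt_max:
        raise ValueError("rt exceeds rt_max: inconsistent scaling constant")
    if not 0 < d_value <= 1:
        raise ValueError("d_value must lie in (0, 1]")
    if mode == "continuous" and (score is None or np.isnan(score)):
        raise ValueError("continuous mode requires a graded accuracy")
    p = (1.0 - rt / rt_max) * score * d_value
    return float(min(max(p, 0.0), 1.0))


def _label_m(idx: _Indexed) -> np.ndarray:
    """Per-label mean of score * (1 - rt/rt_max): the contraction factor of
    the difficulty update (repeat presentations count separately)."""
    w = idx.score * (1.0 - idx.rt / idx.rt_max)
    tot = np.bincount(idx.label_codes, weights=w, minlength=len(idx.labels))
    n = np.bincount(idx.label_codes, minlength=len(idx.labels))
    return tot / n


def closed_form_difficulty(dataset: TaskDataset) -> dict:
    """Analytic fixed point of the difficulty iteration, 1/(1 + m_t).

    The iterative estimator must agree with this on any dataset whose m_t
    stay below 1; it exists as an independent oracle and fast path check.
    """
    idx = _index(dataset)
    m = _label_m(idx)
    return dict(zip(idx.labels.tolist(), (1.0 / (1.0 + m)).tolist()))


def estimate_difficulty(dataset: TaskDataset,
                        config: FitConfig | None = None) -> DifficultyScale:
    """Fixed-point estimate of per-label difficulty D(t).

    Starts from D = 1 (every trial maximally difficult), alternates
    performance and difficulty updates until the mean absolute change in D
    falls below ``config.tol`` or ``config.max_iter`` is reached.  Labels
    whose m_t equals 1 exactly (all correct at rt = 0) would oscillate; they
    are pinned to the analytic fixed point 0.5 with a warning.
    """
    config = config or FitConfig()
    idx = _index(dataset)
    return _estimate_difficulty_indexed(idx, config)


def _estimate_difficulty_indexed(idx: _Indexed,
                                 config: FitConfig) -> DifficultyScale:
    m = _label_m(idx)
    degenerate = np.abs(m - 1.0) < 1e-12
    if degenerate.any():
        warnings.warn(
            "labels with m_t = 1 oscillate; pinned to the fixed point 0.5",
            stacklevel=2)
    d = np.ones(len(idx.labels))
    d[degenerate] = 0.5
    trace = []
    converged = False
    n_iter = 0
    for _ in range(config.max_iter):
        d_new = 1.0 - m * d
        d_new[degenerate] = 0.5
        delta = float(np.mean(np.abs(d_new - d)))
        trace.append(delta)
        d = d_new
        n_iter += 1
        if delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"difficulty stage not converged after {n_iter} iterations "
            f"(residual mean |dD| = {trace[-1]:.3g})", stacklevel=2)
    counts = np.bincount(idx.label_codes, minlength=len(idx.labels))
    return DifficultyScale(labels=idx.labels, d=d,
                           trace=np.asarray(trace), n_iter=n_iter,
                           converged=converged, presentation_counts=counts)


# ---------------------------------------------------------------------------
# stage 2: ability and delay time

def estimate_ability_delay(dataset: TaskDataset,
                           difficulty: DifficultyScale,
                           config: FitConfig | None = None
                           ) -> AbilityEstimates:
    """Fixed-point estimate of ability A(i), answer times AT(i, t) and delay
    time DT(i) given a converged difficulty scale.

    Initialisation treats ability as maximal: AT(i, t) starts at its upper
    bound RT(i, t) - DTmax(i) and DT(i) at DTmax(i) = RTmin(i).  Each
    iteration recomputes performance

        P(i, t) = (1 - AT(i, t)/RTmax - DT(i)/RTmax) * score * D(t)

    (clamped to [0, 1]), ability as the mean of cumulative means of P in
    presentation order, then AT(i, t) = (1 - A(i)) * D(t) * (RT - DTmax(i))
    and DT(i) as the participant mean of RT - AT.  Stops when the mean
    absolute change in A falls below ``config.tol``.  The first trace entry
    measures the change from the all-ability-one start (A0 = 1).
    """
    config = config or FitConfig()
    idx = _index(dataset)
    return _estimate_ability_indexed(idx, difficulty, config)


def _d_per_record(idx: _Indexed, difficulty: DifficultyScale) -> np.ndarray:
    d_map = {lab: v for lab, v in zip(difficulty.labels, difficulty.d)}
    try:
        return np.array([d_map[lab] for lab in idx.labels])[idx.label_codes]
    except KeyError as e:
        raise ValueError(f"difficulty scale missing label {e.args[0]!r}")


def _estimate_ability_indexed(idx: _Indexed, difficulty: DifficultyScale,
                              config: FitConfig) -> AbilityEstimates:
    if idx.rt_max <= 0:
        raise ValueError("invalid dataset: rt_max must be positive")
    d_rec = _d_per_record(idx, difficulty)
    at = idx.rt - idx.dtmax_rec          # AT starts at its maximum (ATmin form)
    a = np.ones(len(idx.participants))   # ability assumed maximal at n = 0
    trace = []
    converged = False
    n_iter = 0
    for _ in range(config.max_iter):
        dt_i = _participant_mean(idx.rt - at, idx)
        p = (1.0 - at / idx.rt_max - dt_i[idx.part_codes] / idx.rt_max)
        p = np.clip(p * idx.score * d_rec, 0.0, 1.0)
        a_new = _mean_cummean(p, idx)
        delta = float(np.mean(np.abs(a_new - a)))
        trace.append(delta)
        a = a_new
        at = (1.0 - a[idx.part_codes]) * d_rec * (idx.rt - idx.dtmax_rec)
        n_iter += 1
        if delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ability stage not converged after {n_iter} iterations "
            f"(residual mean |dA| = {trace[-1]:.3g})", stacklevel=2)
    dt_i = _participant_mean(idx.rt - at, idx)
    at_max = float(at.max())
    participants = pd.DataFrame({
        "a": a,
        "as_": np.nan,
        "dt": dt_i,
        "dt_max": idx.dtmax,
        "q": idx.q,
    }, index=pd.Index(idx.participants, name="participant_id"))
    return AbilityEstimates(participants=participants, at=at, at_max=at_max,
                            trace=np.asarray(trace), n_iter=n_iter,
                            converged=converged)


# ---------------------------------------------------------------------------
# stage 3: specific ability

def compute_specific_ability(dataset: TaskDataset,
                             ability: AbilityEstimates,
                             difficulty: DifficultyScale) -> pd.Series:
    """Specific ability AS(i): ability recomputed from the delay-corrected
    performance PA(i, t) = (1 - AT/ATmax) * score * D(t).

    If every answer time is zero (degenerate: all abilities maximal) the AT
    term is dropped with a warning, leaving PA = score * D(t).
    """
    idx = _index(dataset)
    d_rec = _d_per_record(idx, difficulty)
    if ability.at_max > 0:
        at_term = 1.0 - ability.at / ability.at_max
    else:
        warnings.warn("all answer times are zero; AT term dropped from PA",
                      stacklevel=2)
        at_term = np.ones_like(ability.at)
    pa = np.clip(at_term * idx.score * d_rec, 0.0, 1.0)
    as_ = _mean_cummean(pa, idx)
    return pd.Series(as_, index=pd.Index(idx.participants,
                                         name="participant_id"), name="as_")


# ---------------------------------------------------------------------------
# stage 4: scaled difficulty

def compute_scaled_difficulty(dataset: TaskDataset,
                              difficulty: DifficultyScale,
                              as_: pd.Series) -> np.ndarray:
    """Ability-corrected difficulty scale DS(t).

    Per label the pre-scale value is D(t) times the mean specific ability of
    the distinct participants who were presented that label, which counters
    the sampling bias of adaptive designs (hard trials seen mostly by able
    participants look spuriously easy under D alone).  The pre-scale values
    are then affinely mapped back onto the range [min D, max D], so a task
    with uniform abilities recovers D exactly.
    """
    idx = _index(dataset)
    order = {lab: k for k, lab in enumerate(difficulty.labels)}
    lab_pos = np.array([order[lab] for lab in idx.labels])[idx.label_codes]
    # distinct (participant, label) pairs: each participant counts once per label
    pair = np.unique(np.stack([idx.part_codes, lab_pos], axis=1), axis=0)
    as_by_code = as_.loc[idx.participants].to_numpy()
    n_lab = len(difficulty.labels)
    tot = np.bincount(pair[:, 1], weights=as_by_code[pair[:, 0]],
                      minlength=n_lab)
    n = np.bincount(pair[:, 1], minlength=n_lab)
    if np.any(n == 0):
        missing = difficulty.labels[n == 0]
        raise ValueError(f"labels never presented in dataset: {missing!r}")
    pre = difficulty.d * (tot / n)
    if n_lab < 2:
        warnings.warn("single-label task: DS rescaling undefined, "
                      "returning pre-scale value", stacklevel=2)
        return pre
    lo, hi = pre.min(), pre.max()
    if hi - lo < 1e-15:
        warnings.warn("pre-scale DS is constant: rescaling undefined, "
                      "returning pre-scale values", stacklevel=2)
        return pre
    d_lo, d_hi = difficulty.d.min(), difficulty.d.max()
    return d_lo + (pre - lo) * (d_hi - d_lo) / (hi - lo)


# ---------------------------------------------------------------------------
# full pipeline

def fit(dataset: TaskDataset, config: FitConfig | None = None) -> ModelFit:
    """Run the full decomposition: difficulty, ability/delay, specific
    ability, scaled difficulty.  Deterministic given the dataset (row
    content and per-participant presentation order) and config.
    """
    config = config or FitConfig()
    idx = _index(dataset)
    difficulty = _estimate_difficulty_indexed(idx, config)
    ability = _estimate_ability_indexed(idx, difficulty, config)
    dataset.at_max = ability.at_max
    as_ = compute_specific_ability(dataset, ability, difficulty)
    difficulty.ds = compute_scaled_difficulty(dataset, difficulty, as_)
    participants = ability.participants.copy()
    participants["as_"] = as_
    return ModelFit(difficulty=difficulty, participants=participants,
                    at_max=ability.at_max, ability_trace=ability.trace,
                    ability_n_iter=ability.n_iter,
                    ability_converged=ability.converged,
                    config=config, mode=dataset.mode, rt_max=dataset.rt_max)
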