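"""Synthetic task-data generator with known ground truth.

The generator is the inverse of the decomposition model: each participant
carries a latent ability in (0, 1) and a delay time in ms; each trial label
carries a true difficulty in (0, 1].  A presentation's answer time is

    AT = (1 - ability) * difficulty * tau * noise,    noise ~ lognormal,

its reaction time RT = AT + delay, and its correctness is Bernoulli with
probability logistic(kappa * (ability - difficulty)) (in continuous mode a
graded 0..3 score is drawn as Binomial(3, p)/3, emulating an object-memory
style rubric).  Abilities are Beta-distributed (negatively skewed by
default), delays Gamma-distributed (positively skewed), matching the
qualitative distribution shapes reported for population cognitive data.

Two sampling designs are provided: *balanced* (every participant sees every
label once, shuffled order) and *staircase* (span-task semantics: labels are
ordered by difficulty; success moves up one level, failure repeats the
level, and the run terminates after a configurable number of consecutive
failures or after succeeding at the top level).  The staircase design
reproduces the biased sampling of adaptive tasks: hard trials are seen
almost exclusively by able participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import pearsonr, spearmanr

from .data import FitConfig, TaskDataset
from .model import ModelFit, fit as fit_model

__all__ = [
    "SimulationParams", "SimulationTruth",
    "simulate_task", "simulate_staircase_task",
    "recovery_metrics", "subsample_stability",
]


@dataclass
class SimulationParams:
    """Generator settings; the defaults define the standard study conditions.

    ``ability_shape`` (Beta) defaults to (5, 2): mean 0.71, negative skew.
    ``delay_shape``/``delay_scale`` (Gamma, ms) default to mean 750 ms,
    SD 150 ms, positive skew.  ``tau`` scales answer times, ``rt_sigma`` is
    the lognormal RT noise, ``kappa`` the steepness of the logistic
    correctness link.  Difficulties are evenly spaced over (0, 1].  The
    defaults are calibrated so the group-mean speed-accuracy performance
    sits near 0.35, at which both fixed-point stages converge within about
    ten iterations on a 1000 x 50 balanced task.
    """

    n_participants: int = 1000
    n_labels: int = 50
    ability_shape: tuple[float, float] = (5.0, 2.0)
    delay_shape: float = 25.0
    delay_scale: float = 30.0
    tau: float = 700.0
    rt_sigma: float = 0.15
    kappa: float = 10.0
    mode: Literal["binary", "continuous"] = "binary"
    sampling: Literal["balanced", "staircase"] = "balanced"
    staircase_failures: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        positive = dict(n_participants=self.n_participants,
                        n_labels=self.n_labels, delay_shape=self.delay_shape,
                        delay_scale=self.delay_scale, tau=self.tau,
                        kappa=self.kappa,
                        staircase_failures=self.staircase_failures)
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rt_sigma < 0:
            raise ValueError("rt_sigma must be nonnegative")
        if min(self.ability_shape) <= 0:
            raise ValueError("ability Beta shapes must be positive")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated dataset."""

    true_ability: pd.Series     # indexed by participant_id, in (0, 1)
    true_delay: pd.Series       # indexed by participant_id, ms
    true_difficulty: pd.Series  # indexed by trial_label, in (0, 1]
    params: SimulationParams
    assignment: pd.DataFrame = field(repr=False, default=None)


def _draw_population(params: SimulationParams, rng: np.random.Generator):
    n, L = params.n_participants, params.n_labels
    pid = np.array([f"p{i:05d}" for i in range(n)])
    labels = np.array([f"L{t:03d}" for t in range(L)])
    a, b = params.ability_shape
    ability = np.clip(rng.beta(a, b, size=n), 1e-6, 1 - 1e-6)
    delay = rng.gamma(params.delay_shape, params.delay_scale, size=n)
    difficulty = np.arange(1, L + 1) / (L + 1)
    return pid, labels, ability, delay, difficulty


def _rt_and_score(params: SimulationParams, rng: np.random.Generator,
                  ability: np.ndarray, delay: np.ndarray,
                  difficulty: np.ndarray):
    """Vectorised draw of (rt, correct, acc) for aligned trial arrays."""
    n = len(ability)
    p = expit(params.kappa * (ability - difficulty))
    if params.rt_sigma > 0:
        # mean-one lognormal noise
        noise = rng.lognormal(-params.rt_sigma ** 2 / 2, params.rt_sigma,
                              size=n)
    else:
        noise = np.ones(n)
    at = (1.0 - ability) * difficulty * params.tau * noise
    rt = at + delay
    if params.mode == "binary":
        correct = rng.random(n) < p
        acc = np.full(n, np.nan)
    else:
        acc = rng.binomial(3, p, size=n) / 3.0
        correct = acc > 0.5
    return rt, correct, acc


def simulate_task(params: SimulationParams
                  ) -> tuple[TaskDataset, SimulationTruth]:
    """Balanced design: every participant sees every label once, in random
    order.  Bit-identical regeneration under the same params and seed."""
    if params.sampling == "staircase":
        return simulate_staircase_task(params)
    rng = np.random.default_rng(params.seed)
    pid, labels, ability, delay, difficulty = _draw_population(params, rng)
    n, L = params.n_participants, params.n_labels

    # per participant, a shuffled permutation of the labels
    label_idx = np.argsort(rng.random((n, L)), axis=1).ravel()
    part_idx = np.repeat(np.arange(n), L)
    rt, correct, acc = _rt_and_score(
        params, rng, ability[part_idx], delay[part_idx],
        difficulty[label_idx])
    records = pd.DataFrame({
        "participant_id": pid[part_idx],
        "trial_label": labels[label_idx],
        "rt_ms": rt,
        "correct": correct,
        "acc": acc,
        "order": np.tile(np.arange(L), n),
        "timepoint": 1,
    })
    dataset = TaskDataset(records, mode=params.mode)
    truth = SimulationTruth(
        true_ability=pd.Series(ability, index=pd.Index(pid, name="participant_id"),
                               name="true_ability"),
        true_delay=pd.Series(delay, index=pd.Index(pid, name="participant_id"),
                             name="true_delay_ms"),
        true_difficulty=pd.Series(difficulty,
                                  index=pd.Index(labels, name="trial_label"),
                                  name="true_difficulty"),
        params=params,
        assignment=records[["participant_id", "trial_label"]])
    return dataset, truth


def simulate_staircase_task(params: SimulationParams
                            ) -> tuple[TaskDataset, SimulationTruth]:
    """Adaptive span-style design.

    Labels are ordered by true difficulty (span levels).  Each participant
    starts at the lowest level; a correct answer moves to the next level, an
    incorrect one repeats the level, and the run terminates after
    ``staircase_failures`` consecutive incorrect answers or after a correct
    answer at the top level.  Hard labels are consequently seen mostly by
    high-ability participants.
    """
    rng = np.random.default_rng(params.seed)
    pid, labels, ability, delay, difficulty = _draw_population(params, rng)
    L = params.n_labels
    rows_part, rows_label, rows_order = [], [], []
    rows_correct = []
    for i in range(params.n_participants):
        level = 0
        fails = 0
        order = 0
        p_levels = expit(params.kappa * (ability[i] - difficulty))
        while True:
            ok = rng.random() < p_levels[level]
            rows_part.append(i)
            rows_label.append(level)
            rows_order.append(order)
            rows_correct.append(ok)
            order += 1
            if ok:
                fails = 0
                if level == L - 1:
                    break
                level += 1
            else:
                fails += 1
                if fails >= params.staircase_failures:
                    break
    part_idx = np.asarray(rows_part)
    label_idx = np.asarray(rows_label)
    correct = np.asarray(rows_correct)
    n_rows = len(part_idx)
    if params.rt_sigma > 0:
        noise = rng.lognormal(-params.rt_sigma ** 2 / 2, params.rt_sigma,
                              size=n_rows)
    else:
        noise = np.ones(n_rows)
    at = ((1.0 - ability[part_idx]) * difficulty[label_idx]
          * params.tau * noise)
    rt = at + delay[part_idx]
    if params.mode == "continuous":
        acc = np.where(correct, 1.0, rng.binomial(1, 0.5, n_rows) / 3.0)
    else:
        acc = np.full(n_rows, np.nan)
    records = pd.DataFrame({
        "participant_id": pid[part_idx],
        "trial_label": labels[label_idx],
        "rt_ms": rt,
        "correct": correct,
        "acc": acc,
        "order": np.asarray(rows_order),
        "timepoint": 1,
    })
    dataset = TaskDataset(records, mode=params.mode)
    truth = SimulationTruth(
        true_ability=pd.Series(ability, index=pd.Index(pid, name="participant_id"),
                               name="true_ability"),
        true_delay=pd.Series(delay, index=pd.Index(pid, name="participant_id"),
                             name="true_delay_ms"),
        true_difficulty=pd.Series(difficulty,
                                  index=pd.Index(labels, name="trial_label"),
                                  name="true_difficulty"),
        params=params,
        assignment=records[["participant_id", "trial_label"]])
    return dataset, truth


def _corr_pair(x: np.ndarray, y: np.ndarray) -> dict:
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        return {"pearson": np.nan, "spearman": np.nan}
    return {"pearson": float(pearsonr(x, y)[0]),
            "spearman": float(spearmanr(x, y)[0])}


def recovery_metrics(truth: SimulationTruth, fit: ModelFit) -> dict:
    """Truth-vs-estimate correlations: ability (vs A and AS), delay (vs DT),
    difficulty (vs D and DS).  Degenerate constant vectors report NaN."""
    parts = fit.participants
    common = truth.true_ability.index.intersection(parts.index)
    ab = truth.true_ability.loc[common].to_numpy()
    de = truth.true_delay.loc[common].to_numpy()
    lab = pd.Index(fit.difficulty.labels)
    common_lab = truth.true_difficulty.index.intersection(lab)
    d_map = pd.Series(fit.difficulty.d, index=lab)
    out = {
        "ability_a": _corr_pair(ab, parts.loc[common, "a"].to_numpy()),
        "ability_as": _corr_pair(ab, parts.loc[common, "as_"].to_numpy()),
        "delay_dt": _corr_pair(de, parts.loc[common, "dt"].to_numpy()),
        "difficulty_d": _corr_pair(
            truth.true_difficulty.loc[common_lab].to_numpy(),
            d_map.loc[common_lab].to_numpy()),
    }
    if fit.difficulty.ds is not None:
        ds_map = pd.Series(fit.difficulty.ds, index=lab)
        out["difficulty_ds"] = _corr_pair(
            truth.true_difficulty.loc[common_lab].to_numpy(),
            ds_map.loc[common_lab].to_numpy())
    return out


def subsample_stability(dataset: TaskDataset, sizes: list[int],
                        n_repeats: int, seed: int,
                        config: FitConfig | None = None) -> pd.DataFrame:
    """Stability of the estimates under participant subsampling.

    For each size and repeat, refits the model on a random participant
    subsample and Pearson-correlates the subsample estimates against the
    full-sample fit: AS and DT over the subsampled participants, D and DS
    over the labels present in the subsample.  Labels absent from a
    subsample are omitted from the D/DS correlations and counted.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    full = fit_model(dataset, config)
    participants = full.participants.index.to_numpy()
    if max(sizes) > len(participants):
        raise ValueError("subsample size exceeds participant count")
    full_d = pd.Series(full.difficulty.d, index=full.difficulty.labels)
    full_ds = pd.Series(full.difficulty.ds, index=full.difficulty.labels)
    rows = []
    for size in sizes:
        for rep in range(n_repeats):
            chosen = rng.choice(participants, size=size, replace=False)
            sub = dataset.records[
                dataset.records["participant_id"].isin(chosen)]
            sub_fit = fit_model(TaskDataset(sub, mode=dataset.mode), config)
            sp = sub_fit.participants
            ids = sp.index
            r_as = _corr_pair(full.participants.loc[ids, "as_"].to_numpy(),
                              sp["as_"].to_numpy())["pearson"]
            r_dt = _corr_pair(full.participants.loc[ids, "dt"].to_numpy(),
                              sp["dt"].to_numpy())["pearson"]
            sub_lab = pd.Index(sub_fit.difficulty.labels)
            r_d = _corr_pair(full_d.loc[sub_lab].to_numpy(),
                             sub_fit.difficulty.d)["pearson"]
            r_ds = _corr_pair(full_ds.loc[sub_lab].to_numpy(),
                              sub_fit.difficulty.ds)["pearson"]
            rows.append({"size": size, "repeat": rep, "r_as": r_as,
                         "r_dt": r_dt, "r_d": r_d, "r_ds": r_ds,
                         "n_labels_missing": len(full_d) - len(sub_lab)})
    return pd.DataFrame(rows)
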