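"""Core decomposition: performance, difficulty, ability/delay, AS, DS."""

import numpy as np
import pandas as pd
import pytest

from idoct import (FitConfig, TaskDataset, closed_form_difficulty,
                   compute_performance, compute_scaled_difficulty,
                   compute_specific_ability, estimate_ability_delay,
                   estimate_difficulty, fit)

from bruteforce import (bf_ability_delay, bf_difficulty,
                        bf_scaled_difficulty, bf_specific_ability)
from conftest import make_dataset, to_record_dicts

DEEP = FitConfig(max_iter=5000, tol=1e-12)


# ---------------------------------------------------------------------------
# single-presentation performance

@pytest.mark.parametrize("rt,score,d,mode,expected", [
    (834.0, 0.0, 0.9, "binary", 0.0),         # wrong answer scores zero
    (1000.0, 1.0, 1.0, "binary", 0.0),        # rt at the scaling maximum
    (250.0, 1.0, 0.8, "binary", 0.6),         # (1 - 0.25) * 0.8
    (250.0, 0.5, 0.8, "continuous", 0.3),     # graded accuracy halves it
])
def test_compute_performance_values(rt, score, d, mode, expected):
    p = compute_performance(rt, score, d, rt_max=1000.0, mode=mode)
    assert p == pytest.approx(expected, abs=1e-12)


def test_compute_performance_rejects_inconsistent_scaling():
    with pytest.raises(ValueError):
        compute_performance(2000.0, 1.0, 0.5, rt_max=1000.0)
    with pytest.raises(ValueError):
        compute_performance(500.0, 1.0, 0.0, rt_max=1000.0)
    with pytest.raises(ValueError):
        compute_performance(500.0, float("nan"), 0.5, rt_max=1000.0,
                            mode="continuous")


# ---------------------------------------------------------------------------
# difficulty stage

def _two_trial_dataset():
    # one label, two correct presentations at half the maximum rt
    df = pd.DataFrame({
        "participant_id": ["a", "b", "c"],
        "trial_label": ["w", "w", "x"],
        "rt_ms": [500.0, 500.0, 1000.0],
        "correct": [True, True, True],
        "order": [0, 0, 0],
    })
    return TaskDataset(df, mode="binary")


def test_difficulty_affine_fixed_point():
    """Two correct answers at scaled rt 0.5 give m = 0.5, so the fixed
    point of D = 1 - m D is 2/3; the rt_max record itself has m = 0."""
    ds = _two_trial_dataset()
    scale = estimate_difficulty(ds, DEEP)
    assert scale.d_map["w"] == pytest.approx(2.0 / 3.0, abs=1e-9)
    assert scale.d_map["x"] == pytest.approx(1.0, abs=1e-12)
    assert scale.converged


def test_difficulty_all_incorrect_converges_immediately():
    df = pd.DataFrame({
        "participant_id": list("abcd"),
        "trial_label": ["u", "u", "v", "v"],
        "rt_ms": [400.0, 900.0, 600.0, 1100.0],
        "correct": [False] * 4,
        "order": [0, 0, 0, 0],
    })
    scale = estimate_difficulty(TaskDataset(df), FitConfig())
    assert np.allclose(scale.d, 1.0)
    assert scale.n_iter == 1 and scale.converged


def test_difficulty_matches_closed_form_on_random_data(rng):
    """Iterative D equals the analytic fixed point 1/(1 + m_t)."""
    for _ in range(25):
        ds = make_dataset(rng, n_participants=int(rng.integers(2, 7)),
                          n_labels=int(rng.integers(1, 6)))
        scale = estimate_difficulty(ds, DEEP)
        oracle = closed_form_difficulty(ds)
        for lab, v in oracle.items():
            assert scale.d_map[lab] == pytest.approx(v, abs=1e-6)


def test_difficulty_matches_bruteforce(rng):
    ds = make_dataset(rng, n_participants=6, n_labels=5)
    scale = estimate_difficulty(ds, DEEP)
    oracle = bf_difficulty(to_record_dicts(ds), ds.rt_max)
    for lab, v in oracle.items():
        assert scale.d_map[lab] == pytest.approx(v, abs=1e-9)


def test_difficulty_oscillation_pinned_to_half():
    """All-correct instantaneous answers give m = 1; the alternating
    iteration is short-circuited to the analytic fixed point 0.5."""
    df = pd.DataFrame({
        "participant_id": ["a", "b", "a", "b"],
        "trial_label": ["w", "w", "x", "x"],
        "rt_ms": [1e-9, 1e-9, 1000.0, 1000.0],
        "correct": [True, True, False, False],
        "order": [0, 0, 1, 1],
    })
    with pytest.warns(UserWarning, match="m_t = 1"):
        scale = estimate_difficulty(TaskDataset(df), FitConfig())
    assert scale.d_map["w"] == pytest.approx(0.5, abs=1e-6)


def test_difficulty_nonconvergence_flagged_not_raised(rng):
    ds = make_dataset(rng, n_participants=6, n_labels=3,
                      rt_low=10.0, rt_high=50000.0)
    with pytest.warns(UserWarning, match="not converged"):
        scale = estimate_difficulty(ds, FitConfig(max_iter=2, tol=1e-15))
    assert not scale.converged
    assert len(scale.trace) == 2


def test_difficulty_monotone_in_rt(rng):
    """Slowing one correct answer down cannot make its label easier."""
    ds = make_dataset(rng, n_participants=6, n_labels=3)
    df = ds.records.copy()
    correct_idx = df.index[df["correct"]][0]
    lab = df.loc[correct_idx, "trial_label"]
    d_before = estimate_difficulty(ds, DEEP).d_map[lab]
    df.loc[correct_idx, "rt_ms"] = min(
        df.loc[correct_idx, "rt_ms"] * 1.5, ds.rt_max)
    d_after = estimate_difficulty(TaskDataset(df), DEEP).d_map[lab]
    assert d_after >= d_before - 1e-12


def test_difficulty_counts_repeat_presentations(rng):
    """A participant's repeated presentations of one label each enter the
    label mean separately."""
    df = pd.DataFrame({
        "participant_id": ["a", "a", "b"],
        "trial_label": ["w", "w", "w"],
        "rt_ms": [250.0, 750.0, 1000.0],
        "correct": [True, True, True],
        "order": [0, 1, 0],
    })
    ds = TaskDataset(df)
    scale = estimate_difficulty(ds, DEEP)
    m = (0.75 + 0.25 + 0.0) / 3.0
    assert scale.d_map["w"] == pytest.approx(1.0 / (1.0 + m), abs=1e-9)
    assert scale.presentation_counts[0] == 3


# ---------------------------------------------------------------------------
# ability / delay stage

def test_single_trial_participant_closed_form():
    """With one trial, DTmax is that rt, so AT = 0, DT = rt and the ability
    is the single performance value."""
    df = pd.DataFrame({
        "participant_id": ["solo", "other", "other"],
        "trial_label": ["w", "w", "w"],
        "rt_ms": [400.0, 500.0, 1000.0],
        "correct": [True, True, True],
        "order": [0, 0, 1],
    })
    ds = TaskDataset(df)
    scale = estimate_difficulty(ds, DEEP)
    est = estimate_ability_delay(ds, scale, DEEP)
    d = scale.d_map["w"]
    solo = est.participants.loc["solo"]
    assert solo["dt"] == pytest.approx(400.0, abs=1e-9)
    assert solo["dt_max"] == 400.0
    assert solo["a"] == pytest.approx((1 - 400.0 / 1000.0) * d, abs=1e-9)


def test_all_incorrect_ability_zero_delay_is_min_rt(rng):
    """With no correct answers P is identically zero, so A = AS = 0 and the
    answer time absorbs everything above the participant's fastest rt,
    leaving DT at its lower bound DTmax."""
    ds = make_dataset(rng, n_participants=4, n_labels=3, p_correct=0.0)
    result = fit(ds, DEEP)
    parts = result.participants
    assert np.allclose(parts["a"], 0.0)
    assert np.allclose(parts["as_"], 0.0)
    assert np.allclose(result.difficulty.d, 1.0)
    assert np.allclose(parts["dt"], parts["dt_max"])


def test_ability_delay_matches_bruteforce(rng):
    """Vectorised stage equals the literal loop transliteration."""
    for _ in range(5):
        ds = make_dataset(rng, n_participants=5, n_labels=4)
        scale = estimate_difficulty(ds, DEEP)
        est = estimate_ability_delay(ds, scale, FitConfig(max_iter=50,
                                                          tol=1e-15))
        recs = to_record_dicts(ds)
        a_bf, dt_bf, at_bf, dtmax_bf = bf_ability_delay(
            recs, scale.d_map, ds.rt_max, n_iter=50)
        for pid in a_bf:
            assert est.participants.loc[pid, "a"] == pytest.approx(
                a_bf[pid], abs=1e-9)
            assert est.participants.loc[pid, "dt"] == pytest.approx(
                dt_bf[pid], abs=1e-9)
            assert est.participants.loc[pid, "dt_max"] == dtmax_bf[pid]


def test_specific_ability_matches_bruteforce(rng):
    ds = make_dataset(rng, n_participants=5, n_labels=4, mode="continuous")
    scale = estimate_difficulty(ds, DEEP)
    est = estimate_ability_delay(ds, scale, FitConfig(max_iter=50,
                                                      tol=1e-15))
    as_ = compute_specific_ability(ds, est, scale)
    recs = to_record_dicts(ds)
    _, _, at_bf, _ = bf_ability_delay(recs, scale.d_map, ds.rt_max,
                                      n_iter=50)
    as_bf = bf_specific_ability(recs, scale.d_map, at_bf, ds.rt_max)
    for pid, v in as_bf.items():
        assert as_.loc[pid] == pytest.approx(v, abs=1e-9)


def test_specific_ability_all_at_zero_is_weighted_difficulty_mean():
    """When every answer time is zero and every answer correct, PA reduces
    to D(t) and AS is the cumulative-mean average of the difficulties seen,
    in presentation order."""
    # both participants answer at their own constant rt: dtmax = rt, AT = 0
    df = pd.DataFrame({
        "participant_id": ["a", "a", "b", "b"],
        "trial_label": ["u", "v", "u", "v"],
        "rt_ms": [500.0, 500.0, 1000.0, 1000.0],
        "correct": [True] * 4,
        "order": [0, 1, 0, 1],
    })
    ds = TaskDataset(df)
    scale = estimate_difficulty(ds, DEEP)
    est = estimate_ability_delay(ds, scale, DEEP)
    assert est.at_max == 0.0
    with pytest.warns(UserWarning, match="answer times are zero"):
        as_ = compute_specific_ability(ds, est, scale)
    d_u, d_v = scale.d_map["u"], scale.d_map["v"]
    expected = (d_u + (d_u + d_v) / 2.0) / 2.0   # mean of cumulative means
    assert as_.loc["a"] == pytest.approx(expected, abs=1e-12)


def test_ability_depends_on_presentation_order():
    """Early trials weigh more in the cumulative-performance average, so
    permuting a participant's order changes A."""
    base = pd.DataFrame({
        "participant_id": ["a"] * 3 + ["b"] * 3,
        "trial_label": ["u", "v", "w"] * 2,
        "rt_ms": [300.0, 900.0, 2000.0, 600.0, 700.0, 800.0],
        "correct": [True, True, False, True, False, True],
        "order": [0, 1, 2, 0, 1, 2],
    })
    flipped = base.copy()
    flipped.loc[flipped["participant_id"] == "a", "order"] = [2, 1, 0]
    cfg = FitConfig(max_iter=100, tol=1e-12)
    a1 = fit(TaskDataset(base), cfg).participants.loc["a", "a"]
    a2 = fit(TaskDataset(flipped), cfg).participants.loc["a", "a"]
    assert abs(a1 - a2) > 1e-6


def test_participant_processing_order_irrelevant(rng):
    """Shuffling the row order of whole participants (keeping each
    participant's own presentation order) leaves all estimates unchanged."""
    ds = make_dataset(rng, n_participants=6, n_labels=4)
    shuffled = ds.records.sample(frac=1.0, random_state=3)
    f1 = fit(ds, DEEP)
    f2 = fit(TaskDataset(shuffled), DEEP)
    pd.testing.assert_frame_equal(f1.participants, f2.participants)
    assert np.array_equal(f1.difficulty.d, f2.difficulty.d)


# ---------------------------------------------------------------------------
# range invariants (fuzzed)

def test_range_invariants_fuzzed(rng):
    """Converged D in [0.5, 1]; A, AS in [0, 1]; DT in [DTmax, mean RT]."""
    for _ in range(30):
        ds = make_dataset(rng,
                          n_participants=int(rng.integers(2, 8)),
                          n_labels=int(rng.integers(1, 6)),
                          mode=str(rng.choice(["binary", "continuous"])),
                          p_correct=float(rng.uniform(0.0, 1.0)),
                          rt_low=float(rng.uniform(1.0, 500.0)),
                          rt_high=float(rng.uniform(600.0, 60000.0)))
        result = fit(ds, DEEP)
        d = result.difficulty.d
        assert np.all(d >= 0.5 - 1e-12) and np.all(d <= 1.0 + 1e-12)
        parts = result.participants
        assert np.all(parts["a"] >= -1e-12) and np.all(parts["a"] <= 1 + 1e-12)
        assert np.all(parts["as_"] >= -1e-12)
        assert np.all(parts["as_"] <= 1 + 1e-12)
        mean_rt = ds.records.groupby("participant_id")["rt_ms"].mean()
        assert np.all(parts["dt"] >= parts["dt_max"] - 1e-9)
        assert np.all(parts["dt"].to_numpy()
                      <= mean_rt.loc[parts.index].to_numpy() + 1e-9)


# ---------------------------------------------------------------------------
# scaled difficulty

def test_scaled_difficulty_uniform_ability_recovers_d(rng):
    """If every participant has the same AS, the affine rescale of AS * D
    returns D exactly."""
    ds = make_dataset(rng, n_participants=5, n_labels=4)
    scale = estimate_difficulty(ds, DEEP)
    as_ = pd.Series(0.37, index=pd.Index(sorted(
        ds.records["participant_id"].unique()), name="participant_id"))
    ds_vals = compute_scaled_difficulty(ds, scale, as_)
    assert np.allclose(ds_vals, scale.d, atol=1e-12)


def test_scaled_difficulty_low_ability_group_scores_lower():
    """Two labels with equal D seen by disjoint groups: the label seen by
    the low-AS group gets the lower pre-scale value (and so the lower DS,
    with anchor labels fixing the range)."""
    df = pd.DataFrame({
        "participant_id": ["lo1", "lo2", "hi1", "hi2", "z1", "z2"],
        "trial_label": ["eq_lo", "eq_lo", "eq_hi", "eq_hi", "anchor",
                        "anchor"],
        "rt_ms": [500.0, 500.0, 500.0, 500.0, 250.0, 1000.0],
        "correct": [True] * 6,
        "order": [0] * 6,
    })
    ds = TaskDataset(df)
    scale = estimate_difficulty(ds, DEEP)
    assert scale.d_map["eq_lo"] == pytest.approx(scale.d_map["eq_hi"])
    as_ = pd.Series({"lo1": 0.2, "lo2": 0.2, "hi1": 0.8, "hi2": 0.8,
                     "z1": 0.5, "z2": 0.5})
    as_.index.name = "participant_id"
    ds_vals = compute_scaled_difficulty(ds, scale, as_)
    ds_map = dict(zip(scale.labels, ds_vals))
    assert ds_map["eq_lo"] < ds_map["eq_hi"]


def test_scaled_difficulty_matches_bruteforce(rng):
    ds = make_dataset(rng, n_participants=6, n_labels=5)
    result = fit(ds, DEEP)
    recs = to_record_dicts(ds)
    as_map = result.participants["as_"].to_dict()
    oracle = bf_scaled_difficulty(recs, result.difficulty.d_map, as_map)
    for lab, v in oracle.items():
        assert result.difficulty.ds_map[lab] == pytest.approx(v, abs=1e-9)


def test_scaled_difficulty_single_label_warns(rng):
    ds = make_dataset(rng, n_participants=4, n_labels=1)
    scale = estimate_difficulty(ds, DEEP)
    as_ = pd.Series(0.5, index=pd.Index(sorted(
        ds.records["participant_id"].unique()), name="participant_id"))
    with pytest.warns(UserWarning, match="single-label"):
        vals = compute_scaled_difficulty(ds, scale, as_)
    assert len(vals) == 1


# ---------------------------------------------------------------------------
# full pipeline

def test_fit_deterministic(rng):
    ds = make_dataset(rng, n_participants=6, n_labels=4)
    f1 = fit(ds, FitConfig())
    f2 = fit(ds, FitConfig())
    pd.testing.assert_frame_equal(f1.participants, f2.participants)
    assert np.array_equal(f1.difficulty.d, f2.difficulty.d)
    assert np.array_equal(f1.difficulty.ds, f2.difficulty.ds)


def test_fit_rejects_empty():
    with pytest.raises(Exception):
        TaskDataset(pd.DataFrame(columns=["participant_id", "trial_label",
                                          "rt_ms", "correct"]))
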