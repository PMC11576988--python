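import numpy as np
import pandas as pd
import pytest

from idoct import TaskDataset


def make_dataset(rng, n_participants=5, n_labels=4, mode="binary",
                 p_correct=0.7, rt_low=300.0, rt_high=3000.0):
    """Random small dataset: every participant sees every label once in
    random order."""
    rows = []
    for i in range(n_participants):
        order = rng.permutation(n_labels)
        for pos, t in enumerate(order):
            rt = rng.uniform(rt_low, rt_high)
            correct = rng.random() < p_correct
            acc = rng.integers(0, 4) / 3.0
            rows.append({
                "participant_id": f"p{i:03d}",
                "trial_label": f"L{t:02d}",
                "rt_ms": rt,
                "correct": correct,
                "acc": acc,
                "order": pos,
                "timepoint": 1,
            })
    return TaskDataset(pd.DataFrame(rows), mode=mode)


def to_record_dicts(dataset):
    """Flatten a TaskDataset to the plain-dict form the brute-force oracle
    consumes."""
    score = dataset.score_values()
    out = []
    for (_, row), s in zip(dataset.records.iterrows(), score):
        out.append({"participant": row["participant_id"],
                    "label": row["trial_label"],
                    "rt": float(row["rt_ms"]),
                    "score": float(s),
                    "order": int(row["order"])})
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng)
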