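"""Literal, loop-based transliteration of the decomposition equations.

Deliberately slow and independent of the package's vectorised code paths:
plain dicts and Python loops, recomputing everything from the record list
each iteration.  Serves as the oracle for small-instance equivalence tests.

Records are dicts with keys participant, label, rt, score, order; ``score``
is the 0/1 correctness indicator or the graded accuracy.
"""

from __future__ import annotations


def _mean(xs):
    return sum(xs) / len(xs)


def _mean_cumulative_mean(ps):
    """Ability from ordered performances: mean over N of the mean of the
    first N values (cumulative performance average, early trials weighted
    more)."""
    cums = []
    total = 0.0
    for n, p in enumerate(ps, start=1):
        total += p
        cums.append(total / n)
    return _mean(cums)


def bf_difficulty(records, rt_max, n_iter=200):
    """Difficulty per label by naive fixed-point iteration from D = 1."""
    labels = sorted({r["label"] for r in records})
    d = {t: 1.0 for t in labels}
    for _ in range(n_iter):
        new = {}
        for t in labels:
            one_minus_p = []
            for r in records:
                if r["label"] != t:
                    continue
                p = (1.0 - r["rt"] / rt_max) * r["score"] * d[t]
                one_minus_p.append(1.0 - p)
            new[t] = _mean(one_minus_p)
        d = new
    return d


def bf_ability_delay(records, d, rt_max, n_iter=50):
    """Ability, delay time and answer times by naive iteration.

    Answer times start at their maximum (rt - the participant's smallest
    rt); each iteration recomputes the participant's delay, the performances
    in presentation order, the ability as the cumulative-performance
    average, then the answer times from the new ability.
    """
    by_part = {}
    for r in records:
        by_part.setdefault(r["participant"], []).append(r)
    for recs in by_part.values():
        recs.sort(key=lambda r: r["order"])

    dtmax = {i: min(r["rt"] for r in recs) for i, recs in by_part.items()}
    at = {i: [r["rt"] - dtmax[i] for r in recs]
          for i, recs in by_part.items()}
    a = {i: 1.0 for i in by_part}
    dt = {}
    for _ in range(n_iter):
        for i, recs in by_part.items():
            dt[i] = _mean([r["rt"] - at_v
                           for r, at_v in zip(recs, at[i])])
            ps = []
            for r, at_v in zip(recs, at[i]):
                p = (1.0 - at_v / rt_max - dt[i] / rt_max) \
                    * r["score"] * d[r["label"]]
                ps.append(min(max(p, 0.0), 1.0))
            a[i] = _mean_cumulative_mean(ps)
            at[i] = [(1.0 - a[i]) * d[r["label"]] * (r["rt"] - dtmax[i])
                     for r in recs]
        # delay recomputed from the final answer times
    for i, recs in by_part.items():
        dt[i] = _mean([r["rt"] - at_v for r, at_v in zip(recs, at[i])])
    return a, dt, at, dtmax


def bf_specific_ability(records, d, at, rt_max):
    """Specific ability from delay-corrected performances."""
    by_part = {}
    for r in records:
        by_part.setdefault(r["participant"], []).append(r)
    for recs in by_part.values():
        recs.sort(key=lambda r: r["order"])
    at_max = max(v for vals in at.values() for v in vals)
    as_ = {}
    for i, recs in by_part.items():
        pas = []
        for r, at_v in zip(recs, at[i]):
            term = 1.0 - at_v / at_max if at_max > 0 else 1.0
            pa = term * r["score"] * d[r["label"]]
            pas.append(min(max(pa, 0.0), 1.0))
        as_[i] = _mean_cumulative_mean(pas)
    return as_


def bf_scaled_difficulty(records, d, as_):
    """Pre-scale DS per label, affinely rescaled onto the range of D."""
    seen = {}
    for r in records:
        seen.setdefault(r["label"], set()).add(r["participant"])
    pre = {t: d[t] * _mean([as_[i] for i in sorted(parts)])
           for t, parts in seen.items()}
    if len(pre) < 2:
        return pre
    lo, hi = min(pre.values()), max(pre.values())
    d_lo, d_hi = min(d.values()), max(d.values())
    if hi - lo < 1e-15:
        return pre
    return {t: d_lo + (v - lo) * (d_hi - d_lo) / (hi - lo)
            for t, v in pre.items()}
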