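"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations: explicit
all-window / all-pairs scans and label-permutation nulls, kept simple enough
to verify by eye.
"""
from __future__ import annotations

import numpy as np

EPS = 1e-9


def urine_segments(hours, rates):
    """Maximal contiguous gap-free runs as (hours, rates) pairs."""
    hours = list(hours)
    rates = list(rates)
    segs = []
    cur_h, cur_r = [hours[0]], [rates[0]]
    for h, r in zip(hours[1:], rates[1:]):
        if h == cur_h[-1] + 1:
            cur_h.append(h)
            cur_r.append(r)
        else:
            segs.append((cur_h, cur_r))
            cur_h, cur_r = [h], [r]
    segs.append((cur_h, cur_r))
    return segs


def stage_urine_bruteforce(hours, rates, mode="mean"):
    """Exhaustive scan of every contiguous gap-free window.

    Returns {stage: first_time} for stages whose condition ever holds.
    """
    firsts = {}
    for seg_h, seg_r in urine_segments(hours, rates):
        n = len(seg_r)
        for j in range(n):  # window end
            for i in range(j + 1):  # window start
                w = seg_r[i : j + 1]
                L = len(w)
                agg_low = (sum(w) / L < 0.5) if mode == "mean" else all(r < 0.5 for r in w)
                agg_vlow = (sum(w) / L < 0.3) if mode == "mean" else all(r < 0.3 for r in w)
                anuric = all(r == 0 for r in w)
                t = seg_h[j]
                if L >= 6 and agg_low and 1 not in firsts:
                    firsts[1] = t
                if L >= 12 and agg_low and 2 not in firsts:
                    firsts[2] = t
                if ((L >= 24 and agg_vlow) or (L >= 12 and anuric)) and 3 not in firsts:
                    firsts[3] = t
    return firsts


def stage_creatinine_bruteforce(times, values, baseline_value, baseline_time=0.0,
                                delta_window=48.0, ratio_window=168.0):
    """All-pairs evaluation of the delta and ratio rules.

    Returns {stage: first_time}.
    """
    order = sorted(range(len(times)), key=lambda k: times[k])
    times = [times[k] for k in order]
    values = [values[k] for k in order]
    firsts = {}
    for k, (t, v) in enumerate(zip(times, values)):
        refs = [values[j] for j in range(len(times)) if t - delta_window <= times[j] <= t]
        if t - delta_window <= baseline_time <= t:
            refs.append(baseline_value)
        c1 = bool(refs) and v - min(refs) >= 0.3 - EPS
        c2 = c3 = False
        if 0.0 <= t <= ratio_window:
            r = v / baseline_value
            c1 = c1 or r >= 1.5 - EPS
            c2 = r >= 2.0 - EPS
            c3 = r >= 3.0 - EPS or v >= 4.0 - EPS
        for stage, hit in ((1, c1), (2, c2), (3, c3)):
            if hit and stage not in firsts:
                firsts[stage] = t
    return firsts


def combine_bruteforce(events, tie_break=("creatinine", "urine", "dialysis")):
    """Scan the merged time-sorted event stream for first/max stage."""
    if not events:
        return dict(first_stage=0, first_time=None, max_stage=0, max_time=None, trigger=None)
    stream = sorted(events, key=lambda e: e.time_h)
    first_time = stream[0].time_h
    at_first = [e for e in stream if e.time_h == first_time]
    first_stage = max(e.stage for e in at_first)
    prio = {c: i for i, c in enumerate(tie_break)}
    trigger = sorted(
        (e for e in at_first if e.stage == first_stage), key=lambda e: prio[e.criterion]
    )[0].criterion
    max_stage = max(e.stage for e in stream)
    max_time = min(e.time_h for e in stream if e.stage == max_stage)
    return dict(
        first_stage=first_stage,
        first_time=first_time,
        max_stage=max_stage,
        max_time=max_time,
        trigger=trigger,
    )


def min_rank_scan(rows):
    """Exhaustive redundancy resolution over dict rows with keys
    (patient_id, parameter, timestamp, quality_rank, source_process, value)."""
    best = {}
    for row in rows:
        key = (row["patient_id"], row["parameter"], row["timestamp"])
        contender = (row["quality_rank"], row["source_process"], row["value"])
        if key not in best or contender < best[key]:
            best[key] = contender
    return {k: v[2] for k, v in best.items()}


def chi2_statistic(table):
    table = np.asarray(table, dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def chi2_permutation_p(table, reps=100_000, seed=0, midp=True):
    """Permutation p-value of the Pearson statistic under label shuffling.

    With ``midp`` ties at the observed statistic count half, the standard
    continuity adjustment when comparing a discrete conditional null against
    the continuous chi-square reference.
    """
    rng = np.random.default_rng(seed)
    table = np.asarray(table, dtype=int)
    rows = np.repeat(np.arange(table.shape[0]), table.sum(1))
    cols = np.concatenate([np.repeat(np.arange(table.shape[1]), table[i]) for i in range(table.shape[0])])
    observed = chi2_statistic(table)
    above = ties = 0
    n_rows, n_cols = table.shape
    for _ in range(reps):
        perm = rng.permutation(cols)
        perm_table = np.zeros((n_rows, n_cols), dtype=int)
        np.add.at(perm_table, (rows, perm), 1)
        stat = chi2_statistic(perm_table)
        if stat > observed + 1e-9:
            above += 1
        elif stat >= observed - 1e-9:
            ties += 1
    return (above + (0.5 if midp else 1.0) * ties) / reps


def rank_sum_enumeration(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    from itertools import combinations

    from scipy.stats import rankdata

    all_vals = list(x) + list(y)
    rank_list = rankdata(all_vals)
    n1 = len(x)
    w_obs = float(rank_list[:n1].sum())
    n = len(all_vals)
    mean = n1 * (n + 1) / 2
    stats = [
        float(sum(rank_list[list(idx)])) for idx in combinations(range(n), n1)
    ]
    extreme = sum(1 for w in stats if abs(w - mean) >= abs(w_obs - mean) - 1e-12)
    return w_obs, extreme / len(stats)
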