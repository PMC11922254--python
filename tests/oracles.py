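"""Independent brute-force reference implementations.

These are deliberately written with plain Python arithmetic (no numpy
vectorization, no reuse of package code) so they can serve as independent
oracles for the package's statistics.
"""

from __future__ import annotations

import math
from itertools import combinations, product
from statistics import mean


def _sample_var(xs) -> float:
    m = mean(xs)
    return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)


def _sample_cov(xs, ys) -> float:
    mx, my = mean(xs), mean(ys)
    return sum((x - mx) * (y - my)
               for x, y in zip(xs, ys)) / (len(xs) - 1)


def z_oracle(fr, blfr, sqrt_denominator=True):
    num = mean(fr) - mean(blfr)
    den_sq = _sample_var(fr) + _sample_var(blfr) - 2.0 * _sample_cov(fr, blfr)
    den_sq = max(den_sq, 0.0)
    if den_sq == 0.0:
        return 0.0 if num == 0.0 else None
    return num / (math.sqrt(den_sq) if sqrt_denominator else den_sq)


def rs_oracle(fr, blfr):
    return mean(f - b for f, b in zip(fr, blfr))


def dprime_oracle(fr_a, blfr_a, fr_b, blfr_b, sqrt_denominator=True):
    da = [f - b for f, b in zip(fr_a, blfr_a)]
    db = [f - b for f, b in zip(fr_b, blfr_b)]
    num = 2.0 * (mean(da) - mean(db))
    den_sq = _sample_var(da) + _sample_var(db)
    if den_sq == 0.0:
        return 0.0 if num == 0.0 else None
    return num / (math.sqrt(den_sq) if sqrt_denominator else den_sq)


def ssa_oracle(per_presentation_fr):
    first = mean(per_presentation_fr[:5])
    last = mean(per_presentation_fr[-5:])
    if first == 0.0:
        return None
    return last / first


def offset_ratio_oracle(spike_times, last_motif_end, blfr):
    if blfr == 0.0:
        return None
    count = sum(1 for t in spike_times
                if last_motif_end <= t < last_motif_end + 1.0)
    return count / 1.0 / blfr


def holm_oracle(p_values, alpha=0.05):
    """Hand-stepped Holm: walk the sorted p-values, multiply by the number
    of remaining hypotheses, enforce monotonicity, stop rejecting at the
    first failure."""
    m = len(p_values)
    indexed = sorted(enumerate(p_values), key=lambda t: t[1])
    adjusted = [0.0] * m
    reject = [False] * m
    prev = 0.0
    still_rejecting = True
    for rank, (idx, p) in enumerate(indexed):
        adj = min(max(prev, (m - rank) * p), 1.0)
        adjusted[idx] = adj
        prev = max(prev, (m - rank) * p)
        if still_rejecting and adj < alpha:
            reject[idx] = True
        else:
            still_rejecting = False
    return adjusted, reject


def exact_permutation_p(group_a, group_b):
    """Exhaustive label-split permutation p for the mean-difference statistic
    with the sign-directed tail convention.

    Returns (empirical_stat, p) for two 1-D samples.
    """
    a = list(group_a)
    b = list(group_b)
    pooled = a + b
    n_a = len(a)
    emp = mean(a) - mean(b)
    stats = []
    for idx in combinations(range(len(pooled)), n_a):
        chosen = set(idx)
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        stats.append(mean(ga) - mean(gb))
    if emp > 0:
        p = sum(1 for s in stats if s >= emp) / len(stats)
    elif emp < 0:
        p = sum(1 for s in stats if s <= emp) / len(stats)
    else:
        p = 1.0
    return emp, p


def wilcoxon_exact_oracle(x, y):
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Assumes no zero differences and no tied absolute differences (callers
    draw continuous data).  Returns (W_plus, p).
    """
    diffs = [a - b for a, b in zip(x, y) if a != b]
    n = len(diffs)
    ranked = sorted(range(n), key=lambda i: abs(diffs[i]))
    ranks = [0] * n
    for r, i in enumerate(ranked):
        ranks[i] = r + 1
    w_plus = sum(ranks[i] for i in range(n) if diffs[i] > 0)
    total = n * (n + 1) // 2
    # null distribution of W+ over all 2^n sign patterns
    null = []
    for signs in product([0, 1], repeat=n):
        null.append(sum((r + 1) for r, s in zip(range(n), signs) if s))
    lo, hi = min(w_plus, total - w_plus), max(w_plus, total - w_plus)
    extreme = sum(1 for w in null if w <= lo or w >= hi)
    return w_plus, extreme / len(null)
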