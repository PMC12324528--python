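"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's vectorized code paths: plain Python
loops, direct evaluation of the step definition, explicit prefix sums, and
exhaustive enumeration for the signed-rank test.
"""

from __future__ import annotations

from itertools import product
from typing import List, Sequence, Tuple


def brute_force_es(scores: Sequence[float], member_flags: Sequence[bool],
                   weight: float) -> Tuple[float, List[float]]:
    """Direct step evaluation + explicit prefix sums; first-max tie rule.

    ``scores`` are ordered top-to-bottom; ``member_flags[k]`` marks whether
    the k-th ranked identifier belongs to the set. Returns (es, E_1..E_n).
    """
    from math import fsum

    n = len(scores)
    m = sum(member_flags)
    assert 1 <= m < n
    denom = fsum(abs(s) ** weight for s, flag in zip(scores, member_flags) if flag)
    steps = []
    for s, flag in zip(scores, member_flags):
        if flag:
            if denom == 0:
                steps.append(1.0 / m)
            else:
                steps.append(abs(s) ** weight / denom)
        else:
            steps.append(-1.0 / (n - m))
    running = []
    total = 0.0
    for x in steps:
        total += x
        running.append(total)
    es = running[0]
    for e in running[1:]:
        if abs(e) > abs(es):
            es = e
    return es, running


def exact_wilcoxon_two_sided(diffs: Sequence[float]) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign patterns.

    Assumes no zero differences and no tied absolute values (the cases the
    package's exact path is checked on).
    """
    d = [abs(x) for x in diffs]
    assert all(x > 0 for x in d)
    order = sorted(range(len(d)), key=lambda i: d[i])
    ranks = [0] * len(d)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    w_obs = sum(r for r, x in zip(ranks, diffs) if x > 0)
    total = sum(ranks)
    w_low, w_high = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    count = 0
    for signs in product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_low or w >= w_high:
            count += 1
    return count / 2 ** len(d)


def mean_pairwise_correlation(members: Sequence[str], labels: Sequence[str],
                              r_matrix) -> float:
    """Plain double loop over unordered pairs."""
    idx = [list(labels).index(m) for m in members]
    vals = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            vals.append(float(r_matrix[idx[a], idx[b]]))
    return sum(vals) / len(vals)
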