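"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the code paths (and libraries) they check:
the U-test oracle enumerates labelings, the U null distribution uses the
classic counting recurrence, the BY oracle is an explicit double loop, and
the AUC oracle compares every (case, control) pair.
"""

from functools import lru_cache
from itertools import combinations

import numpy as np


def u_statistic_pairs(x, y) -> float:
    """U for group x: pairwise count of x > y plus half the ties."""
    x = np.asarray(x, float)[:, None]
    y = np.asarray(y, float)[None, :]
    return float((x > y).sum() + 0.5 * (x == y).sum())


def mwu_exact_p_enumeration(x, y) -> float:
    """Two-sided exact p by enumerating all C(n1+n2, n1) labelings.

    Uses the symmetric-tail definition P(|U - mu| >= |u_obs - mu|), which for
    the tie-free symmetric null equals the doubled one-tail convention.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    mu = n1 * (n - n1) / 2.0
    u_obs = u_statistic_pairs(x, y)
    dev = abs(u_obs - mu) - 1e-12
    hits = total = 0
    idx = set(range(n))
    for comb in combinations(range(n), n1):
        rest = sorted(idx - set(comb))
        u = u_statistic_pairs(pooled[list(comb)], pooled[rest])
        hits += abs(u - mu) >= dev
        total += 1
    return hits / total


@lru_cache(maxsize=None)
def _u_count(n1: int, n2: int, u: int) -> int:
    """Number of tie-free arrangements with U statistic exactly u."""
    if u < 0 or u > n1 * n2:
        return 0
    if n1 == 0 or n2 == 0:
        return 1 if u == 0 else 0
    return _u_count(n1 - 1, n2, u - n2) + _u_count(n1, n2 - 1, u)


def mwu_exact_p_recurrence(n1: int, n2: int, u_obs: float) -> float:
    """Two-sided exact p from the counting recurrence (tie-free)."""
    from math import comb

    total = comb(n1 + n2, n1)
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu) - 1e-12
    hits = sum(_u_count(n1, n2, u) for u in range(n1 * n2 + 1)
               if abs(u - mu) >= dev)
    return hits / total


def by_adjust_double_loop(p_values) -> np.ndarray:
    """BY step-up by the definition, one explicit loop per adjusted value."""
    p = np.asarray(p_values, float)
    m = p.size
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, i in enumerate(order):
        best = min(m * c_m / (j + 1) * p[order[j]] for j in range(pos, m))
        out[i] = min(1.0, best)
    return out


def auc_pairwise(scores, labels) -> float:
    """AUC by comparing every (case, control) score pair."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    s1, s0 = scores[labels == 1], scores[labels == 0]
    return u_statistic_pairs(s1, s0) / (s1.size * s0.size)
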