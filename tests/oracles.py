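"""Independent brute-force oracles used to verify the statistical core.

Everything here is deliberately naive (pairwise counting, full label
enumeration, log-gamma tail summation, hand-rolled step-up) and never
shares code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def auroc_pairwise(scores: dict[str, float], set_genes: set[str]) -> float:
    """AUROC as the exhaustive fraction of (set, background) pairs won,
    counting one half per tied pair."""
    set_vals = [v for g, v in scores.items() if g in set_genes and not np.isnan(v)]
    bg_vals = [v for g, v in scores.items() if g not in set_genes and not np.isnan(v)]
    wins = 0.0
    for s in set_vals:
        for b in bg_vals:
            if s > b:
                wins += 1.0
            elif s == b:
                wins += 0.5
    return wins / (len(set_vals) * len(bg_vals))


def mwu_enumeration(values: list[float], n_set: int, u_obs: float,
                    alternative: str = "two-sided") -> float:
    """Exact Mann-Whitney p by enumerating every labeling of the pooled
    values into a set of size n_set (requires tie-free values for the
    two-sided convention to be unambiguous)."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    for pos, i in enumerate(order, start=1):
        ranks[i] = float(pos)
    us = []
    for combo in itertools.combinations(range(n), n_set):
        u = sum(ranks[i] for i in combo) - n_set * (n_set + 1) / 2.0
        us.append(u)
    us = np.asarray(us)
    p_ge = float((us >= u_obs - 1e-9).mean())
    p_le = float((us <= u_obs + 1e-9).mean())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def bh_stepup(pvals) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        idx = order[rank_from_end - 1]
        val = p[idx] / (rank_from_end / m)
        running_min = min(running_min, val)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for hypergeometric(N, K, n) via log-binomial summation."""
    if k <= 0:
        return 1.0
    lo, hi = k, min(K, n)
    if lo > hi:
        return 0.0
    log_denominator = math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1)
    total = 0.0
    for x in range(lo, hi + 1):
        if n - x > N - K:
            continue
        log_num = (
            math.lgamma(K + 1) - math.lgamma(x + 1) - math.lgamma(K - x + 1)
            + math.lgamma(N - K + 1) - math.lgamma(n - x + 1)
            - math.lgamma(N - K - (n - x) + 1)
        )
        total += math.exp(log_num - log_denominator)
    return min(total, 1.0)


def fisher_closed_form(pvals) -> float:
    """Fisher combination via the explicit chi-square survival series.

    For even df = 2k the chi-square upper tail has the closed form
    exp(-x/2) * sum_{j<k} (x/2)^j / j!.
    """
    x2 = -2.0 * sum(math.log(p) for p in pvals)
    k = len(pvals)
    half = x2 / 2.0
    term = 1.0
    total = 1.0
    for j in range(1, k):
        term *= half / j
        total += term
    return math.exp(-half) * total
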