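"""Independent brute-force oracles for the rank tests and curve fits.

Everything here is deliberately naive (exhaustive enumeration, grid
search) and shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def midranks(values):
    """Mid-rank vector computed from scratch (no scipy)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney_exact(a, b, alternative):
    """Exact MW p-value by enumerating every group-A subset of the pool."""
    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    n_a = len(a)
    ranks = midranks(pooled)
    obs = ranks[:n_a].sum()
    total = 0
    count = 0
    for idx in combinations(range(len(pooled)), n_a):
        r = ranks[list(idx)].sum()
        total += 1
        if alternative == "less":
            count += r <= obs
        elif alternative == "greater":
            count += r >= obs
        else:
            raise ValueError(alternative)
    return count / total


def mann_whitney_exact_two_sided(a, b):
    return min(
        1.0,
        2.0
        * min(
            mann_whitney_exact(a, b, "less"),
            mann_whitney_exact(a, b, "greater"),
        ),
    )


def wilcoxon_signed_rank_exact(a, b, alternative):
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = midranks(np.abs(d))
    obs = ranks[d > 0].sum()  # W+ statistic
    count = total = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if alternative == "less":
            count += w <= obs
        elif alternative == "greater":
            count += w >= obs
        else:
            raise ValueError(alternative)
    return count / total


def kruskal_h(groups):
    """Closed-form Kruskal-Wallis H on mid-ranks, with tie correction."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = midranks(pooled)
    N = pooled.size
    h = 0.0
    start = 0
    for n in sizes:
        h += ranks[start : start + n].sum() ** 2 / n
        start += n
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    return h / correction if correction > 0 else 0.0


def grid_fit_B(t, m, lo=-1.0, hi=0.0, step=1e-5):
    """SSE grid search for the exponential decay parameter B."""
    t = np.asarray(t, dtype=float)
    m = np.asarray(m, dtype=float)
    grid = np.arange(lo, hi + step, step)
    sse = ((np.exp(np.outer(grid, t)) - m) ** 2).sum(axis=1)
    return float(grid[np.argmin(sse)])


def bh_fdr(pvals):
    """Benjamini-Hochberg adjusted p-values, textbook construction."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = n - rank_from_end
        running = min(running, p[idx] * n / k)
        adj[idx] = running
    return adj
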