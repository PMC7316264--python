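"""Independent brute-force oracles used to cross-check the fast implementations.

These deliberately use naive enumeration / textbook sums-of-squares so
they share no code path with the library.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_shortest_paths(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by enumerating every simple path."""
    n = lengths.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nodes = list(range(n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            best = np.inf
            others = [v for v in nodes if v not in (i, j)]
            for k in range(len(others) + 1):
                for mid in permutations(others, k):
                    path = (i, *mid, j)
                    total = 0.0
                    for a, b in zip(path[:-1], path[1:]):
                        total += lengths[a, b]
                        if total >= best:
                            break
                    best = min(best, total)
            d[i, j] = best
    return d


def _lengths(w: np.ndarray, cbrt: bool = False) -> np.ndarray:
    lengths = np.full_like(w, np.inf, dtype=float)
    pos = w > 0
    lengths[pos] = 1.0 / w[pos]
    np.fill_diagonal(lengths, 0.0)
    return np.cbrt(lengths) if cbrt else lengths


def brute_global_efficiency(w: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    d = brute_shortest_paths(_lengths(w))
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_local_efficiency(w: np.ndarray) -> float:
    """Weighted local efficiency, cube-root variant, by direct evaluation.

    For each node u: shortest paths among its neighbors are found on the
    neighborhood subgraph with cube-rooted edge lengths, and each ordered
    neighbor pair (j, h) contributes w_uj^(1/3) w_uh^(1/3) / d_jh.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    nodal = []
    for u in range(n):
        nbrs = [v for v in range(n) if w[u, v] > 0]
        k = len(nbrs)
        if k < 2:
            nodal.append(0.0)
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = brute_shortest_paths(_lengths(sub, cbrt=True))
        total = 0.0
        for a, j in enumerate(nbrs):
            for b, h in enumerate(nbrs):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    total += np.cbrt(w[u, j]) * np.cbrt(w[u, h]) / d[a, b]
        nodal.append(total / (k * (k - 1)))
    return float(np.mean(nodal))


def splitplot_anova_balanced(y1: np.ndarray, y2: np.ndarray, g1: np.ndarray):
    """Textbook cell-means sums-of-squares decomposition (balanced designs).

    Returns (F_group, F_time, F_interaction) for the split-plot design
    with subjects nested in group and a two-level within factor.
    """
    y = np.stack([y1, y2], axis=1)  # subjects x time
    N = y.shape[0]
    groups = np.where(g1, 0, 1)
    grand = y.mean()
    ss_a = ss_subj = ss_b = ss_ab = ss_err = 0.0
    subj_mean = y.mean(axis=1)
    time_mean = y.mean(axis=0)
    for g in (0, 1):
        sel = groups == g
        ng = sel.sum()
        gmean = y[sel].mean()
        ss_a += 2 * ng * (gmean - grand) ** 2
        ss_subj += 2 * ((subj_mean[sel] - gmean) ** 2).sum()
        for t in (0, 1):
            cell = y[sel, t].mean()
            ss_ab += ng * (cell - gmean - time_mean[t] + grand) ** 2
            ss_err += (
                (y[sel, t] - subj_mean[sel] - cell + gmean) ** 2
            ).sum()
    for t in (0, 1):
        ss_b += N * (time_mean[t] - grand) ** 2
    df_err = N - 2
    F_a = (ss_a / 1) / (ss_subj / df_err)
    F_b = (ss_b / 1) / (ss_err / df_err)
    F_ab = (ss_ab / 1) / (ss_err / df_err)
    return F_a, F_b, F_ab
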