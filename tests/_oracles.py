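"""Independent brute-force oracles used only by the test suite.

Every function here recomputes a quantity by direct enumeration or naive
looping, deliberately avoiding the code paths of the package itself.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np


def two_loop_pair_tally(bins_j: Sequence[int], bins_k: Sequence[int], n_bins: int):
    """Naive double-loop joint tally of two bin columns (sentinels excluded)."""
    grid = [[0] * n_bins for _ in range(n_bins)]
    total = 0
    for a, b in zip(bins_j, bins_k):
        if a >= 0 and b >= 0:
            grid[a][b] += 1
            total += 1
    return grid, total


def double_loop_mi(grid: Sequence[Sequence[int]]) -> float:
    """Plug-in mutual information in bits, computed with explicit loops."""
    total = sum(sum(row) for row in grid)
    row_sums = [sum(row) for row in grid]
    col_sums = [sum(col) for col in zip(*grid)]
    mi = 0.0
    for a, row in enumerate(grid):
        for b, c in enumerate(row):
            if c > 0:
                p = c / total
                mi += p * math.log2(p / ((row_sums[a] / total) * (col_sums[b] / total)))
    return mi


def prufer_to_edges(seq: Sequence[int], n: int) -> list[tuple[int, int]]:
    """Decode a Pruefer sequence into the edge list of a labeled tree."""
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    edges = []
    seq = list(seq)
    for x in seq:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((min(leaf, x), max(leaf, x)))
                degree[leaf] -= 1
                degree[x] -= 1
                break
    u, v = [i for i in range(n) if degree[i] == 1]
    edges.append((u, v))
    return edges


def all_spanning_trees(n: int) -> Iterable[list[tuple[int, int]]]:
    """All n^(n-2) labeled spanning trees on n nodes (Cayley's formula)."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        yield prufer_to_edges(seq, n)


def best_tree_total_mi(mi: dict[tuple[int, int], float], n: int) -> float:
    """Maximum total MI over every spanning tree, by exhaustive enumeration."""
    return max(
        sum(mi[e] for e in tree) for tree in all_spanning_trees(n)
    )


def pair_count_auc(pos: Sequence[float], neg: Sequence[float]) -> float:
    """AUC as the fraction of (pos, neg) pairs with pos > neg (ties 1/2)."""
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pair_count_u(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Mann-Whitney U of the first group by direct pair counting."""
    return pair_count_auc(pos, neg) * len(pos) * len(neg)


def permutation_mwu_p(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p-value by enumerating all label splits."""
    pooled = list(pos) + list(neg)
    n1 = len(pos)
    mu = n1 * len(neg) / 2.0
    u_obs = pair_count_u(pos, neg)
    dev = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        in_pos = set(comb)
        grp1 = [pooled[i] for i in comb]
        grp2 = [pooled[i] for i in range(len(pooled)) if i not in in_pos]
        u = pair_count_u(grp1, grp2)
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def tree_support_and_probability(
    training_bins: np.ndarray,
    root: int,
    parents: dict[int, int],
    pattern: Sequence[int],
) -> float:
    """Tree-factorized probability of one bin pattern, from first principles.

    Counts are tallied by explicit loops over the training cells; the
    probability is the root relative frequency times one conditional
    relative frequency per (child, parent) pair, zero whenever any required
    count is zero.
    """
    n = len(training_bins)
    root_count = sum(1 for row in training_bins if row[root] == pattern[root])
    if root_count == 0:
        return 0.0
    prob = root_count / n
    for child, parent in parents.items():
        joint = sum(
            1
            for row in training_bins
            if row[child] == pattern[child] and row[parent] == pattern[parent]
        )
        parent_count = sum(1 for row in training_bins if row[parent] == pattern[parent])
        if joint == 0 or parent_count == 0:
            return 0.0
        prob *= joint / parent_count
    return prob
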