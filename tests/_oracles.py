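"""Independent brute-force oracles for the test suite.

These are direct recursive transcriptions of the scoring definitions
(max over all alignments, with a stop option for local mode), kept free
of the package's vectorized DP so the two routes stay independent.
Gap convention matches the package: a gap of length L costs
open + (L - 1) * extend.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np


def brute_global_score(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score over a cell-score matrix."""
    m, n = S.shape

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == m and j == n:
            return 0.0
        options = []
        if i < m and j < n:
            options.append(S[i, j] + best(i + 1, j + 1, "M"))
        if i < m:
            cost = gap_extend if prev == "X" else gap_open
            options.append(-cost + best(i + 1, j, "X"))
        if j < n:
            cost = gap_extend if prev == "Y" else gap_open
            options.append(-cost + best(i, j + 1, "Y"))
        return max(options)

    return float(best(0, 0, "M"))


def brute_local_score(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score: max over all start cells and all paths,
    stopping anywhere; never below zero."""
    m, n = S.shape

    @lru_cache(maxsize=None)
    def ahead(i: int, j: int, prev: str) -> float:
        options = [0.0]  # stop here
        if i < m and j < n:
            options.append(S[i, j] + ahead(i + 1, j + 1, "M"))
        if i < m:
            cost = gap_extend if prev == "X" else gap_open
            options.append(-cost + ahead(i + 1, j, "X"))
        if j < n:
            cost = gap_extend if prev == "Y" else gap_open
            options.append(-cost + ahead(i, j + 1, "Y"))
        return max(options)

    best = 0.0
    for i in range(m):
        for j in range(n):
            # a local alignment must begin with a matched pair
            best = max(best, S[i, j] + ahead(i + 1, j + 1, "M"))
    return float(best)


def count_walker_a(protein: str) -> int:
    """Sliding-window scan for [AG]xxxxGK[ST], counting all windows."""
    count = 0
    for i in range(len(protein) - 7):
        w = protein[i : i + 8]
        if w[0] in "AG" and w[5] == "G" and w[6] == "K" and w[7] in "ST":
            count += 1
    return count


def trim_keep_mask(rows: list[str], max_gap: float) -> list[bool]:
    """Per-column gap count filter, written independently."""
    n_rows = len(rows)
    keep = []
    for j in range(len(rows[0]) if rows else 0):
        gaps = sum(1 for r in rows if r[j] == "-")
        keep.append(gaps / n_rows <= max_gap)
    return keep


def tree_path_distances(tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length distances of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    names = [t.label for t in taxa]
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return names, D
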