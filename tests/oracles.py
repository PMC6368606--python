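"""Independent oracles used by the test suite.

These re-derive expected values by brute force (dynamic programming,
enumeration) without touching the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 11.0
GAP_EXTEND = 1.0


def sw_score(a: str, b: str) -> float:
    """Smith-Waterman local alignment score, Gotoh affine gaps (open 11, extend 1),
    BLOSUM62 — a plain O(nm) dynamic program."""
    n, m = len(a), len(b)
    neg = -1e9
    M = np.zeros((n + 1, m + 1))  # ends in a substitution column
    X = np.full((n + 1, m + 1), neg)  # ends with gap in b (consumes a)
    Y = np.full((n + 1, m + 1), neg)  # ends with gap in a (consumes b)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1]][b[j - 1]]
            M[i, j] = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - GAP_OPEN, X[i - 1, j] - GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] - GAP_OPEN, Y[i, j - 1] - GAP_EXTEND)
            best = max(best, M[i, j], X[i, j], Y[i, j])
    return best


def hamming_identity(a: str, b: str) -> float:
    """Positional identity of equal-length sequences."""
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def expected_richness_enumeration(counts: list[int], depth: int) -> float:
    """Exact expectation of distinct families in a depth-d subsample, by
    enumerating every subset of the expanded protein list (tiny inputs only)."""
    labels = [i for i, c in enumerate(counts) for _ in range(c)]
    n = len(labels)
    total_subsets = comb(n, depth)
    acc = 0
    for subset in combinations(range(n), depth):
        acc += len({labels[i] for i in subset})
    return acc / total_subsets


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, intercept) from the closed-form normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[1]), float(beta[0])


def tree_branch_fraction_bruteforce(dendropy_tree, tips: set[str], mode: str) -> float:
    """Enumerate every edge; build its descendant tip set with dendropy's own
    leaf_nodes(); sum qualifying lengths over the tree's total length."""
    total = 0.0
    contributed = 0.0
    seed = dendropy_tree.seed_node
    for node in dendropy_tree.preorder_node_iter():
        if node is seed:
            continue
        length = node.edge.length or 0.0
        total += length
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if mode == "exclusive":
            if below <= tips:
                contributed += length
        else:
            if node.is_leaf() and node.taxon.label in tips:
                contributed += length
    return contributed / total if total else 0.0
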