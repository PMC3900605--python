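"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the local
alignment oracle is a full dynamic-programming scan over all cells (no
seeding, no diagonal bookkeeping), and the agreement-subtree oracle
enumerates leaf subsets directly, comparing induced bipartition sets.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def dp_best_ungapped_score(a: str, b: str, match: int = 1, mismatch: int = -2) -> int:
    """Exact best ungapped local alignment score by full DP:
    H[i,j] = max(0, H[i-1,j-1] + s(a_i, b_j)), maximized over all cells."""
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    best = 0
    prev = np.zeros(len(y) + 1, dtype=np.int64)
    for i in range(len(x)):
        s = np.where(y == x[i], match, mismatch)
        cur = np.zeros(len(y) + 1, dtype=np.int64)
        cur[1:] = np.maximum(0, prev[:-1] + s)
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def dp_best_ungapped_score_both_strands(a: str, b: str) -> int:
    rc = a.translate(_COMPLEMENT)[::-1]
    return max(dp_best_ungapped_score(a, b), dp_best_ungapped_score(rc, b))


# ---------------------------------------------------------------------------
# brute-force maximum agreement subtree


def _edge_masks(tree, label_index: dict[str, int]) -> list[int]:
    """Leaf bitmask on the child side of every edge of a dendropy tree."""
    masks = []
    node_mask: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_mask[id(node)] = 1 << label_index[node.taxon.label]
        else:
            node_mask[id(node)] = 0
            for c in node.child_nodes():
                node_mask[id(node)] |= node_mask[id(c)]
        if node.parent_node is not None:
            masks.append(node_mask[id(node)])
    return masks


def _induced_splits(masks: list[int], subset: int) -> frozenset[int]:
    splits = set()
    for m in masks:
        x = m & subset
        y = subset & ~x
        if bin(x).count("1") >= 2 and bin(y).count("1") >= 2:
            splits.add(min(x, y))
    return frozenset(splits)


def brute_force_mast(tree_a, tree_b) -> int:
    """Largest leaf subset on which both trees induce the same unrooted
    topology, by enumerating subsets in decreasing size."""
    labels = sorted(
        {t.label for t in tree_a.taxon_namespace}
        & {t.label for t in tree_b.taxon_namespace}
    )
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    ma = _edge_masks(tree_a, index)
    mb = _edge_masks(tree_b, index)
    for size in range(n, 2, -1):
        for combo in combinations(range(n), size):
            subset = 0
            for i in combo:
                subset |= 1 << i
            if _induced_splits(ma, subset) == _induced_splits(mb, subset):
                return size
    return min(n, 3)
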