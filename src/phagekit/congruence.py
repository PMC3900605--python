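"""Maximum agreement subtree (MAST) computation and the congruence index.

The MAST of two unrooted leaf-labelled trees is the largest leaf subset on
which both trees induce identical topologies (branch lengths ignored). The
congruence index divides the observed MAST size by its expectation under a
Monte-Carlo null of independent uniform random binary topologies (PDA model)
on the same leaf set; an index above 1 with a small permutation p-value means
the trees agree more than chance allows.

The DP computes rooted MAST values for every pair of directed edges (each
directed edge (u, v) denotes the subtree on the v side, viewed from u) and
combines the two directions of an edge pair, which maximizes the rooted MAST
over all edge-rootings of both trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class CongruenceResult:
    n_common_leaves: int
    mast_size: int
    icong: float
    p_value: float
    null_reps: int
    seed: int
    null_mean: float


class LightTree:
    """Unrooted tree as adjacency lists with leaves mapped to label indices.

    Degree-2 internal nodes (e.g. rooting knuckles left by restriction) are
    suppressed on construction.
    """

    def __init__(self, adj: dict[int, list[int]], leaf_ix: dict[int, int]):
        self._splice(adj, leaf_ix)
        self._build_edges()

    def _splice(self, adj: dict[int, list[int]], leaf_ix: dict[int, int]) -> None:
        adj = {u: set(vs) for u, vs in adj.items()}
        changed = True
        while changed:
            changed = False
            for u in list(adj):
                if u in leaf_ix or u not in adj:
                    continue
                if len(adj[u]) == 2:
                    a, b = adj[u]
                    adj[a].discard(u)
                    adj[b].discard(u)
                    adj[a].add(b)
                    adj[b].add(a)
                    del adj[u]
                    changed = True
                elif len(adj[u]) == 1:  # unlabelled pendant left by restriction
                    (a,) = adj[u]
                    adj[a].discard(u)
                    del adj[u]
                    changed = True
        remap = {u: i for i, u in enumerate(sorted(adj))}
        self.adj = {remap[u]: sorted(remap[v] for v in vs) for u, vs in adj.items()}
        self.leaf_ix = {remap[u]: ix for u, ix in leaf_ix.items() if u in remap}

    def _build_edges(self) -> None:
        edges = []
        eid = {}
        for u in sorted(self.adj):
            for v in self.adj[u]:
                eid[(u, v)] = len(edges)
                edges.append((u, v))
        self.edges = edges
        self.eid = eid
        n_e = len(edges)
        self.children: list[list[int]] = [[] for _ in range(n_e)]
        self.leafmask = [0] * n_e
        self.leaf_of_edge = [-1] * n_e
        self.size = [0] * n_e
        # compute sizes/masks bottom-up
        done = [False] * n_e
        stack = list(range(n_e))
        while stack:
            e = stack.pop()
            if done[e]:
                continue
            u, v = self.edges[e]
            kids = [self.eid[(v, w)] for w in self.adj[v] if w != u]
            if v in self.leaf_ix:
                self.leafmask[e] = 1 << self.leaf_ix[v]
                self.leaf_of_edge[e] = self.leaf_ix[v]
                self.size[e] = 1
                self.children[e] = []
                done[e] = True
                continue
            if all(done[k] for k in kids):
                self.children[e] = kids
                self.leafmask[e] = 0
                for k in kids:
                    self.leafmask[e] |= self.leafmask[k]
                self.size[e] = sum(self.size[k] for k in kids)
                done[e] = True
            else:
                stack.append(e)
                stack.extend(k for k in kids if not done[k])
        self.order = sorted(range(n_e), key=lambda e: self.size[e])

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ix)


def _from_dendropy(tree: dendropy.Tree, label_index: dict[str, int]) -> LightTree:
    adj: dict[int, list[int]] = {}
    leaf_ix: dict[int, int] = {}
    ids = {}

    def nid(node) -> int:
        if id(node) not in ids:
            ids[id(node)] = len(ids)
            adj[ids[id(node)]] = []
        return ids[id(node)]

    for node in tree.preorder_node_iter():
        u = nid(node)
        if node.taxon is not None and node.is_leaf():
            if node.taxon.label in label_index:
                leaf_ix[u] = label_index[node.taxon.label]
        for child in node.child_nodes():
            v = nid(child)
            adj[u].append(v)
            adj[v].append(u)
    return LightTree(adj, leaf_ix)


def _restrict(tree: dendropy.Tree, labels: list[str]) -> LightTree:
    keep = set(labels)
    pruned = tree.extract_tree_with_taxa_labels(labels=keep)
    return _from_dendropy(pruned, {lab: i for i, lab in enumerate(sorted(keep))})


def _matching_max(M: np.ndarray, ca: list[int], cb: list[int]) -> int:
    if len(ca) > len(cb):
        ca, cb = cb, ca
        sub = M.T
    else:
        sub = M
    best = 0
    for perm in itertools.permutations(cb, len(ca)):
        s = sum(int(sub[a, b]) for a, b in zip(ca, perm))
        if s > best:
            best = s
    return best


def _mast_light(ta: LightTree, tb: LightTree) -> int:
    na, nb = len(ta.edges), len(tb.edges)
    M = np.zeros((na, nb), dtype=np.int32)
    for a in ta.order:
        la = ta.leaf_of_edge[a]
        ca = ta.children[a]
        mask_a = ta.leafmask[a]
        for b in tb.order:
            lb = tb.leaf_of_edge[b]
            if la >= 0 and lb >= 0:
                M[a, b] = 1 if la == lb else 0
            elif la >= 0:
                M[a, b] = 1 if (tb.leafmask[b] >> la) & 1 else 0
            elif lb >= 0:
                M[a, b] = 1 if (mask_a >> lb) & 1 else 0
            else:
                cb = tb.children[b]
                best = _matching_max(M, ca, cb)
                for k in ca:
                    if M[k, b] > best:
                        best = M[k, b]
                for k in cb:
                    if M[a, k] > best:
                        best = M[a, k]
                M[a, b] = best
    best = 0
    for (u, v), a in ta.eid.items():
        ra = ta.eid[(v, u)]
        for (x, y), b in tb.eid.items():
            total = int(M[a, b]) + int(M[ra, tb.eid[(y, x)]])
            if total > best:
                best = total
    return best


def shared_leaf_labels(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> list[str]:
    la = {t.label for t in tree_a.taxon_namespace if t.label}
    lb = {t.label for t in tree_b.taxon_namespace if t.label}
    return sorted(la & lb)


def mast_size(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Size of the maximum agreement subtree of two unrooted trees,
    computed on their shared leaf labels (at least 3 required)."""
    shared = shared_leaf_labels(tree_a, tree_b)
    if len(shared) < 3:
        raise ValueError("trees share fewer than 3 leaf labels")
    ta = _restrict(tree_a, shared)
    tb = _restrict(tree_b, shared)
    return _mast_light(ta, tb)


# ---------------------------------------------------------------------------
# random topologies and the congruence index


def _random_light_tree(n_leaves: int, rng: np.random.Generator) -> LightTree:
    """Uniform random unrooted binary labelled topology (PDA model), built by
    attaching each new leaf to a uniformly chosen existing edge."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    adj = {0: [1], 1: [0]}
    leaf_ix = {0: 0, 1: 1}
    edges = [(0, 1)]
    next_id = 2
    for leaf in range(2, n_leaves):
        u, v = edges[int(rng.integers(0, len(edges)))]
        mid, newleaf = next_id, next_id + 1
        next_id += 2
        adj[u] = [x if x != v else mid for x in adj[u]]
        adj[v] = [x if x != u else mid for x in adj[v]]
        adj[mid] = [u, v, newleaf]
        adj[newleaf] = [mid]
        leaf_ix[newleaf] = leaf
        edges.remove((u, v))
        edges.extend([(u, mid), (mid, v), (mid, newleaf)])
    return LightTree(adj, leaf_ix)


def random_binary_tree(labels: list[str], seed: int = 0) -> dendropy.Tree:
    """Uniform (PDA) random unrooted binary tree over ``labels`` as a
    dendropy tree with unit branch lengths."""
    rng = np.random.default_rng(seed)
    lt = _random_light_tree(len(labels), rng)
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    # root arbitrarily at an internal node
    internal = [u for u in lt.adj if u not in lt.leaf_ix]
    root_u = internal[0] if internal else 0
    nodes = {root_u: tree.seed_node}
    stack = [root_u]
    seen = {root_u}
    while stack:
        u = stack.pop()
        for v in lt.adj[u]:
            if v in seen:
                continue
            seen.add(v)
            child = nodes[u].new_child(edge_length=1.0)
            if v in lt.leaf_ix:
                child.taxon = taxa.get_taxon(labels[lt.leaf_ix[v]])
            nodes[v] = child
            stack.append(v)
    tree.is_rooted = False
    return tree


def mast_null_distribution(
    n_leaves: int, reps: int, seed: int = 0
) -> np.ndarray:
    """MAST sizes for ``reps`` independent pairs of uniform random binary
    topologies on the same ``n_leaves`` labels."""
    rng = np.random.default_rng(seed)
    sizes = np.empty(reps, dtype=np.int32)
    for r in range(reps):
        ta = _random_light_tree(n_leaves, rng)
        tb = _random_light_tree(n_leaves, rng)
        sizes[r] = _mast_light(ta, tb)
    return sizes


def icong(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    null_reps: int = 1000,
    seed: int = 0,
    null_sizes: np.ndarray | None = None,
) -> CongruenceResult:
    """Congruence index: observed MAST size over its Monte-Carlo null mean.

    The null is the MAST size of independent uniform random binary topologies
    (PDA) on the same leaf set; ``null_sizes`` may be supplied to reuse a
    precomputed null (it depends only on the leaf count). The p-value uses
    the add-one permutation convention, so it is never exactly zero.
    """
    shared = shared_leaf_labels(tree_a, tree_b)
    obs = mast_size(tree_a, tree_b)
    if null_sizes is None:
        null_sizes = mast_null_distribution(len(shared), null_reps, seed)
    else:
        null_sizes = np.asarray(null_sizes)
        null_reps = len(null_sizes)
    null_mean = float(null_sizes.mean())
    p = (1 + int((null_sizes >= obs).sum())) / (null_reps + 1)
    return CongruenceResult(
        n_common_leaves=len(shared),
        mast_size=obs,
        icong=obs / null_mean,
        p_value=p,
        null_reps=null_reps,
        seed=seed,
        null_mean=null_mean,
    )
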