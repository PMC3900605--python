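"""Neighbor-joining tree construction, patristic distances, and the
group-separation statistic.

The separation criterion mirrors the phylogenomic argument for a distinct
phage group: two groups are "separated" on a tree when the mean patristic
distance between them exceeds the greatest within-group patristic distance
of either group.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .similarity import DistanceMatrix


@dataclass
class PatristicMatrix:
    labels: list[str]
    values: np.ndarray

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class SeparationReport:
    """Within-group maxima, between-group means, and separation flags."""

    within_max: dict[str, float]
    between_mean: dict[tuple[str, str], float]
    separated: dict[tuple[str, str], bool]


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Q-criterion ties are broken by the lexicographically smallest label pair;
    negative branch lengths are clamped to zero with the deficit moved to the
    sister branch. The returned tree is unrooted (trifurcating root).
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    d = dist.values.astype(float).copy()
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")

    taxa = dendropy.TaxonNamespace(dist.labels)
    nodes: list[dendropy.Node] = []
    for lab in dist.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes.append(node)
    names = list(dist.labels)  # sort key for tie-breaking

    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((names[active[i]], names[active[j]])) ), (i, j))
            for i, j in ties
            if i < j
        )[1]
        i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = dendropy.Node()
        ni, nj_ = nodes[ai], nodes[aj]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = li
        nj_.edge.length = lj

        # distances from the new node to the remaining taxa
        new_row = np.zeros(len(d) + 1)
        for kk in active:
            if kk in (ai, aj):
                continue
            new_row[kk] = 0.5 * (d[ai, kk] + d[aj, kk] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row) - 1] = new_row[:-1]
        d[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        names.append(min(names[ai], names[aj]))
        active = [a for a in active if a not in (ai, aj)] + [len(d) - 1]

    # join the final two (or three, via the trifurcating root)
    tree = dendropy.Tree(taxon_namespace=taxa)
    a, b = active
    dab = max(d[a, b], 0.0)
    root = tree.seed_node
    for node, bl in ((nodes[a], dab / 2.0), (nodes[b], dab / 2.0)):
        root.add_child(node)
        node.edge.length = bl
    # collapse to the conventional unrooted form: if one child is internal,
    # merge the root edge onto a single branch of length dab
    kids = root.child_nodes()
    internal = [k for k in kids if not k.is_leaf()]
    if internal:
        keep = internal[0]
        other = kids[0] if kids[1] is keep else kids[1]
        other.edge.length = dab
        keep_children = list(keep.child_nodes())
        root.remove_child(keep)
        for c in keep_children:
            bl = c.edge.length
            root.add_child(c)
            c.edge.length = bl
    tree.is_rooted = False
    return tree


def patristic_matrix(tree: dendropy.Tree) -> PatristicMatrix:
    """Sum of branch lengths along the leaf-to-leaf path, for all pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return PatristicMatrix(labels=labels, values=vals)


def group_separation(pm: PatristicMatrix, groups: dict[str, str]) -> SeparationReport:
    """Compare within-group maxima against between-group mean patristic
    distances.

    A pair of groups is separated when the mean distance between them exceeds
    the greater of the two within-group maxima (conservative reading).
    Singleton groups have within-max 0 and participate only through
    between-group means.
    """
    labels = pm.labels
    missing = [l for l in labels if l not in groups]
    if missing:
        raise ValueError(f"no group label for leaves: {missing}")
    group_names = sorted(set(groups[l] for l in labels))
    members = {g: [l for l in labels if groups[l] == g] for g in group_names}

    within_max: dict[str, float] = {}
    for g, mem in members.items():
        dmax = 0.0
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                dmax = max(dmax, pm.loc(mem[i], mem[j]))
        within_max[g] = dmax

    between_mean: dict[tuple[str, str], float] = {}
    separated: dict[tuple[str, str], bool] = {}
    for gi in range(len(group_names)):
        for gj in range(gi + 1, len(group_names)):
            g, h = group_names[gi], group_names[gj]
            ds = [pm.loc(a, b) for a in members[g] for b in members[h]]
            mean_bt = float(np.mean(ds))
            between_mean[(g, h)] = mean_bt
            separated[(g, h)] = mean_bt > max(within_max[g], within_max[h])
    return SeparationReport(
        within_max=within_max, between_mean=between_mean, separated=separated
    )


def is_monophyletic(tree: dendropy.Tree, leaf_labels: set[str]) -> bool:
    """Whether a leaf set forms a clade on the unrooted tree, i.e. some edge
    bipartition splits exactly this set from the rest."""
    all_labels = {t.label for t in tree.taxon_namespace}
    if not leaf_labels <= all_labels:
        raise ValueError("labels not on tree")
    if len(leaf_labels) in (0, 1) or leaf_labels == all_labels:
        return True
    tree.encode_bipartitions()
    target = frozenset(leaf_labels)
    complement = frozenset(all_labels - leaf_labels)
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(
            t.label for t in edge.bipartition.leafset_taxa(tree.taxon_namespace)
        )
        if side == target or side == complement:
            return True
    return False


def alignment_distance_matrix(alignment: dict[str, str], alphabet_size: int = 20) -> DistanceMatrix:
    """Poisson-corrected p-distances from an (gap-free) alignment.

    Uses the k-state Jukes-Cantor form d = -((k-1)/k) ln(1 - k p / (k-1)),
    which is additive under the uniform-replacement substitution process the
    marker simulator uses; saturated pairs are clamped just below the
    singularity.
    """
    labels = sorted(alignment)
    seqs = [np.frombuffer(alignment[l].encode(), dtype=np.uint8) for l in labels]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("alignment sequences must have equal length")
    k = alphabet_size
    n = len(labels)
    vals = np.zeros((n, n))
    pmax = (k - 1) / k * 0.9999
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(seqs[i] != seqs[j]))
            p = min(p, pmax)
            dist = -(k - 1) / k * np.log(1 - k * p / (k - 1))
            vals[i, j] = vals[j, i] = dist
    return DistanceMatrix(labels=labels, values=vals)
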