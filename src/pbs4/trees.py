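"""Rooted trees: UPGMA inference, majority-rule consensus, Robinson–Foulds.

All tie-breaking is lexicographic on sorted leaf-label tuples so that runs
are bit-reproducible across platforms.  The Robinson–Foulds distance here
is the rooted-clade version: the number of nontrivial clades present in
exactly one of the two trees (0, 2 or 4 for binary four-taxon trees).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RootedTree:
    """Rooted tree node with branch lengths and optional clade support.

    Leaves carry ``label``; internal nodes carry ``children``.  ``length``
    is the branch above the node (None at the root of unscaled trees);
    ``support`` is the clade frequency in [0, 1] for consensus trees.
    """

    label: str | None = None
    children: tuple["RootedTree", ...] = ()
    length: float | None = None
    support: float | None = None
    _clade: frozenset = field(default=None, repr=False, compare=False)

    def is_leaf(self) -> bool:
        return not self.children

    @property
    def clade(self) -> frozenset:
        if self._clade is None:
            if self.is_leaf():
                self._clade = frozenset({self.label})
            else:
                self._clade = frozenset().union(*(c.clade for c in self.children))
        return self._clade

    def leaf_labels(self) -> frozenset:
        return self.clade

    def nodes(self):
        yield self
        for c in self.children:
            yield from c.nodes()

    def clades(self, nontrivial: bool = True) -> set[frozenset]:
        """Clades of the tree; by default excluding single leaves and the
        full leaf set."""
        all_clades = {n.clade for n in self.nodes()}
        if nontrivial:
            full = self.clade
            all_clades = {c for c in all_clades if len(c) > 1 and c != full}
        return all_clades

    def newick(self, lengths: bool = True, supports: bool = True) -> str:
        return self._newick_node(lengths, supports) + ";"

    def _newick_node(self, lengths, supports) -> str:
        if self.is_leaf():
            s = self.label
        else:
            kids = sorted(self.children, key=lambda c: min(c.clade))
            s = "(" + ",".join(c._newick_node(lengths, supports) for c in kids) + ")"
            if supports and self.support is not None:
                s += format(self.support, "g")
        if lengths and self.length is not None:
            s += f":{self.length:g}"
        return s

    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        """Parse a Newick string (dendropy does the parsing); internal node
        labels are read as support values when numeric."""
        import dendropy

        t = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )

        def convert(node) -> "RootedTree":
            if node.is_leaf():
                return cls(label=node.taxon.label, length=node.edge.length)
            support = None
            if node.label is not None:
                try:
                    support = float(node.label)
                except ValueError:
                    pass
            return cls(
                children=tuple(convert(c) for c in node.child_nodes()),
                length=node.edge.length,
                support=support,
            )

        return convert(t.seed_node)

    def root_to_leaf_depths(self) -> dict[str, float]:
        depths = {}

        def walk(node, depth):
            d = depth + (node.length or 0.0)
            if node.is_leaf():
                depths[node.label] = d
            for c in node.children:
                walk(c, d)

        walk(self, -(self.length or 0.0))
        return depths


def upgma(distances, labels=None) -> RootedTree:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    ``distances`` is a symmetric non-negative matrix (ndarray or DataFrame;
    labels taken from a DataFrame's index when not given).  Ties in the
    minimum pairwise distance are broken lexicographically by the sorted
    leaf-label tuple of the would-be merged cluster, so the output is
    deterministic.  The result is ultrametric: every leaf lies at the same
    depth (half the final merge distance).
    """
    if isinstance(distances, pd.DataFrame):
        if labels is None:
            labels = list(distances.index)
        distances = distances.to_numpy(dtype=float)
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if labels is None or len(labels) != n:
        raise ValueError("labels must match the matrix dimension")
    if n < 3:
        raise ValueError("need at least 3 labels")
    if not np.allclose(d, d.T) or np.any(np.isnan(d)) or np.any(d < 0):
        raise ValueError("distances must be symmetric, finite and >= 0")

    # active clusters: key -> (node, height, size, sorted label tuple)
    clusters = {
        i: (RootedTree(label=lab), 0.0, 1, (lab,)) for i, lab in enumerate(labels)
    }
    dist = {
        frozenset({i, j}): float(d[i, j])
        for i, j in itertools.combinations(range(n), 2)
    }
    next_key = n
    while len(clusters) > 1:
        best = min(
            (
                (dist[frozenset({i, j})], tuple(sorted(clusters[i][3] + clusters[j][3])), i, j)
                for i, j in itertools.combinations(sorted(clusters), 2)
            ),
        )
        dmin, merged_labels, i, j = best
        node_i, h_i, size_i, _ = clusters[i]
        node_j, h_j, size_j, _ = clusters[j]
        height = dmin / 2.0
        node_i.length = height - h_i
        node_j.length = height - h_j
        new_node = RootedTree(children=(node_i, node_j))
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[frozenset({i, k})]
            djk = dist[frozenset({j, k})]
            dist[frozenset({next_key, k})] = (size_i * dik + size_j * djk) / (
                size_i + size_j
            )
        del clusters[i], clusters[j]
        clusters[next_key] = (new_node, height, size_i + size_j, merged_labels)
        next_key += 1
    (root, _, _, _) = next(iter(clusters.values()))
    return root


def _compatible(clade: frozenset, accepted) -> bool:
    return all(
        clade.isdisjoint(c) or clade <= c or c <= clade for c in accepted
    )


def _tree_from_clades(leaf_set: frozenset, clades, supports) -> RootedTree:
    """Assemble a rooted tree from a laminar family of nontrivial clades."""

    def build(members: frozenset, available: list[frozenset]) -> RootedTree:
        # maximal accepted clades strictly inside `members` become children
        inside = [c for c in available if c < members]
        maximal = [c for c in inside if not any(c < o for o in inside)]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        children = [build(c, [o for o in inside if o < c]) for c in maximal]
        children += [RootedTree(label=l) for l in sorted(members - covered)]
        children.sort(key=lambda c: min(c.clade))
        node = RootedTree(children=tuple(children))
        node.support = supports.get(members)
        return node

    return build(leaf_set, list(clades))


def majority_consensus(trees) -> RootedTree:
    """Greedy majority-rule (extended) consensus with clade support.

    Nontrivial clades are tallied across all gene trees and considered in
    decreasing frequency order (ties broken by larger clade first, then
    lexicographically by sorted labels); a clade is accepted when it is
    compatible with every clade already accepted.  Clades in a strict
    majority (>50%) are always mutually compatible and hence always
    included.  Node support is the clade's frequency among all input
    trees.  The consensus carries supports but no branch lengths.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    leaf_set = trees[0].clade
    for t in trees[1:]:
        if t.clade != leaf_set:
            raise ValueError("trees have inconsistent leaf sets")

    counts: dict[frozenset, int] = {}
    for t in trees:
        for c in t.clades():
            counts[c] = counts.get(c, 0) + 1

    order = sorted(
        counts, key=lambda c: (-counts[c], -len(c), tuple(sorted(c)))
    )
    accepted: list[frozenset] = []
    for c in order:
        if _compatible(c, accepted):
            accepted.append(c)
    supports = {c: counts[c] / len(trees) for c in accepted}
    supports[leaf_set] = 1.0
    return _tree_from_clades(leaf_set, accepted, supports)


def rf_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Robinson–Foulds distance between rooted trees on one leaf set: the
    number of nontrivial clades unique to either tree (an even integer;
    0 when topologies are identical)."""
    if t1.clade != t2.clade:
        raise ValueError("trees must share the same leaf set")
    return len(t1.clades() ^ t2.clades())
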