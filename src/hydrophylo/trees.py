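"""Phylogeny handling: Newick I/O, ultrametric Yule simulation and the
phylogenetic covariance matrix.

Trees are plain :class:`dendropy.Tree` objects throughout the package; the
helpers here add the few comparative-methods primitives dendropy does not
ship: the Brownian-motion covariance matrix ``V`` (shared root-to-MRCA path
lengths, with Pagel's lambda scaling of the off-diagonal), a seeded pure-birth
simulator producing depth-normalised ultrametric trees, and the root
bipartition used to assign a two-clade (subgenus-like) factor.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "read_tree",
    "write_tree",
    "tip_labels",
    "phylo_covariance",
    "simulate_yule_tree",
    "root_bipartition",
    "prune_to_taxa",
]


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Polytomies are allowed and zero-length branches preserved.  Raises
    ``ValueError`` with context if the file cannot be parsed or any internal
    edge lacks a length.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"could not parse Newick tree at {path}: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"tree at {path}: edge above "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else 'an internal node'}"
                " has no branch length")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {tree.seed_node: float(tree.seed_node.edge.length or 0.0)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[node] = depths[node.parent_node] + float(node.edge.length or 0.0)
    return depths


def phylo_covariance(
    tree: dendropy.Tree,
    lam: float = 1.0,
    order: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of the tips.

    ``V[i, j]`` is the root-to-MRCA path length for ``i != j`` multiplied by
    ``lam`` (Pagel's lambda), and the root-to-tip path length on the
    diagonal.  For ``lam`` in [0, 1] on a tree with non-negative branch
    lengths the result is symmetric positive semi-definite.

    Returns ``(V, labels)`` with rows/columns ordered by ``order`` when
    given, else by leaf iteration order.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if not tree.is_rooted:
        raise ValueError("phylogenetic covariance requires a rooted tree")
    depths = _node_depths(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    for lf in leaves:
        V[index[lf], index[lf]] = depths[lf]

    def collect(node) -> list[int]:
        if node.is_leaf():
            return [index[node]]
        groups = [collect(ch) for ch in node.child_nodes()]
        d = depths[node]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        V[i, j] = V[j, i] = d
        merged: list[int] = []
        for g in groups:
            merged.extend(g)
        return merged

    collect(tree.seed_node)
    off = ~np.eye(n, dtype=bool)
    V[off] *= lam
    if order is not None:
        order = list(order)
        if set(order) != set(labels):
            raise ValueError("order must be a permutation of the tip labels")
        perm = [labels.index(name) for name in order]
        V = V[np.ix_(perm, perm)]
        labels = order
    return V, labels


def simulate_yule_tree(n_taxa: int, seed: int, depth: float = 1.0) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree, rescaled to total depth ``depth``.

    The process starts from the root split (two lineages), waits
    Exp(k)-distributed times between successive splits while k lineages are
    active, and adds a final Exp(n) stretch before the present so terminal
    branches are never zero.  All root-to-tip paths are equal by
    construction.  Deterministic in ``seed``.
    """
    if n_taxa < 3:
        raise ValueError(f"n_taxa must be >= 3, got {n_taxa}")
    if seed < 0:
        raise ValueError("seed must be >= 0")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    root = dendropy.Node()
    # (node, birth_time) for lineages still open
    active: list[tuple[dendropy.Node, float]] = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, t))
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t_end = t + rng.exponential(1.0 / n_taxa)
    for j, (node, birth) in enumerate(active):
        node.edge.length = t_end - birth

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    # scale to requested depth and label tips in leaf order
    scale = depth / t_end
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"t{i:02d}")
    return tree


def root_bipartition(tree: dendropy.Tree) -> dict[str, int]:
    """Binary clade indicator from the root split.

    Tips descending from the first child of the root get 0, all others 1 —
    the two-subgenus design of a root-divided clade.
    """
    children = tree.seed_node.child_nodes()
    if len(children) < 2:
        raise ValueError("root must have at least two children")
    first = {lf.taxon.label for lf in children[0].leaf_iter()}
    return {label: (0 if label in first else 1) for label in tip_labels(tree)}


def prune_to_taxa(tree: dendropy.Tree, keep: Sequence[str]) -> dendropy.Tree:
    """Return a copy of ``tree`` pruned to ``keep`` (labels must exist)."""
    keep = set(keep)
    have = set(tip_labels(tree))
    missing = keep - have
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    return pruned
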