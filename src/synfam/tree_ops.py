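"""Gene-tree computations: sub-clustering, pruning, collapse, zoom, paths.

The central operation is :func:`assign_subclusters`: an orthogroup's gene tree
is cut into *sub-clusters*, the maximal clades in which every leaf pair is
less than a threshold ``tau`` of total branch length apart.  Tokens that share
a sub-cluster later count as a "perfect match" in synteny scoring, so the
partition must be monophyletic and deterministic — sub-clusters are labelled
``<orthogroup>.<k>`` with ``k`` assigned by the left-to-right position of each
sub-cluster's leftmost leaf.

Trees are dendropy ``Tree`` objects, used rooted exactly as written.  Node
identifiers (for zooming and path highlighting) are leaf labels for leaves and
the internal node's own label when present, else ``n<preorder index>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import dendropy

from .io_formats import read_newick, newick_string

__all__ = [
    "SubclusterAssignment",
    "CollapsedTreeView",
    "PathAnnotation",
    "node_ids",
    "leaf_path_distance",
    "assign_subclusters",
    "prune_to_samples",
    "collapse_at_depth",
    "subtree_at",
    "path_to_gene",
]


@dataclass(frozen=True)
class SubclusterAssignment:
    """A partition of a gene tree's leaves into branch-length sub-clusters."""

    tau: float
    labels: dict[str, str]  # gene_id -> "<orthogroup>.<k>"


@dataclass
class CollapsedTreeView:
    """A tree truncated at ``depth_limit``; stubs carry descendant leaf counts."""

    depth_limit: int
    tree: dendropy.Tree
    leaf_counts: dict[str, int]  # stub node id -> number of collapsed leaves


@dataclass(frozen=True)
class PathAnnotation:
    """Root-to-leaf node id sequence for highlighting a searched gene."""

    target_gene: str
    path_nodes: tuple[str, ...]


def node_ids(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    """Assign deterministic node identifiers and return id → node.

    Leaves are identified by their taxon label; internal nodes by their newick
    label when present, otherwise ``n<i>`` with ``i`` the node's preorder
    index.  Ids are also stored on each node as ``node.nid``.
    """
    mapping: dict[str, dendropy.Node] = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf() and node.taxon is not None:
            nid = node.taxon.label
        elif node.label:
            nid = node.label
        else:
            nid = f"n{i}"
        node.nid = nid
        mapping[nid] = node
    return mapping


def _leaf_node(tree: dendropy.Tree, gene_id: str) -> dendropy.Node:
    node = tree.find_node_with_taxon_label(gene_id)
    if node is None:
        raise KeyError(f"no leaf named {gene_id!r} in tree")
    return node


def leaf_path_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path ``a → MRCA(a, b) → b``."""
    if a == b:
        _leaf_node(tree, a)
        return 0.0
    na, nb = _leaf_node(tree, a), _leaf_node(tree, b)
    anc: dict[int, tuple[dendropy.Node, float]] = {}
    dist = 0.0
    node = na
    while node is not None:
        anc[id(node)] = (node, dist)
        dist += node.edge.length or 0.0
        node = node.parent_node
    dist = 0.0
    node = nb
    while node is not None:
        if id(node) in anc:
            return dist + anc[id(node)][1]
        dist += node.edge.length or 0.0
        node = node.parent_node
    raise ValueError(f"leaves {a!r} and {b!r} share no ancestor")


def _clade_stats(tree: dendropy.Tree) -> dict[int, tuple[float, float]]:
    """Post-order (height, max internal leaf-pair distance) per node.

    ``height`` is the largest node-to-descendant-leaf path length.  The max
    pair distance of a clade with fewer than two leaves is ``-inf`` (no pair),
    so singletons qualify under any ``tau >= 0`` with the strict ``<`` rule.
    """
    stats: dict[int, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            stats[id(node)] = (0.0, -math.inf)
            continue
        depths = []
        maxpair = -math.inf
        for ch in children:
            h, mp = stats[id(ch)]
            depths.append(h + (ch.edge.length or 0.0))
            maxpair = max(maxpair, mp)
        # deepest leaf-pair straddling this node: two largest child depths
        if len(depths) >= 2:
            top = sorted(depths, reverse=True)
            maxpair = max(maxpair, top[0] + top[1])
        stats[id(node)] = (max(depths), maxpair)
    return stats


def assign_subclusters(
    tree: dendropy.Tree, tau: float, orthogroup_id: str
) -> SubclusterAssignment:
    """Partition the tree's leaves into maximal clades with diameter < ``tau``.

    A clade qualifies when every leaf pair inside it is strictly less than
    ``tau`` of total branch length apart; qualifying clades with a qualifying
    ancestor are absorbed into it (maximality).  ``tau = 0`` therefore yields
    all-singleton sub-clusters and ``tau = inf`` a single one.
    """
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    stats = _clade_stats(tree)
    labels: dict[str, str] = {}
    k = 0

    def visit(node: dendropy.Node) -> None:
        nonlocal k
        if stats[id(node)][1] < tau:
            for leaf in node.leaf_iter():
                labels[leaf.taxon.label] = f"{orthogroup_id}.{k}"
            k += 1
            return
        for ch in node.child_nodes():
            visit(ch)

    visit(tree.seed_node)
    return SubclusterAssignment(tau=tau, labels=labels)


def prune_to_samples(
    tree: dendropy.Tree,
    keep: set[str],
    gene_to_sample: Mapping[str, str] | Callable[[str], str],
) -> dendropy.Tree:
    """Induced tree on leaves whose sample is in ``keep``.

    Unary internal nodes created by the pruning are suppressed with their
    branch lengths summed, so pairwise path distances among surviving leaves
    are preserved exactly.  The input tree is not modified.
    """
    if not keep:
        raise ValueError("keep must be a non-empty set of sample ids")
    lookup = gene_to_sample if callable(gene_to_sample) else gene_to_sample.__getitem__
    survivors = [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if lookup(leaf.taxon.label) in keep
    ]
    if not survivors:
        raise ValueError(f"no leaf belongs to any sample in {sorted(keep)}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(survivors)
    pruned.seed_node.edge.length = 0.0
    return pruned


def collapse_at_depth(tree: dendropy.Tree, depth_limit: int) -> CollapsedTreeView:
    """Truncate the tree at ``depth_limit`` (root depth 0).

    Internal nodes at the limit become terminal stubs annotated with the exact
    number of leaves they hid; leaf counts are conserved.
    """
    if depth_limit < 1:
        raise ValueError(f"depth limit must be >= 1, got {depth_limit}")
    view = read_newick(newick_string(tree))  # independent copy and namespace
    node_ids(view)
    counts: dict[str, int] = {}
    for node in view.preorder_node_iter():
        depth = 0
        p = node.parent_node
        while p is not None:
            depth += 1
            p = p.parent_node
        if depth == depth_limit and not node.is_leaf():
            counts[node.nid] = sum(1 for _ in node.leaf_iter())
            node.set_child_nodes([])
            node.taxon = view.taxon_namespace.require_taxon(label=node.nid)
    return CollapsedTreeView(depth_limit=depth_limit, tree=view, leaf_counts=counts)


def subtree_at(tree: dendropy.Tree, node_id: str) -> dendropy.Tree:
    """Standalone tree for the clade rooted at ``node_id`` (root edge reset)."""
    mapping = node_ids(tree)
    if node_id not in mapping:
        raise KeyError(f"no node with id {node_id!r}")
    sub = dendropy.Tree(seed_node=mapping[node_id].extract_subtree())
    sub.seed_node.edge.length = 0.0
    # reparse so the subtree owns an independent taxon namespace
    return read_newick(newick_string(sub))


def path_to_gene(tree: dendropy.Tree, gene_id: str) -> PathAnnotation:
    """Node-id sequence from the root down to the searched gene's leaf."""
    node_ids(tree)
    leaf = _leaf_node(tree, gene_id)
    path = []
    node = leaf
    while node is not None:
        path.append(node.nid)
        node = node.parent_node
    return PathAnnotation(target_gene=gene_id, path_nodes=tuple(reversed(path)))
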