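"""Independent brute-force oracles and random generators for the test suite.

These deliberately avoid the package's dynamic-programming and traversal code
paths: the alignment oracle enumerates every global alignment recursively and
the sub-cluster oracle tests every clade against every leaf pair.
"""

from __future__ import annotations

import random

import dendropy

from synfam.synteny_align import SyntenyToken, token_score
from synfam.tree_ops import leaf_path_distance


def brute_force_nw_score(tokens1, tokens2, scheme) -> float:
    """Max total score over ALL global alignments, by exhaustive enumeration."""

    def best(i: int, j: int) -> float:
        if i == len(tokens1) and j == len(tokens2):
            return 0.0
        options = []
        if i < len(tokens1) and j < len(tokens2):
            options.append(
                token_score(tokens1[i], tokens2[j], scheme) + best(i + 1, j + 1)
            )
        if i < len(tokens1):
            options.append(scheme.s_gap + best(i + 1, j))
        if j < len(tokens2):
            options.append(scheme.s_gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def brute_force_subclusters(tree: dendropy.Tree, tau: float) -> list[frozenset[str]]:
    """Maximal clades whose every internal leaf pair is < tau apart.

    Checks every clade directly with pairwise path distances; maximality means
    no qualifying proper ancestor.  Returns the partition as leaf-label sets.
    """
    nodes = list(tree.preorder_node_iter())

    def qualifies(node) -> bool:
        leaves = [l.taxon.label for l in node.leaf_iter()]
        return all(
            leaf_path_distance(tree, a, b) < tau
            for i, a in enumerate(leaves)
            for b in leaves[i + 1 :]
        )

    ok = {id(n): qualifies(n) for n in nodes}
    clusters = []
    for n in nodes:
        if not ok[id(n)]:
            continue
        p = n.parent_node
        ancestor_ok = False
        while p is not None:
            if ok[id(p)]:
                ancestor_ok = True
                break
            p = p.parent_node
        if not ancestor_ok:
            clusters.append(frozenset(l.taxon.label for l in n.leaf_iter()))
    return clusters


def random_newick(rng: random.Random, n_leaves: int, prefix: str = "g") -> str:
    """Random rooted tree over n_leaves with uniform [0, 1] branch lengths."""
    names = [f"{prefix}{i}" for i in range(n_leaves)]

    def build(labels: list[str]) -> str:
        if len(labels) == 1:
            return f"{labels[0]}:{rng.uniform(0, 1):.4f}"
        cut = rng.randint(1, len(labels) - 1)
        return (
            f"({build(labels[:cut])},{build(labels[cut:])}):{rng.uniform(0, 1):.4f}"
        )

    if n_leaves == 1:
        return f"({names[0]}:{rng.uniform(0, 1):.4f});"
    return build(names) + ";"


def random_token_string(rng: random.Random, length: int) -> list[SyntenyToken]:
    """Random tokens over a small orthogroup/sub-cluster alphabet, incl. unassigned."""
    tokens = []
    for i in range(length):
        og = rng.choice(["OG1", "OG2", "OG3", None])
        sub = None
        if og is not None and rng.random() < 0.7:
            sub = f"{og}.{rng.randint(0, 2)}"
        tokens.append(SyntenyToken(f"t{i}", og, sub))
    return tokens
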