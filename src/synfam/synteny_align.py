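"""Multiple synteny alignment: progressive Needleman–Wunsch over gene-order tokens.

The neighborhood of a focal gene — up to ``k`` genes on each side in contig
order — is rendered as a string of tokens, each token a gene labelled with its
orthogroup and orthogroup sub-cluster.  Two tokens *match* when they belong to
the same orthogroup and match *perfectly* when they share a sub-cluster; a
gene absent from the orthogroup table is an unassigned token that matches
nothing.  Neighborhood strings are aligned globally with Needleman–Wunsch
(linear gap penalty), and alignments are merged progressively up the
orthogroup's gene tree, which doubles as the guide tree.  Columns of two
profiles are compared by sum-of-pairs: every cell of one column is scored
against every cell of the other and the scores are summed.

The result is a :class:`SyntenyProfile`, a gapped matrix whose rows are focal
genes and whose columns are aligned gene-order positions.  Conserved local
gene order shows up as columns sharing one orthogroup label ("banding"); a
tandem duplication shows up as an extra column private to one lineage,
adjacent to the duplicated gene.

Determinism: Needleman–Wunsch traceback ties break diagonal, then up (gap in
the second string/profile), then left, so identical inputs give byte-identical
profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .io_formats import GeneOrders, OrthogroupTable

__all__ = [
    "GAP",
    "SyntenyToken",
    "NeighborhoodString",
    "ScoringScheme",
    "ProfileRow",
    "SyntenyProfile",
    "extract_neighborhood",
    "token_score",
    "pairwise_nw",
    "profile_column_score",
    "align_profiles",
    "progressive_align",
]

logger = logging.getLogger(__name__)

GAP = None  # gap cells in profiles are represented as None


@dataclass(frozen=True)
class SyntenyToken:
    """A gene rendered as its homology labels for gene-order comparison."""

    gene_id: str
    orthogroup_id: str | None = None  # None = gene absent from the table
    subcluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.subcluster_id is not None:
            if self.orthogroup_id is None or not self.subcluster_id.startswith(
                self.orthogroup_id + "."
            ):
                raise ValueError(
                    f"subcluster {self.subcluster_id!r} does not extend "
                    f"orthogroup {self.orthogroup_id!r}"
                )


@dataclass(frozen=True)
class NeighborhoodString:
    """The focal gene plus up to ``k`` flanking genes on each side, as tokens."""

    focal_gene: str
    sample_id: str
    k: int
    tokens: tuple[SyntenyToken, ...]
    focal_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.focal_index < len(self.tokens):
            raise ValueError("focal_index out of range")
        if self.tokens[self.focal_index].gene_id != self.focal_gene:
            raise ValueError("token at focal_index is not the focal gene")
        if len(self.tokens) > 2 * self.k + 1:
            raise ValueError("window longer than 2k+1")


@dataclass(frozen=True)
class ScoringScheme:
    """Token-level scores.

    ``s_perfect`` — same orthogroup sub-cluster; ``s_match`` — same orthogroup
    but different sub-cluster; ``s_mismatch`` — different or unassigned
    orthogroups; ``s_gap`` — token against gap; ``s_gapgap`` — gap against gap
    inside profile columns (always 0).
    """

    s_perfect: float = 2.0
    s_match: float = 1.0
    s_mismatch: float = -1.0
    s_gap: float = -1.0
    s_gapgap: float = 0.0

    def __post_init__(self) -> None:
        if not (self.s_perfect >= self.s_match > self.s_mismatch):
            raise ValueError("require s_perfect >= s_match > s_mismatch")
        if self.s_gap >= 0:
            raise ValueError("gap penalty must be negative")
        if self.s_gapgap != 0:
            raise ValueError("gap-vs-gap score must be 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class ProfileRow:
    focal_gene: str
    sample_id: str
    focal_index: int | None = None  # index of the focal token within the row


@dataclass
class SyntenyProfile:
    """A gapped matrix of synteny tokens; rows are focal genes.

    ``score`` is the Needleman–Wunsch score of the merge that produced this
    profile; ``total_score`` accumulates the merge scores over the whole
    progressive history and equals the sum-of-pairs score of the final matrix.
    """

    rows: list[ProfileRow]
    cells: list[list[SyntenyToken | None]]
    score: float = 0.0
    total_score: float = 0.0

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.cells}
        if len(self.cells) != len(self.rows) or (widths and len(widths) != 1):
            raise ValueError("ragged or mis-sized profile matrix")

    @property
    def n_columns(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row_tokens(self, i: int) -> list[SyntenyToken]:
        """Row ``i`` with gaps removed: the original neighborhood string."""
        return [c for c in self.cells[i] if c is not GAP]

    def column(self, j: int) -> list[SyntenyToken | None]:
        return [row[j] for row in self.cells]

    @property
    def focal_column(self) -> int | None:
        """The single column holding every row's focal gene, if it exists."""
        cols: set[int] = set()
        for row, cells in zip(self.rows, self.cells):
            if row.focal_index is None:
                continue
            seen = -1
            for j, c in enumerate(cells):
                if c is not GAP:
                    seen += 1
                    if seen == row.focal_index:
                        cols.add(j)
                        break
        if len(cols) == 1:
            return cols.pop()
        return None

    def to_tsv(self) -> str:
        """rows × columns of gene IDs, gaps as ``-``; first column = focal gene."""
        lines = []
        for row, cells in zip(self.rows, self.cells):
            ids = [c.gene_id if c is not GAP else "-" for c in cells]
            lines.append("\t".join([row.focal_gene] + ids))
        return "\n".join(lines) + "\n"

    def to_json_obj(self) -> dict:
        return {
            "rows": [
                {
                    "focal_gene": r.focal_gene,
                    "sample_id": r.sample_id,
                    "focal_index": r.focal_index,
                }
                for r in self.rows
            ],
            "focal_column": self.focal_column,
            "cells": [
                [
                    None
                    if c is GAP
                    else {
                        "gene_id": c.gene_id,
                        "orthogroup_id": c.orthogroup_id,
                        "subcluster_id": c.subcluster_id,
                    }
                    for c in cells
                ]
                for cells in self.cells
            ],
        }


# ---------------------------------------------------------------------------
# neighborhood extraction
# ---------------------------------------------------------------------------


def extract_neighborhood(
    focal: str,
    orders: GeneOrders,
    table: OrthogroupTable,
    subclusters: Mapping[str, str],
    k: int,
    *,
    normalize_strand: bool = True,
) -> NeighborhoodString:
    """Token string of up to ``k`` genes on each side of ``focal``.

    Tokens carry their own orthogroup and sub-cluster labels, including genes
    from other orthogroups inside the window (cross-window matches are what
    create consistent banding).  If the focal gene is on the minus strand the
    token order is reversed so inverted loci band together; disable with
    ``normalize_strand=False``.

    Raises ``KeyError`` when the focal gene has no recorded locus.
    """
    if k < 0:
        raise ValueError(f"window radius k must be >= 0, got {k}")
    loc = orders.locus(focal)
    contig = orders.contig_genes(loc.sample_id, loc.contig_id)
    lo = max(0, loc.ordinal - k)
    hi = min(len(contig), loc.ordinal + k + 1)
    genes = contig[lo:hi]
    focal_index = loc.ordinal - lo
    if normalize_strand and loc.strand == "-":
        genes = genes[::-1]
        focal_index = len(genes) - 1 - focal_index
    tokens = tuple(
        SyntenyToken(
            gene_id=g,
            orthogroup_id=table.orthogroup_of(g),
            subcluster_id=subclusters.get(g),
        )
        for g in genes
    )
    return NeighborhoodString(
        focal_gene=focal,
        sample_id=loc.sample_id,
        k=k,
        tokens=tokens,
        focal_index=focal_index,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def token_score(
    a: SyntenyToken | None, b: SyntenyToken | None, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    if a is GAP and b is GAP:
        return scheme.s_gapgap
    if a is GAP or b is GAP:
        return scheme.s_gap
    if a.subcluster_id is not None and a.subcluster_id == b.subcluster_id:
        return scheme.s_perfect
    if a.orthogroup_id is not None and a.orthogroup_id == b.orthogroup_id:
        return scheme.s_match
    return scheme.s_mismatch


def profile_column_score(
    col1: Sequence[SyntenyToken | None],
    col2: Sequence[SyntenyToken | None],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> float:
    """Sum of ``token_score`` over the full cross product of the two columns."""
    total = 0.0
    for a in col1:
        if a is GAP:
            # gap vs token = s_gap per token in col2; gap vs gap = 0
            total += scheme.s_gap * sum(1 for b in col2 if b is not GAP)
        else:
            for b in col2:
                total += token_score(a, b, scheme)
    return total


# ---------------------------------------------------------------------------
# Needleman–Wunsch (pairwise and profile-profile)
# ---------------------------------------------------------------------------


def _nw_columns(
    cols1: list[tuple],
    cols2: list[tuple],
    colscore,
    gap1: list[float],
    gap2: list[float],
) -> tuple[float, list[tuple[int, int]]]:
    """Generic global DP over two column sequences.

    ``gap1[i]`` is the cost of aligning column i of the first sequence against
    a gap; likewise ``gap2[j]``.  Returns the optimal score and the traceback
    as (di, dj) steps with tie-break diagonal > up (consume first) > left.
    """
    m, n = len(cols1), len(cols2)
    dp = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        dp[i][0] = dp[i - 1][0] + gap1[i - 1]
    for j in range(1, n + 1):
        dp[0][j] = dp[0][j - 1] + gap2[j - 1]
    for i in range(1, m + 1):
        row, prev = dp[i], dp[i - 1]
        for j in range(1, n + 1):
            row[j] = max(
                prev[j - 1] + colscore(cols1[i - 1], cols2[j - 1]),
                prev[j] + gap1[i - 1],
                row[j - 1] + gap2[j - 1],
            )
    steps: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 or j > 0:
        here = dp[i][j]
        if (
            i > 0
            and j > 0
            and here == dp[i - 1][j - 1] + colscore(cols1[i - 1], cols2[j - 1])
        ):
            steps.append((1, 1))
            i, j = i - 1, j - 1
        elif i > 0 and here == dp[i - 1][j] + gap1[i - 1]:
            steps.append((1, 0))
            i -= 1
        else:
            steps.append((0, 1))
            j -= 1
    steps.reverse()
    return dp[m][n], steps


def _leaf_profile(s: NeighborhoodString) -> SyntenyProfile:
    return SyntenyProfile(
        rows=[ProfileRow(s.focal_gene, s.sample_id, s.focal_index)],
        cells=[list(s.tokens)],
    )


def align_profiles(
    p1: SyntenyProfile, p2: SyntenyProfile, scheme: ScoringScheme = DEFAULT_SCHEME
) -> SyntenyProfile:
    """Needleman–Wunsch over profile columns with sum-of-pairs column scores.

    Skipping a column costs its sum-of-pairs score against an all-gap column
    of the other profile's height (each real token in the skipped column pays
    ``s_gap`` per row on the other side; gap cells pay nothing).  Rows of
    ``p1`` precede rows of ``p2``; every row still projects back to its
    original neighborhood string.
    """
    if not p1.rows or not p2.rows:
        raise ValueError("cannot align an empty profile")
    r1, r2 = len(p1.rows), len(p2.rows)
    cols1 = [tuple(p1.column(j)) for j in range(p1.n_columns)]
    cols2 = [tuple(p2.column(j)) for j in range(p2.n_columns)]

    def ntok(col: tuple) -> int:
        return sum(1 for c in col if c is not GAP)

    gap1 = [ntok(c) * r2 * scheme.s_gap for c in cols1]
    gap2 = [ntok(c) * r1 * scheme.s_gap for c in cols2]
    score, steps = _nw_columns(
        cols1, cols2, lambda a, b: profile_column_score(a, b, scheme), gap1, gap2
    )
    cells: list[list[SyntenyToken | None]] = [[] for _ in range(r1 + r2)]
    i = j = 0
    for di, dj in steps:
        top = cols1[i] if di else (GAP,) * r1
        bot = cols2[j] if dj else (GAP,) * r2
        for r, c in enumerate(top):
            cells[r].append(c)
        for r, c in enumerate(bot):
            cells[r1 + r].append(c)
        i += di
        j += dj
    return SyntenyProfile(
        rows=p1.rows + p2.rows,
        cells=cells,
        score=score,
        total_score=p1.total_score + p2.total_score + score,
    )


def pairwise_nw(
    s1: NeighborhoodString,
    s2: NeighborhoodString,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> SyntenyProfile:
    """Global alignment of two neighborhood strings (2-row profile).

    The profile's ``score`` is the terminal Needleman–Wunsch cell, i.e. the
    maximal total token score under a linear gap penalty.
    """
    if not s1.tokens or not s2.tokens:
        raise ValueError("cannot align an empty neighborhood string")
    return align_profiles(_leaf_profile(s1), _leaf_profile(s2), scheme)


# ---------------------------------------------------------------------------
# progressive alignment along the guide tree
# ---------------------------------------------------------------------------


def progressive_align(
    tree: dendropy.Tree,
    neighborhoods: Mapping[str, NeighborhoodString],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> SyntenyProfile:
    """Align all neighborhoods progressively, guided by the gene tree.

    Leaves are aligned bottom-up in post-order; each internal node merges its
    children's profiles left to right (multifurcations fold sequentially in
    child order), so the final row order is the tree's left-to-right leaf
    order.  Leaves without a neighborhood (typically genes lacking
    coordinates) are dropped with a warning before traversal.
    """
    missing = [
        l.taxon.label
        for l in tree.leaf_node_iter()
        if l.taxon.label not in neighborhoods
    ]
    if missing:
        logger.warning(
            "dropping %d leaves without coordinates from synteny alignment: %s",
            len(missing),
            ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""),
        )

    def build(node: dendropy.Node) -> SyntenyProfile | None:
        if node.is_leaf():
            label = node.taxon.label
            if label not in neighborhoods:
                return None
            return _leaf_profile(neighborhoods[label])
        merged: SyntenyProfile | None = None
        for child in node.child_nodes():
            prof = build(child)
            if prof is None:
                continue
            merged = prof if merged is None else align_profiles(merged, prof, scheme)
        return merged

    profile = build(tree.seed_node)
    if profile is None:
        raise ValueError("no tree leaf has a neighborhood; nothing to align")
    return profile
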