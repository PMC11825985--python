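"""Readers, writers and the canonical in-memory model for all standard inputs.

Everything downstream works on four containers built here:

* :class:`GeneLocus` / :class:`GeneOrders` — per-sample gene coordinates and the
  per-contig gene order (ordinals) that synteny windows are cut from.
* :class:`OrthogroupTable` — orthogroup → sample → gene IDs, plus the inverse
  gene → orthogroup map that labels synteny tokens.
* dendropy ``Tree`` objects for gene trees and the species phylogeny.
* :class:`SequenceSet` — an ordered ID → residues mapping, optionally an
  alignment.

Coordinates are normalized to 1-based inclusive (GFF3 convention); BED's
0-based half-open intervals are converted on read.  Gene order within a contig
is by ascending start (ties: ascending end, then gene ID); strand does not
affect the ordinal.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "GeneLocus",
    "GeneOrders",
    "OrthogroupTable",
    "SequenceSet",
    "read_gene_loci",
    "read_orthogroups",
    "read_newick",
    "write_newick",
    "newick_string",
    "read_fasta",
    "write_fasta",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GeneLocus:
    """One gene's genomic placement and its rank in the contig's gene order."""

    gene_id: str
    sample_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "."
    ordinal: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


class GeneOrders:
    """Index over loci: gene → locus, and (sample, contig) → ordered gene IDs."""

    def __init__(self, loci: Iterable[GeneLocus]):
        self.by_gene: dict[str, GeneLocus] = {}
        self.by_contig: dict[tuple[str, str], list[str]] = {}
        grouped: dict[tuple[str, str], list[GeneLocus]] = {}
        for loc in loci:
            if loc.gene_id in self.by_gene:
                raise ValueError(f"duplicate gene ID {loc.gene_id!r} in gene orders")
            self.by_gene[loc.gene_id] = loc
            grouped.setdefault((loc.sample_id, loc.contig_id), []).append(loc)
        for key, group in grouped.items():
            group.sort(key=lambda l: l.ordinal)
            ords = [l.ordinal for l in group]
            if ords != list(range(len(group))):
                raise ValueError(
                    f"ordinals on {key} are not a contiguous 0..n-1 run: {ords}"
                )
            self.by_contig[key] = [l.gene_id for l in group]

    def locus(self, gene_id: str) -> GeneLocus:
        try:
            return self.by_gene[gene_id]
        except KeyError:
            raise KeyError(f"no locus recorded for gene {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_gene

    def contig_genes(self, sample_id: str, contig_id: str) -> list[str]:
        return self.by_contig[(sample_id, contig_id)]

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _ in self.by_contig})


@dataclass
class OrthogroupTable:
    """Orthogroup → sample → gene IDs, with the inverse gene → orthogroup map."""

    groups: dict[str, dict[str, list[str]]]
    reverse: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reverse:
            for og, per_sample in self.groups.items():
                for genes in per_sample.values():
                    for g in genes:
                        if g in self.reverse:
                            raise ValueError(
                                f"gene {g!r} appears in both {self.reverse[g]!r} "
                                f"and {og!r}"
                            )
                        self.reverse[g] = og
        for og, per_sample in self.groups.items():
            if not any(per_sample.values()):
                raise ValueError(f"orthogroup {og!r} is empty")

    def orthogroup_of(self, gene_id: str) -> str | None:
        return self.reverse.get(gene_id)

    def members(self, orthogroup_id: str) -> list[str]:
        """All member genes of one orthogroup, in table (sample, cell) order."""
        per_sample = self.groups[orthogroup_id]
        return [g for sample in per_sample for g in per_sample[sample]]

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for per_sample in self.groups.values():
            for s in per_sample:
                seen.setdefault(s)
        return list(seen)

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.groups)


@dataclass
class SequenceSet:
    """Ordered ID → residue strings; ``is_alignment`` means equal lengths."""

    records: dict[str, str]
    is_alignment: bool = False

    def __post_init__(self) -> None:
        if self.is_alignment and self.records:
            lengths = {len(s) for s in self.records.values()}
            if len(lengths) > 1:
                raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def alignment_length(self) -> int:
        if not self.is_alignment:
            raise ValueError("not an alignment")
        return len(next(iter(self.records.values()))) if self.records else 0


# ---------------------------------------------------------------------------
# gene coordinates (GFF3 / BED)
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_gff3_loci(
    path: str | Path, sample_id: str, feature_type: str, id_attribute: str
) -> Iterator[GeneLocus]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype != feature_type:
                continue
            ids = feat.attributes.get(id_attribute, [])
            if not ids:
                raise ValueError(
                    f"{path}: line {lineno}: {feature_type} feature lacks "
                    f"attribute {id_attribute!r}"
                )
            strand = feat.strand if feat.strand in VALID_STRANDS else "."
            yield GeneLocus(
                gene_id=ids[0],
                sample_id=sample_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
            )


def _iter_bed_loci(path: str | Path, sample_id: str) -> Iterator[GeneLocus]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < 4 or not cols[3]:
                raise ValueError(
                    f"{path}: line {lineno}: BED record needs >= 4 columns "
                    "with a name field"
                )
            strand = cols[5] if len(cols) >= 6 and cols[5] in VALID_STRANDS else "."
            # BED is 0-based half-open; internal model is 1-based inclusive.
            yield GeneLocus(
                gene_id=cols[3],
                sample_id=sample_id,
                contig_id=cols[0],
                start=int(cols[1]) + 1,
                end=int(cols[2]),
                strand=strand,
            )


def read_gene_loci(
    path: str | Path,
    format: str,
    sample_id: str,
    *,
    feature_type: str = "gene",
    id_attribute: str = "ID",
) -> list[GeneLocus]:
    """Read one sample's gene coordinates from GFF3 or BED.

    Returns one :class:`GeneLocus` per gene feature with per-contig ordinals
    assigned by ascending start (ties: ascending end, then gene ID).  GFF3
    feature type and ID attribute are configurable because annotation dialects
    vary (mRNA-level IDs are common).

    Raises
    ------
    ValueError
        On an unknown format, a duplicate gene ID within the sample, or a
        feature without a usable name/ID (reported with its line number).
    """
    if format == "gff3":
        raw = list(_iter_gff3_loci(path, sample_id, feature_type, id_attribute))
    elif format == "bed":
        raw = list(_iter_bed_loci(path, sample_id))
    else:
        raise ValueError(f"unknown coordinate format {format!r} (use gff3 or bed)")

    seen: set[str] = set()
    for loc in raw:
        if loc.gene_id in seen:
            raise ValueError(
                f"{path}: duplicate gene ID {loc.gene_id!r} in sample {sample_id!r}"
            )
        seen.add(loc.gene_id)

    out: list[GeneLocus] = []
    by_contig: dict[str, list[GeneLocus]] = {}
    for loc in raw:
        by_contig.setdefault(loc.contig_id, []).append(loc)
    for contig in by_contig:
        group = sorted(by_contig[contig], key=lambda l: (l.start, l.end, l.gene_id))
        for ordinal, loc in enumerate(group):
            out.append(
                GeneLocus(
                    gene_id=loc.gene_id,
                    sample_id=loc.sample_id,
                    contig_id=loc.contig_id,
                    start=loc.start,
                    end=loc.end,
                    strand=loc.strand,
                    ordinal=ordinal,
                )
            )
    return out


# ---------------------------------------------------------------------------
# orthogroups table
# ---------------------------------------------------------------------------


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Read an OrthoFinder-style ``Orthogroups.tsv``.

    Header row is ``Orthogroup<TAB>sample1<TAB>...``; cells are comma (and
    optional space) separated gene lists, possibly empty.  Gene IDs are
    whitespace-trimmed.  A gene listed in two orthogroups is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns.size < 2 or df.columns[0] != "Orthogroup":
        raise ValueError(
            f"{path}: malformed header; expected 'Orthogroup<TAB>sample1...', "
            f"got {list(df.columns)[:3]}"
        )
    samples = list(df.columns[1:])
    groups: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        og = row["Orthogroup"].strip()
        per_sample: dict[str, list[str]] = {}
        for s in samples:
            genes = [g.strip() for g in row[s].split(",") if g.strip()]
            if genes:
                per_sample[s] = genes
        if per_sample:
            groups[og] = per_sample
    return OrthogroupTable(groups=groups)


# ---------------------------------------------------------------------------
# newick trees
# ---------------------------------------------------------------------------


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a newick tree from a path or a literal newick string.

    The tree is used rooted as written (no re-rooting); missing branch lengths
    default to 0.0 and the root edge length is forced to 0.0.  Underscores in
    labels are preserved verbatim; quoted labels are unquoted.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and ";" not in source and os.path.exists(source)
    ):
        tree = dendropy.Tree.get(
            path=os.fspath(source), schema="newick", preserve_underscores=True
        )
    else:
        tree = dendropy.Tree.get(
            data=str(source), schema="newick", preserve_underscores=True
        )
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        elif edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    tree.seed_node.edge.length = 0.0
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    return tree


def newick_string(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line newick string with branch lengths."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_annotations=True,
        ).strip()
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, *, is_alignment: bool | None = None) -> SequenceSet:
    """Read FASTA into an ordered :class:`SequenceSet`.

    ``is_alignment`` is auto-detected (all lengths equal and any ``-``
    present) unless given explicitly.  Duplicate record IDs are a hard error.
    """
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"{path}: duplicate FASTA ID {rec.id!r}")
            records[rec.id] = str(rec.seq)
    if is_alignment is None:
        lengths = {len(s) for s in records.values()}
        is_alignment = (
            len(lengths) == 1 and any("-" in s for s in records.values())
        )
    return SequenceSet(records=records, is_alignment=is_alignment)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write FASTA, 60-column wrapped. Round-trips IDs, order and residues."""
    if not seqs.records:
        raise ValueError("refusing to write an empty sequence set")
    bio = [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in seqs.records.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")
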