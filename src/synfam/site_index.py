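"""Static index generation: per-orthogroup JSON bundles, manifest and search.

The output directory is a front-end-agnostic artifact::

    out/
      manifest.json            # sample list, bundle paths, payload flags, anomalies
      phylogeny.json           # species tree newick + leaf list
      search_index.json        # sorted (key, gene, orthogroup) entries
      orthogroups/<OG>.json    # gene tree, sub-clusters, optional MSA + synteny

Builds are byte-stable: JSON is written with sorted keys and fixed layout, so
re-running on identical input produces hash-identical files.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy

from .io_formats import GeneOrders, OrthogroupTable, SequenceSet, newick_string
from .synteny_align import (
    DEFAULT_SCHEME,
    GAP,
    ProfileRow,
    ScoringScheme,
    SyntenyProfile,
    SyntenyToken,
    extract_neighborhood,
    progressive_align,
)
from .tree_ops import assign_subclusters, prune_to_samples

__all__ = [
    "OrthogroupBundle",
    "SearchIndex",
    "build_bundles",
    "search",
    "export_subset",
    "load_bundle",
    "profile_from_json_obj",
]


@dataclass
class OrthogroupBundle:
    """Everything one orthogroup's views consume."""

    orthogroup_id: str
    gene_tree: str  # newick
    members: dict[str, list[str]]  # sample -> gene ids
    subclusters: dict[str, str]
    msa: SequenceSet | None = None
    synteny: SyntenyProfile | None = None
    anomalies: list[str] | None = None

    def gene_to_sample(self) -> dict[str, str]:
        return {g: s for s, genes in self.members.items() for g in genes}


@dataclass
class SearchIndex:
    """Sorted lowercase-key entries for case-insensitive prefix lookup."""

    entries: list[tuple[str, str, str]]  # (normalized_key, gene_id, orthogroup_id)

    @classmethod
    def from_table(cls, table: OrthogroupTable) -> "SearchIndex":
        entries = sorted(
            (g.lower(), g, og) for g, og in table.reverse.items()
        )
        return cls(entries=entries)


def search(
    index: SearchIndex, query: str, limit: int = 10
) -> list[tuple[str, str]]:
    """Case-insensitive prefix matches in sorted key order, up to ``limit``."""
    q = query.lower()
    keys = [e[0] for e in index.entries]
    i = bisect_left(keys, q)
    out: list[tuple[str, str]] = []
    while i < len(index.entries) and len(out) < limit:
        key, gene, og = index.entries[i]
        if not key.startswith(q):
            break
        out.append((gene, og))
        i += 1
    return out


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def _bundle_obj(bundle: OrthogroupBundle) -> dict:
    return {
        "orthogroup_id": bundle.orthogroup_id,
        "gene_tree": bundle.gene_tree,
        "members": bundle.members,
        "subclusters": bundle.subclusters,
        "msa": bundle.msa.records if bundle.msa is not None else None,
        "synteny": bundle.synteny.to_json_obj() if bundle.synteny else None,
        "anomalies": bundle.anomalies or [],
    }


def build_bundles(
    out_dir: str | Path,
    table: OrthogroupTable,
    gene_trees: Mapping[str, dendropy.Tree],
    *,
    species_tree: dendropy.Tree | None = None,
    msas: Mapping[str, SequenceSet] | None = None,
    gene_orders: GeneOrders | None = None,
    keep_samples: set[str] | None = None,
    k: int = 10,
    tau: float = 0.5,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> dict:
    """Build the whole static index; returns the manifest object.

    MSA and gene coordinates are optional per orthogroup; a bundle simply
    marks the payloads it has.  ``keep_samples`` restricts the build to a
    sample subset (trees pruned, members and MSAs filtered) before any
    computation.  A gene-tree leaf that is not a member of its orthogroup is
    recorded as an anomaly in both the bundle and the manifest.
    """
    out = Path(out_dir)
    (out / "orthogroups").mkdir(parents=True, exist_ok=True)
    msas = msas or {}

    gene_to_sample = {
        g: s
        for og in table.groups
        for s, genes in table.groups[og].items()
        for g in genes
    }

    # sub-cluster labels are global: windows may contain other orthogroups
    pruned_trees: dict[str, dendropy.Tree] = {}
    subclusters: dict[str, str] = {}
    for og in sorted(table.groups):
        tree = gene_trees.get(og)
        if tree is None:
            continue
        if keep_samples is not None:
            try:
                tree = prune_to_samples(tree, keep_samples, gene_to_sample.get)
            except ValueError:
                continue  # orthogroup absent from the kept samples
        pruned_trees[og] = tree
        subclusters.update(assign_subclusters(tree, tau, og).labels)

    manifest_groups: dict[str, dict] = {}
    for og in sorted(table.groups):
        if og not in pruned_trees:
            continue
        tree = pruned_trees[og]
        members = {
            s: genes
            for s, genes in table.groups[og].items()
            if keep_samples is None or s in keep_samples
        }
        member_set = {g for genes in members.values() for g in genes}

        anomalies = [
            f"tree leaf {l.taxon.label!r} is not a member of {og}"
            for l in tree.leaf_node_iter()
            if l.taxon.label not in member_set
        ]

        msa = msas.get(og)
        if msa is not None and keep_samples is not None:
            kept = {
                name: seq for name, seq in msa.records.items() if name in member_set
            }
            msa = SequenceSet(records=kept, is_alignment=msa.is_alignment) if kept else None

        synteny = None
        if gene_orders is not None:
            neighborhoods = {}
            for leaf in tree.leaf_node_iter():
                g = leaf.taxon.label
                if g in gene_orders:
                    neighborhoods[g] = extract_neighborhood(
                        g, gene_orders, table, subclusters, k
                    )
            if neighborhoods:
                synteny = progressive_align(tree, neighborhoods, scheme)

        bundle = OrthogroupBundle(
            orthogroup_id=og,
            gene_tree=newick_string(tree),
            members=members,
            subclusters={
                g: c for g, c in subclusters.items() if g in member_set
            },
            msa=msa,
            synteny=synteny,
            anomalies=anomalies,
        )
        rel = f"orthogroups/{og}.json"
        _dump_json(_bundle_obj(bundle), out / rel)
        manifest_groups[og] = {
            "path": rel,
            "payloads": {
                "gene_tree": True,
                "msa": msa is not None,
                "synteny": synteny is not None,
            },
            "anomalies": anomalies,
        }

    if species_tree is not None:
        sp = species_tree
        if keep_samples is not None:
            sp = prune_to_samples(sp, keep_samples, lambda s: s)
        _dump_json(
            {
                "newick": newick_string(sp),
                "samples": sorted(l.taxon.label for l in sp.leaf_node_iter()),
            },
            out / "phylogeny.json",
        )

    index = SearchIndex.from_table(table)
    _dump_json([list(e) for e in index.entries], out / "search_index.json")

    samples = table.samples
    if keep_samples is not None:
        samples = [s for s in samples if s in keep_samples]
    manifest = {
        "samples": samples,
        "orthogroups": manifest_groups,
        "phylogeny": "phylogeny.json" if species_tree is not None else None,
        "search_index": "search_index.json",
        "parameters": {
            "k": k,
            "tau": tau,
            "scores": {
                "s_perfect": scheme.s_perfect,
                "s_match": scheme.s_match,
                "s_mismatch": scheme.s_mismatch,
                "s_gap": scheme.s_gap,
                "s_gapgap": scheme.s_gapgap,
            },
        },
    }
    _dump_json(manifest, out / "manifest.json")
    return manifest


def profile_from_json_obj(obj: dict) -> SyntenyProfile:
    rows = [
        ProfileRow(r["focal_gene"], r["sample_id"], r.get("focal_index"))
        for r in obj["rows"]
    ]
    cells = [
        [
            GAP
            if c is None
            else SyntenyToken(c["gene_id"], c["orthogroup_id"], c["subcluster_id"])
            for c in row
        ]
        for row in obj["cells"]
    ]
    return SyntenyProfile(rows=rows, cells=cells)


def load_bundle(out_dir: str | Path, orthogroup_id: str) -> OrthogroupBundle:
    """Read one bundle back from a built index directory."""
    path = Path(out_dir) / "orthogroups" / f"{orthogroup_id}.json"
    obj = json.loads(path.read_text())
    msa = None
    if obj["msa"] is not None:
        records = obj["msa"]
        lengths = {len(s) for s in records.values()}
        msa = SequenceSet(
            records=records,
            is_alignment=len(lengths) == 1
            and any("-" in s for s in records.values()),
        )
    return OrthogroupBundle(
        orthogroup_id=obj["orthogroup_id"],
        gene_tree=obj["gene_tree"],
        members=obj["members"],
        subclusters=obj["subclusters"],
        msa=msa,
        synteny=profile_from_json_obj(obj["synteny"]) if obj["synteny"] else None,
        anomalies=obj["anomalies"],
    )


def export_subset(
    bundle: OrthogroupBundle, keep: set[str], what: str
) -> SequenceSet:
    """Sequences of the kept samples, as plain FASTA records or MSA rows.

    ``what="fasta"`` strips gaps; ``what="msa"`` keeps rows aligned and drops
    columns that became all-gap after the subset.
    """
    if bundle.msa is None:
        raise ValueError(f"bundle {bundle.orthogroup_id} has no sequence payload")
    if what not in ("fasta", "msa"):
        raise ValueError(f"unknown export kind {what!r} (use fasta or msa)")
    g2s = bundle.gene_to_sample()
    kept = {
        name: seq
        for name, seq in bundle.msa.records.items()
        if g2s.get(name) in keep
    }
    if not kept:
        raise ValueError(f"no sequence belongs to any sample in {sorted(keep)}")
    if what == "fasta":
        return SequenceSet(
            records={n: s.replace("-", "") for n, s in kept.items()},
            is_alignment=False,
        )
    rows = list(kept.values())
    keep_cols = [j for j in range(len(rows[0])) if any(r[j] != "-" for r in rows)]
    return SequenceSet(
        records={n: "".join(s[j] for j in keep_cols) for n, s in kept.items()},
        is_alignment=True,
    )
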