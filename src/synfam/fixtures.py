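"""Synthetic OrthoFinder-style datasets with controllable evolutionary events.

The generator evolves an ancestral gene order along a random sample tree and
emits every input the rest of the package consumes, at toy scale and in the
standard formats: one GFF3 per sample, an orthogroups TSV, one newick gene
tree per orthogroup, a newick species tree, one aligned FASTA per orthogroup,
and an ``events.json`` ground-truth log.

Every ancestral gene founds one orthogroup.  Events are applied independently
on each terminal branch (i.e. per sample):

* tandem duplication — an adjacent extra copy in the same orthogroup;
* loss — the gene is removed from that sample;
* inversion — a short gene-order segment is reversed with strands flipped.

Gene trees mirror the sample tree restricted to samples carrying the
orthogroup; tandem copies hang from a short (0.01) pair of edges under their
sample's position, so sub-clustering at a threshold between the duplication
edge scale and the between-sample scale separates duplicate clades.

Everything is deterministic given the seed: running twice with the same
config produces byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

__all__ = ["SimulationConfig", "SimulationResult", "simulate", "event_fixture"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``n_orthogroups`` is the ancestral gene count and defaults to
    ``contigs_per_sample * genes_per_contig``; an explicit conflicting value
    is an error.
    """

    n_samples: int = 8
    genes_per_contig: int = 30
    contigs_per_sample: int = 2
    n_orthogroups: int | None = None
    p_tandem_dup: float = 0.05
    p_loss: float = 0.05
    p_inversion: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "genes_per_contig", "contigs_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("p_tandem_dup", "p_loss", "p_inversion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        expected = self.contigs_per_sample * self.genes_per_contig
        if self.n_orthogroups is None:
            object.__setattr__(self, "n_orthogroups", expected)
        elif self.n_orthogroups != expected:
            raise ValueError(
                f"n_orthogroups={self.n_orthogroups} conflicts with "
                f"contigs_per_sample*genes_per_contig={expected}"
            )


@dataclass
class SimulationResult:
    out_dir: Path
    config: SimulationConfig
    events: list[dict]
    sample_ids: list[str]
    orthogroup_ids: list[str]
    orthogroups_tsv: Path
    species_tree: Path
    gene_trees_dir: Path
    msa_dir: Path
    gff_dir: Path


class _Node:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None, children=(), length=0.0):
        self.name = name
        self.children = list(children)
        self.length = length

    def newick(self) -> str:
        return self._fmt() + ";"

    def _fmt(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._fmt() for c in self.children)
        return f"({inner}):{self.length:.6g}"


def _random_sample_tree(samples: Sequence[str], rng: random.Random) -> _Node:
    """Random rooted binary tree; edge lengths uniform on [0.05, 0.15]."""

    def build(names: list[str]) -> _Node:
        if len(names) == 1:
            return _Node(name=names[0], length=rng.uniform(0.05, 0.15))
        split = rng.randint(1, len(names) - 1)
        return _Node(
            children=[build(names[:split]), build(names[split:])],
            length=rng.uniform(0.05, 0.15),
        )

    root = build(list(samples))
    root.length = 0.0
    return root


def _gene_tree(
    sample_tree: _Node, copies: dict[str, list[str]]
) -> _Node | None:
    """Sample tree with each leaf replaced by that sample's gene copies."""
    if not sample_tree.children:
        genes = copies.get(sample_tree.name, [])
        if not genes:
            return None
        if len(genes) == 1:
            return _Node(name=genes[0], length=sample_tree.length)
        # tandem copies: short rake under the sample's position
        return _Node(
            children=[_Node(name=g, length=0.01) for g in genes],
            length=sample_tree.length,
        )
    kids = [k for k in (_gene_tree(c, copies) for c in sample_tree.children) if k]
    if not kids:
        return None
    if len(kids) == 1:
        kids[0].length += sample_tree.length
        return kids[0]
    return _Node(children=kids, length=sample_tree.length)


def _mutate(motif: str, rng: random.Random) -> str:
    out = [
        rng.choice(_AA) if rng.random() < 0.05 else aa for aa in motif
    ]
    if rng.random() < 0.1 and len(out) > 6:  # occasional 3-column deletion
        i = rng.randrange(0, len(out) - 3)
        out[i : i + 3] = ["-", "-", "-"]
    return "".join(out)


def simulate(
    config: SimulationConfig,
    out_dir: str | Path,
    forced_events: list[dict] | None = None,
) -> SimulationResult:
    """Generate a full input set on disk plus the ground-truth event log.

    ``forced_events`` injects specific events regardless of the probabilities;
    each entry is ``{"kind": "tandem_duplication"|"loss", "sample": ...,
    "orthogroup": ...}``.  With all probabilities 0 and no forced events, all
    samples share the ancestral gene order exactly (the null model).
    """
    rng = random.Random(config.seed)
    out = Path(out_dir)
    gff_dir = out / "gff"
    trees_dir = out / "gene_trees"
    msa_dir = out / "msa"
    for d in (gff_dir, trees_dir, msa_dir):
        d.mkdir(parents=True, exist_ok=True)

    samples = [f"S{i:02d}" for i in range(1, config.n_samples + 1)]
    ogs = [f"OG{i:04d}" for i in range(config.n_orthogroups)]
    contigs = [f"ctg{i}" for i in range(1, config.contigs_per_sample + 1)]
    # ancestral order: og index -> (contig, position)
    ancestral: dict[str, list[str]] = {
        contig: ogs[i * config.genes_per_contig : (i + 1) * config.genes_per_contig]
        for i, contig in enumerate(contigs)
    }
    forced = forced_events or []
    events: list[dict] = []

    # evolve per-sample gene orders: list of (og, strand, copy_index)
    orders: dict[str, dict[str, list[tuple[str, str, int]]]] = {}
    for sample in samples:
        per_contig: dict[str, list[tuple[str, str, int]]] = {}
        for contig in contigs:
            genes: list[tuple[str, str, int]] = []
            for og in ancestral[contig]:
                forced_here = [
                    f
                    for f in forced
                    if f["sample"] == sample and f["orthogroup"] == og
                ]
                lost = any(f["kind"] == "loss" for f in forced_here) or (
                    rng.random() < config.p_loss
                )
                if lost:
                    events.append(
                        {
                            "kind": "loss",
                            "sample": sample,
                            "contig": contig,
                            "orthogroup": og,
                        }
                    )
                    continue
                genes.append((og, "+", 0))
                dup = any(
                    f["kind"] == "tandem_duplication" for f in forced_here
                ) or (rng.random() < config.p_tandem_dup)
                if dup:
                    genes.append((og, "+", 1))
                    events.append(
                        {
                            "kind": "tandem_duplication",
                            "sample": sample,
                            "contig": contig,
                            "orthogroup": og,
                            "gene_id": f"{sample}_{og}_c1",
                        }
                    )
            if len(genes) > 4 and rng.random() < config.p_inversion:
                start = rng.randrange(0, len(genes) - 3)
                seg_len = rng.randint(2, 4)
                seg = genes[start : start + seg_len]
                genes[start : start + seg_len] = [
                    (og, "-" if strand == "+" else "+", c)
                    for og, strand, c in reversed(seg)
                ]
                events.append(
                    {
                        "kind": "inversion",
                        "sample": sample,
                        "contig": contig,
                        "start_index": start,
                        "length": len(seg),
                    }
                )
            per_contig[contig] = genes
        orders[sample] = per_contig

    def gene_name(sample: str, og: str, copy: int) -> str:
        return f"{sample}_{og}" if copy == 0 else f"{sample}_{og}_c{copy}"

    # GFF3 per sample
    for sample in samples:
        lines = ["##gff-version 3"]
        for contig in contigs:
            for i, (og, strand, copy) in enumerate(orders[sample][contig]):
                start = 1 + i * 1000
                lines.append(
                    "\t".join(
                        [
                            contig,
                            "synfam-sim",
                            "gene",
                            str(start),
                            str(start + 599),
                            ".",
                            strand,
                            ".",
                            f"ID={gene_name(sample, og, copy)}",
                        ]
                    )
                )
        (gff_dir / f"{sample}.gff3").write_text("\n".join(lines) + "\n")

    # orthogroup membership
    membership: dict[str, dict[str, list[str]]] = {og: {} for og in ogs}
    for sample in samples:
        for contig in contigs:
            for og, _strand, copy in orders[sample][contig]:
                membership[og].setdefault(sample, []).append(
                    gene_name(sample, og, copy)
                )

    header = "Orthogroup\t" + "\t".join(samples)
    rows = [header]
    for og in ogs:
        cells = [", ".join(membership[og].get(s, [])) for s in samples]
        rows.append(og + "\t" + "\t".join(cells))
    og_tsv = out / "orthogroups.tsv"
    og_tsv.write_text("\n".join(rows) + "\n")

    # trees
    sample_tree = _random_sample_tree(samples, rng)
    sp_path = out / "species_tree.nwk"
    sp_path.write_text(sample_tree.newick() + "\n")
    kept_ogs: list[str] = []
    for og in ogs:
        if not membership[og]:
            continue  # lost everywhere
        kept_ogs.append(og)
        gt = _gene_tree(sample_tree, membership[og])
        if not gt.children:  # single surviving gene: keep a unifurcating root
            txt = f"({gt.name}:{gt.length:.6g});"
        else:
            gt.length = 0.0
            txt = gt.newick()
        (trees_dir / f"{og}.nwk").write_text(txt + "\n")

    # aligned FASTA per orthogroup (motif + point substitutions + rare dels)
    for og in kept_ogs:
        motif = "".join(rng.choice(_AA) for _ in range(40))
        recs = []
        for sample in samples:
            for g in membership[og].get(sample, []):
                recs.append((g, _mutate(motif, rng)))
        with open(msa_dir / f"{og}.fa", "w") as fh:
            for name, seq in recs:
                fh.write(f">{name}\n{seq}\n")

    (out / "events.json").write_text(
        json.dumps({"config": asdict(config), "events": events}, indent=1) + "\n"
    )

    return SimulationResult(
        out_dir=out,
        config=config,
        events=events,
        sample_ids=samples,
        orthogroup_ids=kept_ogs,
        orthogroups_tsv=og_tsv,
        species_tree=sp_path,
        gene_trees_dir=trees_dir,
        msa_dir=msa_dir,
        gff_dir=gff_dir,
    )


def event_fixture(
    out_dir: str | Path, seed: int = 0, n_samples: int = 4
) -> tuple[SimulationResult, dict]:
    """Dataset with exactly one tandem duplication and one loss.

    The duplicated orthogroup sits immediately downstream of a designated
    focal orthogroup and the lost one two genes upstream, so a window of
    radius >= 2 around the focal gene covers both events.  Returns the
    simulation plus a descriptor of the planted events.
    """
    config = SimulationConfig(
        n_samples=n_samples,
        genes_per_contig=21,
        contigs_per_sample=1,
        p_tandem_dup=0.0,
        p_loss=0.0,
        p_inversion=0.0,
        seed=seed,
    )
    focal_idx = 10
    info = {
        "focal_og": f"OG{focal_idx:04d}",
        "dup_og": f"OG{focal_idx + 1:04d}",
        "dup_sample": "S01",
        "loss_og": f"OG{focal_idx - 2:04d}",
        "loss_sample": "S03",
    }
    result = simulate(
        config,
        out_dir,
        forced_events=[
            {
                "kind": "tandem_duplication",
                "sample": info["dup_sample"],
                "orthogroup": info["dup_og"],
            },
            {
                "kind": "loss",
                "sample": info["loss_sample"],
                "orthogroup": info["loss_og"],
            },
        ],
    )
    return result, info
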