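# synfam

Gene-family analysis downstream of OrthoFinder usually means juggling an
orthogroups table, hundreds of gene trees, protein MSAs and genome
annotations across separate viewers. `synfam` turns those inputs into a
single static, searchable artifact: one JSON bundle per orthogroup (gene
tree, sub-cluster labels, MSA, multiple synteny alignment), a species
phylogeny bundle, a manifest and a prefix-search index — everything a
browser front-end, a notebook or a script needs to explore a gene family,
with no server and no rerun of the upstream analysis. It is aimed at
comparative genomicists who already have OrthoFinder-style results (it is
not tied to OrthoFinder's directory layout) plus GFF3/BED gene coordinates.

## The multiple synteny alignment

The novel computation is a *multiple synteny alignment* in
protein/orthogroup space rather than nucleotide or amino-acid space. For a
focal gene *g*, take the window of up to *k* genes on each side of *g* in
contig order and render each gene as a token carrying two homology labels:
its orthogroup *O* and its orthogroup **sub-cluster** — the maximal clade of
*O*'s gene tree in which every leaf pair is less than a branch-length
threshold τ apart. Two tokens **match** when they share an orthogroup and
**match perfectly** when they share a sub-cluster.

Windows are aligned like sequences: global Needleman–Wunsch with a linear
gap penalty over the token alphabet, with scores

| pair | score (default) |
|---|---|
| same sub-cluster | s_perfect = 2 |
| same orthogroup, different sub-cluster | s_match = 1 |
| different / unassigned orthogroup | s_mismatch = −1 |
| token vs gap | s_gap = −1 |
| gap vs gap (profile columns) | s_gapgap = 0 |

and alignments are merged progressively up the orthogroup's gene tree, which
is reused as the guide tree. Two profile columns are compared by
sum-of-pairs: every cell of one column is scored against every cell of the
other and the scores summed. The result is a gapped matrix — rows are focal
genes, columns are aligned gene-order positions. Conserved microsynteny
appears as columns monochromatic in orthogroup ("banding"); a tandem
duplication appears as an extra column private to one lineage, adjacent to
the duplicated gene.

## Worked example

The built-in generator plants known evolutionary events, so the output can
be read against a ground truth. Build a four-sample dataset with exactly one
tandem duplication (of `OG0011` in sample `S01`) and one loss (of `OG0008`
in `S03`), then index it and print the synteny alignment around `OG0010`:

```
$ python -c "from synfam import event_fixture; event_fixture('demo/data', seed=3)"
$ synfam build --input demo/data --out demo/site --k 5
INFO synfam: built 21 orthogroup bundles (0 anomalies) into demo/site
$ synfam synteny --input demo/data --orthogroup OG0010 --k 5
S01_OG0010  -           S01_OG0005  S01_OG0006  S01_OG0007  S01_OG0008  S01_OG0009  S01_OG0010  S01_OG0011  S01_OG0011_c1  S01_OG0012  ...
S02_OG0010  -           S02_OG0005  S02_OG0006  S02_OG0007  S02_OG0008  S02_OG0009  S02_OG0010  -           S02_OG0011     S02_OG0012  ...
S03_OG0010  S03_OG0004  S03_OG0005  S03_OG0006  S03_OG0007  -           S03_OG0009  S03_OG0010  -           S03_OG0011     S03_OG0012  ...
S04_OG0010  -           S04_OG0005  S04_OG0006  S04_OG0007  S04_OG0008  S04_OG0009  S04_OG0010  -           S04_OG0011     S04_OG0012  ...
```

The first column names each row's focal gene; `-` is a gap. Reading the
matrix: the column holding `S01_OG0011` is private to `S01` and sits
immediately next to the focal column — the signature of the planted tandem
duplication (its two copies, `S01_OG0011` and `S01_OG0011_c1`, occupy
adjacent columns of that row). In `S03`'s row the single gap in the
`OG0008` column marks the planted loss. Every other column is monochromatic
in orthogroup — conserved synteny banding.

Sub-clusters for the duplicated orthogroup, at a threshold tighter than the
between-sample divergence (total path length, here τ = 0.1):

```
$ synfam subclusters --tree demo/data/gene_trees/OG0011.nwk --tau 0.1 --orthogroup OG0011
S01_OG0011      OG0011.0
S01_OG0011_c1   OG0011.0
S02_OG0011      OG0011.1
S03_OG0011      OG0011.2
S04_OG0011      OG0011.3
```

The tandem pair (0.02 apart in the gene tree) shares sub-cluster
`OG0011.0`; each other sample's copy is its own sub-cluster, so only the
tandem pair scores as a perfect match in synteny alignment.

Other subcommands: `synfam search --site demo/site --query s01_og001`
(case-insensitive prefix search), `synfam export --site demo/site
--orthogroup OG0010 --samples S01,S02 --what msa --out sub.fa` (sample-subset
MSA with all-gap columns dropped), and `synfam simulate` to generate
datasets from the command line.

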