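# Methods

## Scope and data model

`synfam` consumes OrthoFinder-style results — an orthogroups table
(orthogroup × sample → gene IDs), one rooted newick gene tree per
orthogroup, a newick species phylogeny, optional aligned protein FASTA per
orthogroup, and per-sample GFF3 or BED gene coordinates — and emits static
JSON bundles plus a search index. Trees are used rooted exactly as written:
upstream tools emit rooted gene trees, and silent re-rooting would change
sub-cluster assignments. Coordinates are normalized internally to 1-based
inclusive intervals (GFF3 convention; BED's 0-based half-open intervals are
converted on read). Gene order within a contig is the rank by ascending
start coordinate (ties broken by end, then gene ID); strand does not affect
rank, because the synteny view is positional.

Genes present in the annotation but absent from the orthogroups table are
kept as *unassigned* tokens: singletons are real genes and must occupy
alignment positions, they simply never match anything.

## Orthogroup sub-clusters

Given a gene tree with branch lengths and a threshold τ (total path length,
same units as the tree), the sub-clusters are the **maximal clades whose
every internal leaf pair is strictly less than τ apart** (leaf-to-leaf path
length through their common ancestor). Strict `<` makes τ = 0 yield
all-singleton clusters. The pairwise criterion could also be read
non-transitively ("some ancestor less than τ away"), but only the clade
reading guarantees a partition and monophyly, which downstream labelling
requires; the leaf↔leaf distance (rather than ancestor↔leaf) is the
implemented variant. Computation is a single post-order pass tracking each
clade's height and maximal internal leaf-pair distance, then a pre-order
sweep selecting the topmost qualifying clades; a clade with fewer than two
leaves has no pairs and qualifies vacuously. Labels are
`<orthogroup>.<k>` with `k` numbered by each sub-cluster's leftmost leaf in
tree order, so repeated runs produce identical labels. Multifurcations are
handled natively; nothing is binarized.

The test-suite oracle is a brute-force search that checks every clade
against every leaf pair and keeps the unshadowed qualifying clades; the two
routes share no traversal code. Sub-cluster partitions are monotone in τ
(smaller τ refines larger), which the suite verifies over a τ grid.

## Synteny tokens and scoring

A focal gene's neighborhood is the up-to-`k` genes on each side in contig
order (truncated at contig ends), each rendered as a token `(gene,
orthogroup, sub-cluster)`. Tokens from *other* orthogroups inside the
window keep their own labels — cross-window matches are what produce
consistent banding. If the focal gene lies on the minus strand, the token
order is reversed so inverted loci band together; this orientation
normalization can be disabled (`normalize_strand=False`).

Token scores: same sub-cluster 2 (perfect), same orthogroup 1 (match),
otherwise −1 (mismatch, including any unassigned gene), token-vs-gap −1,
gap-vs-gap 0. The match categories are structural; the magnitudes are a
design choice constrained by `s_perfect ≥ s_match > s_mismatch`, `s_gap <
0`, `s_gapgap = 0`, and are exposed in `ScoringScheme`. The gap penalty is
linear: it is the base Needleman–Wunsch formulation, it keeps the
exhaustive-enumeration oracle tractable, and nothing in the problem demands
affine gaps (an extension point, not a config flag).

## Pairwise and profile alignment

Pairwise alignment is standard global Needleman–Wunsch maximization over
tokens. Profile-profile alignment runs the same DP over *columns*, scored
by sum-of-pairs: the score of two columns is the sum of token scores over
their full cross product. Aligning a column against a gap is scored as that
column against an all-gap column of the other profile's height — each real
token pays `s_gap` once per opposing row, gap cells pay nothing. This keeps
the algebra closed: the total of all merge scores over a progressive run
equals the sum-of-pairs score of the final matrix (each unordered row pair
crosses the merge frontier exactly once, and gap columns inserted later
contribute 0 within already-merged rows). The suite asserts this identity
at 1e-9.

Traceback ties break **diagonal, then up (gap in the second profile), then
left**, fixed, so identical inputs give byte-identical profiles. One
consequence used by the tandem-duplication readout: when a row carries two
adjacent same-sub-cluster copies and the others carry one, the diagonal
preference aligns the *rightmost* copy with the others, leaving the first
copy in a private column on the focal-gene side.

## Progressive alignment on the guide tree

The orthogroup's gene tree doubles as the guide tree. Each leaf with
coordinates yields a 1-row profile; each internal node merges its
children's profiles left to right (multifurcations fold sequentially in
child order); the root's profile is the multiple synteny alignment, its row
order the tree's left-to-right leaf order. Leaves without coordinates are
dropped from the profile with a warning but remain in tree and MSA views —
coordinates are only required for this figure type. Every produced profile
satisfies the projection invariant: deleting a row's gaps reproduces that
row's input token string exactly.

When the user restricts a build to a sample subset, trees are pruned first
and the alignment runs on the pruned tree; the alternative (align on the
full tree, subset rows for display) gives columns informed by excluded
samples, which is defensible for interactive filtering but surprising for a
subsetted build artifact.

## Tree views

* **Pruning** to a sample subset returns the induced tree; suppressed unary
  nodes have their branch lengths summed, so surviving leaf-pair distances
  are preserved exactly (verified on random trees).
* **Collapse at depth D** (root = depth 0) replaces internal nodes at depth
  D by terminal stubs annotated with their exact descendant leaf count;
  counts are conserved.
* **Subtree zoom** extracts a clade as a standalone tree with its root edge
  reset to 0. **Path annotation** returns the root-to-leaf node-id chain
  for highlighting a searched gene. Node ids are leaf labels for leaves,
  the newick label when present for internal nodes, else `n<preorder
  index>` — deterministic for a fixed topology.

## Static index

Bundles are plain JSON (one file per orthogroup, plus `manifest.json`,
`phylogeny.json`, `search_index.json`), written with sorted keys and fixed
layout so rebuilding on identical input is hash-identical. The on-disk
schema is defined here, not inherited from any viewer, keeping the artifact
front-end-agnostic. The search index is a sorted list of lowercase keys for
bisect-based case-insensitive prefix lookup with a result limit. Sequence
export either strips gaps (`fasta`) or keeps rows aligned and drops columns
that became all-gap after the sample subset (`msa`) — what a viewer
filtering "dynamically" would show. A gene-tree leaf that is not a member
of its orthogroup is recorded as an anomaly in the bundle and the manifest
rather than being an error.

## Synthetic data generator

The generator emulates the full input set at toy scale: an ancestral gene
order (every ancestral gene founds one orthogroup) evolved along a random
rooted binary sample tree with uniform [0.05, 0.15] edge lengths. Events
are applied per terminal branch: tandem duplication (adjacent same-
orthogroup copy, default probability 0.05/gene), loss (0.05/gene), and
segmental inversion of 2–4 genes with strand flips (0.02/contig); defaults
chosen to put a handful of each event into a typical 8-sample × 60-gene
dataset, dense enough to exercise every code path without drowning the
conserved background. All events are logged as ground truth, and specific
events can be forced for planted-event fixtures. Gene trees mirror the
sample tree restricted to carriers, with tandem copies on short 0.01 edges
so a τ between the duplication scale and the between-sample scale isolates
duplicate clades. Emitted MSAs are a per-orthogroup motif with 5% point
substitutions and occasional 3-column deletions — enough to exercise MSA
plumbing, not a model of sequence evolution.

What the generator does **not** emulate: events on internal branches
(shared ancestral duplications/losses), whole-genome duplication,
rearrangement breakpoint realism, annotation errors such as split gene
models, or realistic sequence evolution. Passing tests therefore
demonstrate algorithmic correctness on clean, lineage-private events; they
do not certify behavior on noisy real annotations, where unassigned genes
and split models will add mismatch tokens and extra columns.

## Problem sizes and numerical choices

The suite and the acceptance script run at desk scale, chosen to exercise
every code path while staying quick: 200 random token pairs (length ≤ 6)
for the alignment oracle, 100 random trees (≤ 8 leaves for the sub-cluster
oracle, ≤ 12 for conservation laws), a 20-sample × 25-gene dataset with
21-token windows for the projection check, and 4–8-sample datasets
elsewhere. Scores are plain floats; the only tolerance in use is 1e-9 for
the merge-score audit (pure summation noise). Degenerate inputs are
defined, not special-cased: `k = 0` gives single-token windows, τ = 0 gives
singleton sub-clusters, a single-leaf guide tree returns its neighborhood
unchanged, and empty profiles, empty sample selections and missing loci are
explicit errors.

## Known limitations

Progressive alignment is greedy: the guide-tree merge order can lock in a
column placement a simultaneous multiple alignment would avoid (ties are
merely placed deterministically, never re-optimized). Sum-of-pairs profile
scoring is O(r₁·r₂) per column pair, fine for hundreds of rows but not
thousands. Gap placement at window boundaries reflects window truncation
rather than biology when neighborhood lengths differ. GFF3 parsing reads
flat gene features only (configurable type/attribute); it does not
reconstruct parent/child hierarchies.
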