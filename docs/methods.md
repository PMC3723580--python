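# Methods

This note documents the statistical procedures, the parameter defaults
and the design choices behind `crossomics`, and what the synthetic
test-beds do and do not establish about real data.

## Data model

An omics table is a molecules × conditions matrix of real values, one
table per layer (T = transcriptomics with Entrez Gene IDs,
P = proteomics with UniProtKB accessions, M = metabolomics with PubChem
CIDs). Identifiers are namespaced: a gene "123" and a metabolite "123"
are distinct objects everywhere, which is why network exports label
nodes with a layer prefix ("T:123"). Condition labels are opaque
strings; time-series ordering is taken from column order and never
parsed from the labels. Tables must have at least two condition
columns and unique row IDs. The empty string and `NA` parse as missing
values; any other non-numeric cell is an error naming its row and
column — silently coercing would hide upload mistakes in exactly the
place users cannot inspect later. Missing-data policy downstream is
per-analysis: correlation uses pairwise-complete observations,
coexpression drops incomplete rows (logged), enrichment and phenotype
mapping operate on ID sets and ignore values entirely.

The reference knowledgebase is a directory of five TSV snapshots
(relation triples, pathway sets, GO annotations, phenotype records,
name synonyms). GO and phenotype files are optional; their absence
disables those analyses rather than failing the load. Provenance of a
relation triple is a free-form evidence tag (here always
"literature"), so an online text-mining source could be plugged in
later without schema changes.

## Correlation network

Pearson correlation is computed for every molecule pair across the
shared condition sequence, on pairwise-complete observations. A pair
with fewer than `min_shared_obs` (default 3) shared finite values, or
with zero variance on the shared support, is *undefined* — excluded
from edge formation — rather than forced to 0; a constant row is
evidence of nothing, and one bad row must not abort a run.

An edge is drawn iff r > `pcc_threshold`, strictly, with default 0.9.
The threshold is signed by default: strong anti-correlations are not
edges unless `use_absolute` is set. The strictness and the signed
default mirror the convention of drawing only positive co-behaviour;
the absolute-value mode is provided because anti-correlated regulation
is often equally informative.

When exactly two layers are supplied, the missing third layer is
bridged: every third-layer molecule that co-occurs in a relation
triple with an input molecule joins the network as a literature-origin
node, connected to each of its input partners by an unweighted edge
(rendered dotted; solid strokes are reserved for measured
correlations). Bridged molecules carry no expression vector and can
never form correlation edges.

Clusters are connected components of size ≥ 2, ranked by descending
size, ties broken by the lexicographically smallest member ID so that
reruns and tests are deterministic. Literature edges participate in
connectivity by default (`literature_in_clusters=False` reverts to
correlation-only components). Isolated nodes are drawn but not ranked.

Layout is a Fruchterman–Reingold-style loop (100 iterations, geometric
cooling) with all-pairs repulsion ~ k²/d and per-edge attraction
~ d²/k. The `repulsion` (default 160) and `attraction` (default 80)
parameters scale the two force terms relative to those defaults, so
the defaults reproduce the plain algorithm. Initial placement is drawn
from a seeded generator (`layout_seed`); a single node sits at the
origin by convention. The layout exists to make the SVG/PNG scenes
readable; no analysis consumes coordinates.

Exports: SIF (`source TAB relation TAB target`, relation `cor` or
`lit`, canonically sorted) for Cytoscape-style editors; SVG 1.1 with
squares/triangles/circles for transcripts/proteins/metabolites in
green/red/blue and dashed strokes on literature edges; PNG via
matplotlib.

## Coexpression

Rows (molecules from up to three stacked layers) and columns
(conditions) are clustered agglomeratively on Euclidean distance.
Linkage is complete by default — the common default of R
`hclust`/`gplots`-style heatmap stacks — configurable
to single or average. The merge trees are scipy linkage matrices; the
agglomeration is deterministic, with equal-distance ties resolved by
scipy's internal (nearest-neighbor-chain) ordering. Colors map the
global matrix minimum to cyan and the maximum to pink, on the raw
input values by default ("what you uploaded is what is colored");
`scale="row_z"` standardizes each row to mean 0 / variance 1 first,
dropping constant rows for which a z-score is undefined. A fully
constant matrix maps every cell to the mid color 0.5. The SVG renderer
lays the cell grid out in leaf order with dendrograms top and left and
the omics color strip along the row edge, and is byte-deterministic.

## Pathway enrichment

Inputs are an overall metabolite set A (size N) and a significantly
changed subset B ⊆ A (size n). For a pathway containing m members of
A and x members of B, the reported probability is the lower-tail
cumulative hypergeometric P(X ≤ x): the probability of seeing x *or
fewer* of the pathway's mapped metabolites in the significant subset
under random sampling of n from N. Pathways are ranked by this
probability, descending, ties by pathway ID; a pathway whose mapped
members all reach the significant set attains probability exactly 1
and ranks first. Because most enrichment tools report the opposite
tail, the table also carries `upper_tail_p` = P(X ≥ x) so the result
reads both ways without re-computation. Pathways with m = 0 are
omitted (a pathway sharing nothing with the uploaded set is not a
finding); no further minimum-m filter is applied. The "normal" mode
skips the statistics and lists mapped members ranked by m. The tail
probabilities come from `scipy.stats.hypergeom`; tests pin them to
exact rational-arithmetic summation at 1e-12.

## GO over-representation

For query gene set q against background B (default: every gene with at
least one GO annotation in the knowledgebase), each term with K
annotated background genes and k annotated query genes is scored with
the one-sided (greater) Fisher's exact p-value, i.e. the
hypergeometric upper tail of the 2×2 table (k, |q|−k, K−k,
|B|−|q|−K+k). The default `ease` method first replaces k by
max(k−1, 0) — the conservative variant that discounts single-gene
hits, for which it returns exactly p = 1. FDR is Benjamini–Hochberg,
applied within each ontology (BP, CC, MF) separately, matching the
sectioned per-ontology reporting convention; the display set is terms
with raw p < `alpha` (default 0.05), with the full table retained.
Query genes must be a subset of the background at the library level;
the pipeline intersects the uploaded transcript list with the
annotated background first and logs what it dropped, since uploads
routinely contain unannotated genes.

## Phenotype mapping

Phenotype records are gene sets with OMIM-style numeric IDs. Input
genes match directly; input proteins are translated to genes through
the relation-triple table (proteins with no relation are skipped with
a logged warning — inventing a gene for them would be worse). One
output row per phenotype aggregates all matched genes and all
contributing input molecules and carries an `OMIM:<id>` external
reference string. Metabolomics-only input is rejected with a
capability error: metabolites carry no gene context.

## Capability matrix and pipeline

The seven modes × five analyses matrix is encoded once in
`capabilities.py` and enforced by `plan()`: correlation and
coexpression everywhere; phenotype everywhere except M alone; pathway
enrichment iff M is present; GO iff T is present; two-layer modes
bridge their missing layer for the network. In mixed modes GO runs on
the T layer alone, since the test consumes gene IDs. The pipeline runs
stages in a fixed order (bridge → correlation → coexpression →
pathway → GO → phenotype), writes a `manifest.json` of outputs,
parameters and summary counts, and is deterministic: identical inputs
and seeds yield identical manifests and byte-identical CSV/SIF/SVG
outputs (matplotlib rasters are made reproducible by fixing the SVG
hash salt and stripping timestamps). Input tables are not copied into
the output directory unless `keep_inputs` is set.

## Synthetic test-beds

Two generators make every test and the acceptance studies run offline
with known ground truth.

`knowledgebase.generate_fixture(seed)` writes a snapshot with (by
default) 60 genes, 40 proteins, 150 metabolites, 80 relation triples,
20 pathways (members drawn uniformly, sizes 5–12), 30 GO terms (sizes
3–10 across the three ontologies) and 25 phenotype records. The first
pathway and the first GO term are "planted" and recorded in a
manifest so recovery tests are self-describing. Output is
byte-deterministic per (seed, sizes).

`simulate(design)` builds omics tables from block designs: every
molecule in a block is its block's latent profile plus i.i.d. Gaussian
noise. Profiles are drawn once per design from a standard normal over
the conditions and, by default, orthogonalized (Gram–Schmidt, rescaled
to ~unit variance), which pins the between-block latent correlation at
exactly zero; with few conditions, two *random* profiles can exceed
the 0.9 correlation threshold by chance, which is a property of short
random vectors, not of the clustering. The default recovery study
uses 8 conditions, blocks of 12 transcripts and 8 proteins, and
noise_sd = 0.03 against ~unit-sd profiles (3% noise): within-block
correlations then sit near 1/(1 + noise_sd²) ≈ 0.999 and between-block
correlations near 0, so the planted partition is recoverable at the
default threshold.

What these test-beds establish: that the statistics match their exact
definitions, that network construction and clustering are correct
graph-theoretically, and that the pipeline recovers structure it is
mathematically entitled to recover. What they do not establish:
performance on real multi-omics data — real expression is
heavy-tailed, block structure is not clean, relation/pathway/GO
annotation is biased and incomplete, and real condition counts are
often small enough that correlation estimates are noisy. The planted
studies are calibration checks, not benchmarks.

## Numerical and policy choices

- Hypergeometric/Fisher tails: `scipy.stats.hypergeom` (log-space
  internally), verified to 1e-12 against exact rationals for N ≤ 25
  exhaustively and on random instances beyond.
- Strict `>` at the correlation threshold; an exactly-threshold pair
  is not an edge.
- Undefined correlations (NaN) never become edges and never become 0.
- Cluster and ranking ties: lexicographic by ID, for reproducibility.
- BH FDR via `statsmodels.stats.multitest`; input order preserved.
- CSV writer emits `repr(float)` so write→read→write round-trips are
  bit-identical; missing cells serialize as the empty string.
- Acceptance problem sizes (N ≤ 25 exhaustive, 500 Fisher instances,
  200 random networks ≤ 50 nodes, 50 recovery seeds, 100 + 200
  enrichment replicates) were chosen as the smallest sizes that
  exercise every code path and tail regime while keeping the whole
  verification run in seconds.

## Known limitations

- No live database access: users must convert their own KEGG/
  HumanCyc/GO/OMIM/UniProt exports into the documented TSV schema.
- Bridging returns *all* literature partners of the input molecules;
  in dense relation tables the dotted edges can dominate the scene
  (prune via the threshold or by disabling literature edges in
  clustering).
- The coexpression heatmap does no optimal leaf ordering.
- Pathway enrichment treats pathways as flat metabolite sets; no
  topology or impact analysis.
- The EASE correction is applied to the count, not derived from a
  full DAVID-compatible annotation pipeline; results on real GO
  snapshots will differ from DAVID's to the extent the annotation
  universes differ.
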