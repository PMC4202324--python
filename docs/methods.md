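# Methods

This note documents the models, parameters and design choices behind
`linecns`, and what the synthetic-data tests do and do not establish about
real genomes.

## Coordinates and formats

Internally all coordinates are 0-based half-open. GFF3 I/O converts to/from
1-based inclusive; BED is native 0-based half-open; methylation tables are
read as (chromosome, 1-based position, strand, context) and converted on
input. Interval merging (used for the ancestral-CNS superset) also merges
*abutting* intervals, because the merged set represents covered ancestral
sequence rather than hit identity.

## Alignment engine and statistics

The search engine is a self-contained nucleotide seed-and-extend aligner:

- **Seeding.** Exact shared w-mers (default w = 11), on both strands by
  default. Seeds never start in masked bases (lowercase or N, soft-masking
  semantics); extension may cross masked bases, scoring every masked column
  as a mismatch. Seeds falling inside an already-extended alignment on the
  same diagonal band are skipped.
- **Extension.** Anchored X-drop extension in both directions from the seed,
  with affine gaps (default match +1, mismatch −2, gap open −5, gap extend
  −2; a gap of length k costs open + k·extend). The DP keeps a contiguous
  window of subject offsets per query row and trims it to cells within
  `x_drop` (default 30) of the running best; extension length is capped at
  `max_extension` (default 3000) per direction. The final gapped strings are
  recomputed by banded global alignment of the bounded segments; the reported
  score is the extension score.
- **Statistics.** λ is the unique positive root of
  Σ pᵢpⱼ e^{λ s(i,j)} = 1 (bisection to 1e−12); K follows the lattice-case
  series K = δ·λ·e^{−2σ} / (H·(1−e^{−λδ})) with
  σ = Σ_j (1/j)·(P(S_j ≥ 0) + E[e^{λS_j}; S_j < 0]), truncated when a term
  falls below 1e−8. For the default scheme this gives λ = 1.3327,
  K = 0.6210, matching the published ungapped blastn constants. Gapped
  scores reuse the ungapped λ and K — a stated approximation; exact gapped
  calibration is out of scope. E = K·m·n·e^{−λS} with m the individual query
  length and n the total subject length; E ≤ 0.001 (inclusive) is
  significant.
- **Exactness.** When the optimal local alignment between two sequences
  contains an exact shared unmasked w-mer and the X-drop is large enough not
  to prune the optimal path, the engine returns the full Smith–Waterman
  optimum (the optimum decomposes into best-left-extension + seed +
  best-right-extension). The test suite verifies this on hundreds of seeded
  random pairs against an independent full-matrix Gotoh implementation, using
  x_drop = 150 ("exact mode"); the default x_drop = 30 trades a small amount
  of tail exactness for speed on genome-scale inputs.
- **Determinism.** Hits sort by ascending E, ties by higher score, then query
  (chromosome, start).

## Discovery pipeline

- **Chained common search.** Step 1 aligns the reference genome against the
  second species; hits overlapping CDS on either side (and, when supplied,
  ncRNA intervals on the query side) are removed; overlapping query hits are
  resolved greedily by ascending (E, −score, query start). Each surviving
  candidate is a reference subsequence. Every further step searches the
  candidates against the next genome with the same filters; a candidate
  survives iff at least one significant noncoding hit remains and is
  *trimmed to its best hit's aligned query span*, so the final coordinates
  are the conserved core supported in every chain species. Candidates
  shorter than `min_length` (default 15 bp) after trimming are dropped.
- **Outgroup exclusion.** A common CNS is lineage-specific iff it has no hit
  with E ≤ cutoff anywhere in each outgroup genome — including outgroup
  coding regions. Restricting outgroup presence to noncoding context would
  call an element "specific" even when its sequence survives in an outgroup
  exon; the unrestricted rule is the conservative choice for specificity.
- **All-pairs unions.** One search per unordered pair (C(n,2); 105 for 15
  species). Unions across pairs need a common coordinate system, which the
  pairwise design does not supply globally; each internal tree node therefore
  reports the merged union on a per-node reference leaf (the configured
  global reference when it belongs to the clade, otherwise the clade's first
  leaf), over the pairs that involve that leaf. Along the path of clades
  containing the global reference the pair sets are nested, so union counts
  are monotone from child to root.
- **Dollo loss counting.** Each ancestral element originates once at the root
  of the ingroup tree (it is present in the basal reference by construction);
  the minimum-loss explanation of a presence pattern places one loss on the
  stem of each maximal all-absent clade, found in a single post-order pass.
  An all-absent pattern yields one loss on the ingroup stem (the root's own
  branch). The implementation is checked against exhaustive minimum-subset
  enumeration over all rooted trees with up to 6 leaves and every
  presence pattern, at per-branch resolution.

## Annotation

Location classes use UTR > intron > intergenic precedence: any UTR-feature
overlap wins (5′ vs 3′ by larger overlap, ties to 5′); otherwise a CNS fully
inside a gene span with no exon overlap is intronic; everything else is
intergenic. Percentages are rounded half-up to one decimal. Each category is
compared to the genome's noncoding composition with a one-proportion z-test
(normal approximation, two-sided) — the test behind the printed location
tables is not specified in more detail than "P value", so this simple,
reproducible choice is used and no claim is made to reproduce
genome-scale table p-values. Nearest-gene assignment is edge-to-edge with
exact ties reported both ways (primary = lexicographically smaller id);
synteny uses a 5,000-bp inclusive edge-to-edge range. Enrichment is a
hypergeometric upper tail P(X ≥ k) per term with Benjamini–Hochberg
adjustment across terms; the term database is supplied by the user.

## Sequence profiles

- **A+T borders.** 1,000-bp flanks each side plus a 20-bp center on the CNS
  midpoint (the floor midpoint of the reference interval), 10-bp windows at
  1-bp step, computed within each segment (no windows span segment
  junctions, so differing CNS lengths cannot blur the border). CNSs whose
  flanks touch CDS or a chromosome end are excluded and counted. Two Welch
  t-tests are reported: the headline test compares flank vs center *window
  values of the averaged profile* (the natural reading of a moving-window
  analysis), and a per-CNS-means variant (`t_cns`, `p_cns`) treats elements
  as independent units. The window-value test is anticonservative —
  overlapping windows are autocorrelated and positions share the same CNS
  set — so its p-values overstate significance; the per-CNS test is valid
  but has little power at small element counts because the center is only
  20 bp. Both numbers are always reported.
- **Nucleosome occupancy.** The published probabilistic occupancy model is an
  external artifact and is *not* re-implemented; the module defines a model
  interface (sequence → per-base probability in [0,1]) plus a built-in
  stand-in: a logistic of 147-bp windowed G+C content with a phased
  A/T-dinucleotide periodicity bonus at 10.25 bp (the helical repeat on the
  histone octamer). Profiles average the model over ±4,000 bp around each
  CNS center; the matched control resamples noncoding intervals with the
  same lengths and A+T within ±1 percentage point (rejection sampling,
  explicit seed, hard failure after 10⁴ tries per element); the unmatched
  control has no composition constraint. Welch's t compares per-element mean
  occupancy over the central 147 bp, CNS vs matched control.
- **Methylation.** An interval counts methylated iff ≥1 call of any context
  (CG/CHG/CHH) on either strand falls inside it. Random sets are
  length-matched noncoding intervals (n_sets × |CNS set| elements); the
  pooled two-proportion z-statistic is used, and a degenerate pooled
  proportion (0 or 1) is reported as not testable rather than ±∞.

## Phylogenetics

Center-star multiple alignment (center = sequence maximizing mean pairwise
identity; pairwise global alignments via Biopython's PairwiseAligner under
the search scoring scheme; merge under "once a gap, always a gap");
all-pairs identity < 40% flags the alignment low-confidence. Distances are
Kimura 2-parameter with pairwise deletion of gapped columns; saturation
(non-positive log arguments) is an error for a single distance and a capped
value (default 10 substitutions/site) inside bootstrap replicates. K2P was
chosen over a composite-likelihood distance because it is closed-form and
directly testable, and the downstream claims are topology plus bootstrap
support, which K2P supports. Neighbor-joining follows Saitou–Nei with ties
in the Q-criterion broken to the lowest taxon-index pair and negative branch
lengths clamped to zero; bootstrap resamples columns with replacement and
reports the percentage of replicates containing each split of the full-data
tree.

## Synthetic data

The simulator evolves a block-structured ancestral genome down a Newick tree
with branch lengths in substitutions/site:

- **Architecture.** Alternating intergenic and gene blocks; each gene is
  5′UTR (120 bp) + 4 CDS exons (300 bp) separated by 3 introns (400 bp) +
  3′UTR (170 bp), with 3,477 bp intergenic per gene — giving a noncoding
  composition of ≈70% intergenic / 24.2% intron / 5.8% UTR, the composition
  of the rice noncoding genome. Background base composition is A+T 0.56 (the
  rice genomic average); planted elements use A+T 0.54.
- **Evolution.** K2P substitution kernel (transition/transversion ratio 0.5
  = Jukes–Cantor by default; raising it exercises the K2P distance with
  Q ≠ P). Planted elements evolve at a scaled rate (default 0.05× —
  conserved but not frozen). Indels (default 0.002 events/site per
  substitution unit, geometric lengths capped at 10 bp) occur only in
  intergenic background, keeping annotation and ground-truth coordinates
  exact; coding sequence evolves at the background rate because the pipeline
  filters coding regions by annotation, not by conservation.
- **Lineages and losses.** An element assigned to a tree node is retained in
  exactly the leaves below it and deleted on each branch hanging off the
  root path — each deletion is recorded as a loss event, so Dollo counting
  can be validated against ground truth exactly.
- **Elements.** Lengths are lognormal (median ≈80 bp, σ = 0.45) clipped to
  [40, 400] bp by default, within the length range reported for plant
  lineage-specific CNSs; the 40-bp floor keeps elements above the seeding
  detectability threshold at the default divergences.
- **Reproducibility.** Every draw flows from one master seed through named
  substreams (per branch, per block, per track); identical configurations
  give byte-identical outputs.

The discovery preset uses a five-species ingroup chain with 0.25
substitutions/site per branch and two deeper outgroups, 50 ingroup-lineage
elements plus 15 shared and 10 outgroup-only elements, on ~100-kb genomes
(16 genes per species). These problem sizes keep a full simulate-and-discover
cycle around half a minute while leaving adjacent species realistically
alignable (~64% background identity) and distant chain species beyond
background detectability, which is the regime the chained design relies on.

**What the simulator does not emulate:** repeat landscapes and segmental
duplication (so paralogy and masking stress are untested), genome
rearrangement (gene order is conserved, so synteny is trivially satisfied),
indels inside conserved elements (trimming robustness is only exercised via
the dedicated flag), rate variation across sites, and biased gene
conversion. Passing the planted-recovery tests therefore shows the pipeline
logic is correct under its own model assumptions, not that real-genome
sensitivity matches the simulated one.

## Known limitations

- Gapped e-values reuse ungapped λ/K; absolute e-values are approximate,
  though ordering (and hence best-hit resolution) is robust.
- The chained search is order-sensitive by design, as in the original study
  layout; no attempt is made to symmetrize it.
- The all-pairs union coordinates are reference-leaf-relative per node (see
  above), so counts at nodes off the reference path are not directly
  comparable to each other.
- The one-proportion z-test and the window-value t-test use normal
  approximations whose validity degrades at very small counts; exact
  alternatives were not required by any downstream decision.
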