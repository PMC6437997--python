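# Methods

## The deduplication model

A droplet library is modelled as a set of pre-PCR molecules, each a
(cell, gene, transcript, UMI) tuple. PCR amplifies whole molecules before
fragmentation, so reads from one molecule can start at different positions
of the transcript and therefore land in *different* transcript equivalence
classes; conversely, UMIs acquire errors during amplification and
sequencing, so reads of one molecule can carry *different* UMIs. Per cell,
every observed (UMI, equivalence class) pair becomes a vertex of the
parsimonious UMI graph with its read count c:

- a **directed edge** v_i → v_j is added when the UMIs are at Hamming
  distance exactly 1, the transcript sets intersect, and c_i > 2c_j − 1
  (equivalently c_i ≥ 2c_j for integer counts): v_j is plausibly an
  amplification/sequencing error of v_i;
- pairs with intersecting transcript sets at Hamming distance ≤ 1 that get
  no directed edge are joined by one **bi-directed edge**. In particular,
  vertices sharing a UMI verbatim but carrying different (overlapping)
  classes — the signature of fragmentation-position splitting — are joined
  at distance 0.

After edge formation the counts play no further role. The deduplicated
molecule count is a minimum-cardinality covering of this graph by
vertex-disjoint **monochromatic arborescences**: rooted trees, traversing
directed edges forward and bi-directed edges either way, whose vertices'
transcript sets have a non-empty intersection. Each arborescence is one
molecule; the intersection is its feasible transcript set.

Two count conventions about the directional rule coexist in the field:
c_m > 2c_n + 1 for the classic error-collapse criterion and c_i > 2c_j − 1
for the graph's directed edges. This package uses the latter throughout,
since it is the rule that governs graph construction; the two differ by one
read in the boundary case and we do not attempt to reconcile them.

### Greedy covering

Finding the minimum covering is NP-complete: an undirected graph with each
node labelled by its closed neighbourhood (implemented in
`dominating_set_pug`) has a covering of size k iff the graph has a
dominating set of size k. The production path is therefore greedy: weakly
connected components are processed independently (in order of smallest
vertex index); within a component, every remaining (vertex, transcript)
pair is scored by the size of its colour-restricted BFS reachable set, the
largest is emitted as an arborescence and removed, and the process repeats.
Each iteration removes at least one vertex, so termination is linear in the
component order. Ties are broken on the smallest (vertex insertion index,
transcript id) — deterministic without a seed; a seeded random tie-break
mode exists but is off by default. `brute_force_cover` (exhaustive dynamic
programming over vertex subsets, guarded to ≤ 12 vertices) exists purely as
a test oracle; on 500 random 8-vertex graphs the greedy covering matches
the exact minimum in ≈ 99% of instances and never beats it.

On single-transcript data the covering reduces to directional UMI
clustering. The comparator used in tests (`directional_cluster_count`)
re-implements the same collapse rule directly on a {UMI: count} dictionary
— directed link at Hamming 1 when c_i > 2c_j − 1, undirected link
otherwise, greedy max-reach cluster growth — with none of the graph or
equivalence-class machinery. Note this is *not* the classic
directional-adjacency clusterer: that one never merges, say, counts (3, 2)
at Hamming distance 1, whereas the parsimony model joins them with a
bi-directed edge and collapses them to one molecule.

### EM and tiers

Arborescences whose feasible set spans several genes contribute one
molecule each to an EM that splits them across their gene sets
proportionally to current abundances (uniformly where all are zero), with
abundance *not* divided by an effective length — tagged-end protocols have
no fragment-length effect. Each molecule has weight 1 regardless of its
read count. Convergence: maximum absolute count change < 1e-3 (absolute
molecules) or 1000 iterations; conservation of the total molecule count
holds exactly at every iteration, and the implied multinomial
log-likelihood is non-decreasing (asserted in tests). Tiers per cell and
gene: 0 = no reads; 1 = evidence only from classes whose transcripts all
belong to one gene; genes in a connected component of the multi-gene-class
transcript graph are tier 2 if the component contains a tier-1 gene
(unique evidence anchors the EM) and tier 3 otherwise (counts are an
uninformative split). Optional bootstraps resample reads multinomially over
the cell's (UMI, class) records with the total preserved and rerun the
whole chain, so error-edge structure can change across replicates; the
per-gene sample variance (ddof = 1) is reported.

## Whitelisting

The knee is found on the distribution of log10 read counts over distinct
barcodes using a Gaussian KDE with Scott's-rule bandwidth (counts span
orders of magnitude; the log scale makes the ambient and cell modes
comparable). The threshold is the count at the largest (right-most) local
density minimum below the high-count mode, with the high-count mode taken
as the right-most local maximum of the density. When the density has no
usable interior minimum (unimodal, uniform or degenerate tallies), the
fallback threshold is min(max(10, 0.01·max count), max count); the cap at
the maximum count guarantees the whitelist is never empty (a bare
max(10, ...) would empty it whenever every barcode has fewer than 10
reads). The initial whitelist is deliberately liberal and is not shrunk
before quantification.

Correction enumerates, for every whitelisted barcode, all barcodes
reachable by one substitution, one insertion-with-terminal-clip or one
deletion-with-appended-base (barcodes are short, so this is cheaper than
all-vs-all edit distance). Substitution labels take priority over indels;
remaining ties are broken uniformly by a seeded generator recorded in the
run manifest. When a barcode is reachable from the same whitelisted barcode
by several edit kinds, the recorded kind follows the same priority
(substitution, then insertion, then deletion).

Final whitelisting splits the above-knee barcodes by descending count
(ties lexicographic) into an upper half 𝓗 and lower half 𝓛 (odd sizes give
𝓗 the extra barcode) and trains a Gaussian naive Bayes classifier
(scikit-learn, variance smoothing 1e-9 × the largest feature variance) on
𝓗 versus n_l = max(0.2·|𝓗|, 1000) barcodes just below the knee, classifying
𝓛 at posterior ≥ 0.5. Barcodes below the knee that were *corrected into* a
whitelisted barcode no longer exist as cells, so the negative training set
is drawn from the uncorrected (discarded) below-knee barcodes, ranked by
count; when fewer than n_l are available all are used and a warning is
logged. Features: fraction of reads mapped; duplication rate
(mapped − molecules)/mapped; mean gene count, molecules / expressed genes
(both formulas are this package's definitions — the terms have no standard
closed form); optional mitochondrial and rRNA molecule fractions from
user-provided gene lists; optionally the maximum Spearman correlation of
log1p counts against every 𝓗 cell, restricted per pair to genes expressed
in either cell (Spearman rather than Pearson: robust to the heavy-tailed
count distribution; all of 𝓗 is used — desk scale permits it). A barcode
with zero mapped reads gets an all-zero feature row and a logged warning.
With an external whitelist the provided barcodes are the fixed final
whitelist and both the knee and the classifier are skipped.

## Pseudo-mapping

The mapper is deliberately simple: a forward-strand (non-canonical) k-mer
index, k = 31 by default, with sequence-identical transcripts optionally
collapsed (`keep_duplicates=False` records the collapse). A read's class is
the intersection of transcript sets over its indexed k-mers, accepted when
at least τ = 0.8 of its valid k-mers hit the index; k-mers containing N are
skipped on both sides. Stranded indexing matters: with forward-only k-mers
a read cannot multimap between two genes through a reverse-complement
match, which is also why the gene-uniqueness statistic (fraction of a
gene's distinct forward k-mers found in no other gene) is computed on
non-canonicalized k-mers. This intersection-with-coverage rule is adequate
for synthetic reads drawn verbatim from the transcriptome; it is not a
substitute for full selective alignment on real data, and it produces
position-independent classes (within-transcript positional splitting of
classes is emulated only through isoform structure).

## The simulator

`synthetic_data` emulates, per cell: a lognormal gene-abundance profile
(dispersion σ = 1.0 by default; heavy-tailed like real cells), a Poisson
molecule count (mean 100), uniform UMI draws (collisions possible — at UMI
length 10 and the default depth the expected number of same-gene UMI
collisions per experiment is ≪ 1, mirroring how unlikely same-transcript
collisions are at current depths), whole-molecule PCR (per cycle each copy
duplicates with probability `pcr_dup_prob`; new copies inherit their
parent's CB/UMI including earlier errors, mutated at `pcr_error_rate` per
base per cycle), per-copy read sampling (`read_sampling_rate`), 3'-biased
fragmentation (fragment 3'-end offset ~ Exponential with scale
(1 − bias)·L, fragment length ~ Normal(150, 20) clipped to the transcript)
and per-base sequencing errors. Ambient barcodes emit geometric read counts
(mean 5) from the library-mean profile without amplification. Transcriptome
sharing is verbatim: each entry of `sharing_fractions` makes one gene pair
share that fraction of its 3' sequence, and isoforms are 3' suffixes of the
gene body, so multi-gene and multi-transcript-single-gene classes arise the
way 3'-biased reads create them.

What the simulator does **not** model: quality-score-conditioned error
profiles, doublets, intronic/intergenic reads, chimeric PCR, or empirical
fragment-length distributions. Closed-loop tests therefore demonstrate the
correctness of the algorithms under the stated generative model, not
performance on real libraries.

### Study conditions used in the closed-loop tests

- *Exact recovery*: 50 cells × 100 sequence-unique genes, no errors,
  fragments covering the whole transcript, read sampling 1.0 (every
  molecule sequenced at least once) and profile dispersion 0.3. Under these
  conditions the pipeline's count matrix equals the ground truth entry for
  entry. Two caveats are inherent to the model: a same-gene UMI collision at
  Hamming ≤ 1 is indistinguishable from an amplification error and is
  collapsed (at this depth the expected number of such collisions per
  experiment is ≈ 0.02), and read sampling below 1 loses molecules to
  capture dropout, which no deduplicator can recover.
- *Error recovery*: same geometry with 4 PCR cycles (duplication 0.9),
  per-base per-cycle CB/UMI error 5e-4 (≈ 1% of reads carry an erroneous
  UMI), sampling 0.4; total molecules stay within 2% of truth and per-gene
  totals keep Spearman ≥ 0.95.
- *Multimapping bias*: 25 gene pairs at 0.9 sharing, 25 at 0.5, 20 unique
  genes; fragments Normal(100, 10) with 3' bias 0.9, *shorter than the
  shared 3' block*, so reads from the shared region are genuinely
  gene-ambiguous — the regime (≈ 14–23% multimapping reads) that 3'-biased
  protocols actually produce. Read sampling is 1.0 here to isolate
  multimapping handling from capture dropout, which would bias both methods
  low and confound the sign test. Against a foil that discards multi-gene
  classes before deduplicating, the pipeline's per-gene relative error at
  0.9 sharing is below the foil's at 0.5 sharing, the foil is biased low at
  0.9-sharing genes (sign test p < 0.01 over 50 genes) and the pipeline is
  not.

These problem sizes keep the whole suite fast while leaving every rate
estimated from hundreds of genes or graphs.

## Numerical and degenerate-input choices

- KDE grid: 512 points over the log10 count range padded by 0.25; local
  extrema from slope sign changes.
- Knee fallback and its cap at the maximum count: see above.
- EM: tol 1e-3 absolute counts, 1000 iterations max, per cell.
- Greedy tie-breaks and component order: deterministic, see above.
- `brute_force_cover` guard: 12 vertices (subset DP is exponential).
- Reads with N in the cell barcode or UMI are discarded before tallying:
  neither the knee nor Hamming-distance-1 correction is defined over N.
- Empty cells quantify to empty count dicts; barcodes with zero mapped
  reads are excluded from the output matrix rows.
- MatrixMarket output is written as real-valued (EM counts are fractional);
  gzip inputs are detected by magic bytes, not extension.

## Known limitations

- The pseudo-mapper has no notion of mapping position within a transcript,
  so equivalence classes are coarser than a position-aware mapper would
  produce; on real data this understates class fragmentation.
- Greedy covering is not optimal (the problem is NP-complete); the measured
  optimality gap on small random graphs is ~1% of instances.
- The whitelist classifier is only as good as its features; with very few
  ambient barcodes below the knee the negative training set is small and a
  warning is logged.
- Bootstrap variances resample reads within a cell only; they do not model
  between-cell or amplification variability.
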