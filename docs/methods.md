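# Methods

## Problem setting

Grape berry secondary metabolism — the early phenylpropanoid (ePP), stilbene,
and flavonoid branches — is coordinated by transcription factors, miRNAs, and
long non-coding RNAs acting on large, partly tandem-duplicated enzyme gene
families (PAL, STS, CHS, …). `phenolnet` builds a single typed network over
these layers so that candidate regulators can be ranked by their connectivity
to a pathway of interest. Each layer is a deliberately simple, fully
parameterized primitive; the value is in their reproducible integration, not
in any one statistic.

## Co-expression layer

Edges come from thresholding the Pearson correlation coefficient (PCC) of
expression profiles across the sample design: an edge exists iff
`|r| > pcc_threshold`, strictly, with the default threshold 0.8. The sign of
r is kept (positive / negative co-expression). Correlations are computed on
`log2(x + 1)`-transformed abundances by default — the standard
variance-stabilizing choice for FPKM-like RNA-Seq tables; `transform="raw"`
correlates the values as given. Missing values are handled pairwise-complete
with a minimum of 3 shared finite samples; pairs below that minimum, and any
zero-variance gene, produce no edge. No multiple-testing control is applied:
the hard threshold, not a p-value, defines the network.

The pre-filter for developmentally dynamic genes supports three rules —
an explicit gene list (the default mode of use, mirroring a curated pathway
set), a max/min fold-change over stage means, and a coefficient-of-variation
cutoff. No claim is made that any rule reproduces a particular published gene
selection; the differential-expression criterion behind such selections is
generally not published alongside them.

## lncRNA co-location layer

A candidate lncRNA–gene edge requires both genomic proximity and strong
co-expression. Proximity is interval intersection between the gene and the
lncRNA interval extended by `window_bp` (default 100,000 bp) on both sides,
in 0-based half-open arithmetic; consequently a gene whose gap to the lncRNA
is exactly `window_bp` is excluded — a documented boundary that the tests pin
down. Distance is the gap between closest interval ends (0 on overlap).
Proximity is strand-agnostic; strand enters only in classification:
*antisense* (overlaps a gene on the opposite strand), *intergenic* (no
overlap), and *sense_overlapping* (same-strand overlap, an explicit extension
of the usual two-way vocabulary). A strand-less overlapping lncRNA is flagged
`overlapping_unstranded` rather than silently classified. The co-expression
requirement reuses the global PCC cutoff by default but is independently
configurable, since window and threshold choices for cis-regulatory lncRNA
candidates vary between studies (50 kb and 100 kb are both in circulation).

## miRNA target layer

Scores follow the classical plant-miRNA complementarity penalty scheme in
ungapped antiparallel alignment: Watson–Crick pair 0, G:U wobble 0.5,
anything else 1.0, penalties doubled in the core region (miRNA positions
2–13, 1-based from the 5′ end), summed into an *expectation*; duplexes with
expectation ≤ 3.0 are reported. All constants are fields of `ScoringScheme`.
This is "psRNATarget-like": the widely used web scorers add bulge/gap
alignment and target accessibility terms that are deliberately excluded here
so that every score is exactly reproducible half-integer arithmetic,
checkable against a hand-computed truth table. T and U are interchangeable
on both strands. Per (miRNA, gene) the minimum expectation over the gene's
transcripts defines the edge weight; among equal-scoring windows the smallest
transcript offset is reported as the representative site.

## Promoter CRE layer

Promoters default to the 2,000 bp upstream of the annotated gene start
(strand-aware; truncated with a warning at chromosome edges). The paper-trail
motif is the R2R3-MYB site CCWACC; the bundled companions (WRKY W-box TTGACY,
AP2/ERF GCC-box GCCGCC, bHLH E-box CANNTG, bZIP G-box CACGTG) are standard
literature consensi supplied as replaceable defaults via the motif TSV, not
curated claims. Scanning is IUPAC-exact on both strands with overlapping hits
reported. Enrichment is computed on motif *presence* (≥1 hit per promoter),
not hit counts: per (module, motif) a one-sided hypergeometric upper tail
P(X ≥ k) with background size N, background carriers K, module size n, module
carriers k, followed by Benjamini–Hochberg FDR across all tests jointly.
Presence rather than counts matches how such annotations are displayed
(per-gene binary pie sectors) and keeps the null elementary.

## Integration

Node types: enzyme_gene, TF, lncRNA, miRNA. Edge types: coexpression_pos /
coexpression_neg (undirected), tf_coexpression (directed TF→target),
mirna_target (directed), lncrna_colocation (undirected). A positive
co-expression edge with exactly one endpoint in the user's TF list is
re-typed as a directed TF→target edge — a readability convention for the
regulator semantics; the correlation is symmetric and the undirected view is
recoverable since the weight is untouched. TF–TF and negative TF edges stay
undirected co-expression. Nothing is dropped silently: re-typings and any
cross-layer identifier collisions (resolved by type prefixes) are logged.

Module detection defaults to connected components of the positive-edge
subgraph: negative edges never merge modules but persist as between-module
links, reflecting the antagonism between early- and late-ripening expression
programs. Greedy modularity maximization on |weight| is available as an
alternative. Labels are deterministic (components ordered by smallest member;
every node labeled, isolates as singletons). Manually delineated clusters in
published figures are not reproducible objects; this package substitutes a
reproducible partition and makes no claim that its labels match any figure.

Centrality is reported as integer degree per edge type plus total (an
undirected edge contributes one to each endpoint, a directed edge one to each
of source and target), hubs first, ties lexicographic. Exports: GraphML
(attribute-preserving round trip), SIF with the edge type as the interaction
token, and node/edge TSV tables; all outputs byte-deterministic given the
inputs and seed.

## Synthetic data generator

The generator is first-class, tested code that defines the study conditions:

* **Expression.** A 5-cultivar × 4-stage × 1-replicate design (20 samples) by
  default. Module gene g gets abundance
  `baseline + sign_g · amplitude · (w·z + √(1−w²)·u_g) + ε`, where z is the
  standardized per-sample stage template (piecewise-linear: ripening-up,
  early-up, mid-peak), u_g a gene-specific standardized vector
  orthogonalized against z, `w = √within_module_r`, and ε i.i.d. Gaussian
  with sd `noise_sd`. Defaults: baseline 120, amplitude 30 (FPKM-like units),
  noise_sd 6 = 0.2 × amplitude — noise at a fifth of the signal amplitude,
  a regime where berry-stage expression contrasts remain clearly resolvable.
  The signal is built on the linear abundance scale (not log) so that the
  generator's exactness guarantees hold on the emitted values: with
  `within_module_r = 1` and zero noise, same-sign pairs correlate at exactly
  +1 and opposite-sign pairs at exactly −1. Values are floored at 0 with a
  warning (the defaults never reach it). Background genes get independent
  standardized vectors: uncorrelated in expectation.
* **Genome.** Uniform-random A/C/G/T chromosomes carrying: nine tandem
  same-strand paralogs (3 kb bodies, 5 kb gaps) with an intergenic lncRNA
  20 kb upstream — all nine genes inside the 100 kb co-location window by
  interval arithmetic — plus a control gene beyond the window; and a gene
  with an antisense lncRNA overlapping it on the opposite strand. When a
  motif is planted, all declared promoter windows are first scrubbed of
  chance occurrences (both strands) and one concrete instance is inserted
  into each selected gene's promoter, making enrichment ground truth exact.
* **Promoters.** Uniform background with rejection of exact motif matches on
  either strand; exactly `round_half_up(fraction × n)` sequences receive a
  planted instance (fractions round half up: 0.5 × 7 → 4).
* **miRNA pairs.** Each miRNA is the reverse complement of a random window
  of its target with the requested numbers of mismatches and G:U wobbles
  introduced at recorded positions; the truth expectation is computed by
  independent penalty arithmetic, giving a dual-route check against the
  scorer.

What the generator does **not** emulate: realistic genome composition or
gene structure (no introns, UTRs, GC skew), read-level count noise
(abundances are Gaussian around templates, not negative binomial counts),
cultivar-specific expression effects, correlated backgrounds, or chance
promoter motif co-occurrence once scrubbing is on. Passing tests therefore
demonstrate algorithmic correctness and planted-structure recovery under
controlled conditions — not performance on real RNA-Seq compendia, where
thresholds interact with library size, normalization, and biological
confounding.

## Problem sizes and numerical choices

Default verification runs use 24–44 planted genes plus 20 background genes
over 20 samples, 20 generator seeds for recovery statistics, 100 random
matrices (≤50 genes × ≤24 samples) for the brute-force network oracle, 1,000
random duplex perturbations for score monotonicity, and the full 4,096-hexamer
enumeration for motif degeneracy — sizes at which the independent oracles are
exhaustive. Correlation ties at the threshold are excluded by the strict
inequality; equal-scoring duplex windows are all reported with the smallest
offset as representative; module labels break ties lexicographically; the
fold-change filter clamps zero stage-means at 1e−9 rather than erroring.
One global seed fans out to per-stage seeds by fixed offsets, so each stage
is independently reproducible.

## Known limitations

* Co-location is symmetric interval logic only; it cannot distinguish
  cis-regulation from passive neighborhood co-transcription.
* The duplex scorer omits bulges and accessibility, so sites requiring gapped
  alignment will be missed relative to full target-prediction servers.
* Hypergeometric enrichment assumes exchangeable promoters; real promoter
  sets share composition biases that inflate significance.
* Connected components over-merge modules in dense networks; the greedy
  modularity option mitigates but does not resolve this.
* TF→target direction is asserted from list membership, not from binding
  evidence.
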