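# Methods

This note records the models implemented by `lncscape`, the parameter
defaults and why they were chosen, the numerical decisions made where the
procedure was genuinely open, and what the synthetic-data generator does
and does not emulate.

## Coordinates and data model

All genomic intervals are 0-based half-open; GTF/GFF (1-based inclusive)
is converted only at the I/O boundary. A transcript is a stranded,
sorted, non-overlapping exon chain with a provenance sample; its intron
chain (the ordered splice junctions) is the identity used for merging and
for class-code comparison. Strand "." on input is coerced to "+" with a
warning rather than dropped, so no record silently disappears.

## Class codes

A query transcript is compared against every reference transcript on its
contig and receives exactly one code by fixed precedence
`= > j > i > x > o > u`:

- `=` — identical intron chain with a same-strand reference transcript.
  Mono-exonic transcripts have no chain, so identity is defined as
  reciprocal exonic overlap ≥ 0.95 on the same strand (mono vs. mono
  only).
- `j` — shares at least one splice junction with a same-strand reference
  transcript but is not `=`.
- `i` — all exons inside a single intron of a same-strand reference
  transcript. An antisense transcript inside an intron has no exonic
  overlap and falls through to `u`.
- `x` — exonic overlap with an opposite-strand reference transcript.
- `o` — same-strand exonic overlap without a shared junction.
- `u` — none of the above.

The upstream assembler-comparison tools leave the precedence and the
mono-exonic identity rule underspecified; fixing them (and the 0.95
reciprocal threshold, the conventional containment cutoff for mono-exonic
redundancy) makes assignment total and deterministic. The test suite
checks the implementation against an independently written declarative
rule table enumerated over all two-transcript geometries with up to three
exons per transcript.

## Identification cascade

Stages are applied in study order, each a pure contraction with a removal
log:

1. **Interval filters.** A transcript is removed if more than 0.75 of its
   exonic bp lies in organelle (chloroplast/mitochondrial) intervals, or
   more than 0.3 in known-ncRNA intervals — strict inequalities, so a
   ratio exactly at the threshold survives.
2. **Cross-sample merge.** Multi-exon transcripts collapse on identical
   (contig, strand, intron chain); mono-exonic ones collapse transitively
   at reciprocal overlap ≥ 0.95. The representative is the longest
   member; recurrence is the number of distinct contributing samples.
   Loci are connected components of same-strand exonic overlap.
3. **Contamination filter.** Two classifiers — a random forest and an
   RBF-kernel SVM (standardized inputs), both at library defaults with a
   fixed seed — are trained to separate `=`-labelled from `i`-labelled
   transcripts on five features: recurrence ratio (recurrence /
   n_samples), max TPM, mean TPM, exonic length, exon count. A 20%
   stratified hold-out accuracy is recorded. Retained-code candidates
   predicted `intronic_like` are removed. The two votes merge under a
   configurable rule; the default `both_agree` removes only on consensus,
   the conservative choice toward keeping candidates, because the
   upstream procedure never states how the two classifiers' outputs were
   combined. The filter is applied to all retained-code candidates (not
   only `u`), again because no restriction is stated.
4. **Code retention.** Only `j`, `u`, `x`, `o` continue.
5. **Coding-ability cascade**, in order: similarity (removed iff some
   protein hit satisfies e < 1e-4 AND alignment ≥ 40 aa AND identity ≥
   35% — a conjunction, all three jointly), length (exonic length < 150
   bp removed; the 150 value is kept as printed even though the classical
   lncRNA definition says > 200 bp — it is configurable), coding
   potential (below), and domains (any precomputed domain hit with e <
   1e-4). Domain evidence is consumed as a table rather than a live
   profile search so the cascade runs at desk scale. Full-length inputs
   (cDNA / Iso-Seq routes) can skip merge and the ML step and enter the
   cascade directly.

### Coding-potential scorer

The coding call combines the longest forward-frame ORF with the Fickett
TESTCODE statistic (the published position-bias and composition lookup
tables): a transcript is *coding* iff its longest ORF reaches 100 aa, or
the Fickett score reaches 0.95 (the classical coding threshold) with an
ORF of at least 50 aa. `longest_orf_aa` counts the sense codons strictly
between the ATG and the stop; ORFs without an in-frame stop run to the
sequence end. This scorer is a deliberately transparent, deterministic
coding-potential rule; an adapter accepts a precomputed external verdict
table when a trained external classifier is preferred. On uniform-random
300-nt sequences the rule calls under 2% coding (the suite bounds it at
10%).

## Tissue specificity

τ = Σᵢ(1 − xᵢ/max x)/(N − 1) over *samples* (not aggregated tissues):
annotation transfers a single best sample's free-text description, which
implies per-sample resolution. Samples without a description are excluded
before any computation — mirroring real archives, where only a fraction
of runs carry usable metadata. Calls are strict (τ > 0.95); the annotated
tissue is the description of the top-TSI sample (TSIᵢ = xᵢ/Σx), ties
resolved to the lexicographically smallest sample id and flagged.
All-zero profiles are undefined and skipped. τ is scale-invariant, 0 iff
constant, 1 iff one-hot; these are asserted as properties.

## Co-expression

Unsigned adjacency aᵢⱼ = |cor(xᵢ,xⱼ)|^β with β = 6, the WGCNA
convention for unsigned networks (β is configurable). Unsigned is the
right choice here because the downstream negative-regulation scan looks
for anti-correlated lncRNA–gene pairs, which a signed network would
discard at the adjacency step. The topological overlap is

TOMᵢⱼ = (Lᵢⱼ + aᵢⱼ) / (min(kᵢ,kⱼ) + 1 − aᵢⱼ),  Lᵢⱼ = Σᵤ aᵢᵤaᵤⱼ,
kᵢ = Σᵤ aᵢᵤ (diagonal excluded),

computed exactly with dense linear algebra and verified against an O(n³)
triple-loop oracle to 1e-10. Zero-variance rows are excluded and logged;
at least 4 samples are required. Partnership is strict (TOM > 0.1).

## GSEA over co-expression partners

For each lncRNA with at least 5 coding partners, all coding genes are
ranked by their TOM weight with that lncRNA and tested against GO term
sets (flat sets, 5–500 members in the universe; no DAG propagation). The
enrichment score is the weighted Kolmogorov–Smirnov running sum with
weight exponent 1 on the ranking metric. Significance is by gene-label
permutation, judged against same-sign permutations with +1 smoothing (the
standard GSEA convention; it keeps the null rejection rate at the nominal
level, which the suite verifies over 500 null sets). BH adjustment is
applied across terms within one lncRNA; terms with padj < 0.005 and
positive ES annotate the lncRNA — depletion is not an annotation. The
ranking metric and permutation scheme are this package's documented
choices; the upstream description names the method but not the statistic.

## Annotation combination

Union semantics: a lncRNA is annotated iff at least one channel is
non-empty. The summary reports per-channel counts and percentages, the
seven Venn cells, and the overall percentage rounded to two decimals —
the suite checks this arithmetic against the published channel counts
(e.g. a 28,227-member union over 37,009 lncRNAs is 76.27%).

## Network mining

- Keyword selection: case-insensitive substring match for text terms,
  exact match for GO ids, over the channels named in the query; selection
  is monotone in the term list.
- The bipartite network reports all (lncRNA, coding gene) pairs at
  TOM > 0.1 with unique-gene and pair counts (two lncRNAs sharing three
  genes are 3 genes, 6 pairs).
- Expression patterns are z-scored per row (n−1 denominator, matching
  R's `scale()`); constant rows are excluded and logged. Clustering is
  k-means with 10 restarts and a fixed seed, clusters renumbered by
  descending size — a deterministic stand-in for the unspecified
  clustering behind the published 12-pattern figure.
- The negative-regulation scan thresholds Pearson r on scaled profiles at
  r ≤ −0.8. The published analysis found its three pairs by visual
  pattern matching; a numeric threshold makes the scan reproducible, and
  −0.8 is deliberately stringent. The threshold is configurable.

## Differential expression

On log2(TPM + 1) (pseudocount 1; the upstream transformation is
unstated), logFC is the group-mean difference. The per-row variance is
shrunk toward a scaled-F prior whose parameters (d₀, s₀²) are estimated
by moment matching of log s² — the mean and trigamma-variance equations
of the log-F distribution, solved by Newton inversion — and the moderated
t is tested on d₀ + d_residual degrees of freedom with BH adjustment.
This is the standard empirical-Bayes moderated-t construction,
implemented directly so the package carries no external statistics
dependency for it. A row is *called* at |logFC| > 2 and adjusted p <
0.001 (both strict); the magnitude is used because differential calls in
either direction count. Null calibration (rejection at α = 0.05 within
[0.03, 0.07]) and power on a planted 16-fold change at n = 5/group are
part of the acceptance suite.

## Promoter scan

Promoters are the 3-kb region upstream of the transcript's 5′ end
(minus-strand: downstream window, reverse-complemented), truncated at
contig boundaries with the actual length recorded; overlapping upstream
genes are not masked. PWMs carry a 0.01-per-cell pseudocount before
normalization (configurable) so log-odds stay finite. Scores are log2
odds in bits against the background; `N` contributes 0, and windows that
are mostly `N` are never hits. P-values are exact: the null score
distribution under the background model is computed by dynamic
programming over per-column score distributions discretized to 1e-3-bit
bins, so the p-value error at the 1e-6 hit threshold is bounded by one
bin. The suite checks the DP against exhaustive 4^w enumeration for
w ≤ 8 and the degenerate closed form (consensus p = 4^−w). Hits are
strictly p < 1e-6, sorted by p.

## Orthologs

Best hit per query = lowest e-value, ties by higher bit score then
lexicographic subject id. Primary tier: mutual best hits. Secondary tier:
non-primary pairs among each query's top-three forward hits whose
e-value falls strictly below the peak (mode) of the pooled best-hit
e-value distribution. The peak is located on the log10 scale (raw-scale
modes are degenerate over 100 orders of magnitude) with
Freedman–Diaconis bins, e = 0 mapped to 1e-200; degenerate spreads fall
back to the exact-value mode. The top-three/secondary construction is an
explicit interpretation of a loosely worded published criterion and is
flagged as such in the output (`tier`, `rank_forward`).

## Pathway preference

A query gene's TOM > 0.1 partners are tagged flavonoid- or
lignin-related by intersecting their GO sets with the printed term lists
(six flavonoid ids, four lignin ids; used as flat sets). Labels follow
the partner counts exactly: flavonoid_preferred (n_flav > 0, n_lig = 0),
lignin_preferred (converse), dual, none; they partition the query set,
and raising the TOM threshold can only move genes toward `none`. Only
coding-gene partners count when a coding universe is supplied.

## The synthetic study

The generator is a pure function of (config, seed) and emulates the
study conditions end to end:

- **Genome**: 2 main contigs × 300 kb of uniform-random sequence with 60
  non-overlapping genes (1–8 exons, both strands), plus dedicated `chrC`
  and `chrM` organelle contigs, mirroring real organelle filtering.
- **Assembly**: 240 planted transcripts at rates =: 0.25, j: 0.15,
  i: 0.15, u: 0.25, x: 0.10, o: 0.10, each realized geometrically
  against a sampled reference gene ("i" strictly inside an intron, "j" a
  partial chain reading into an intron, etc.), replicated into a random
  subset of 24 samples. Contaminants are planted at overlap ratios
  straddling the filter thresholds (organelle 0.5–1.0 around 0.75;
  ncRNA 0.2–1.0 around 0.3), and coding contaminants carry a real
  ≥ 120-codon ORF or rows in the similarity/domain tables. Planted
  lncRNAs are guaranteed genuinely non-coding: chance ORFs approaching
  the 100-aa rule are disrupted in the genome at generation time.
  Intronic artifacts get low recurrence and low TPM (0.4), everything
  else recurs in ≥ a third of samples at TPM 4–64, which is what makes
  the "="-vs-"i" feature space learnable.
- **Expression**: 16 described tissues at one sample each plus 8
  undescribed samples (~33% unusable, matching the fraction of archive
  runs lacking metadata). One described sample per tissue label reflects
  how archive runs carry individual descriptions; with per-sample τ, a
  transcript high in m > 1 samples cannot exceed τ = 0.95 at moderate N,
  so this is also the regime in which tissue-specific planting is
  well-defined. Tissue-specific members are 100-fold elevated in their
  tissue; co-expression modules (5 modules of 1 lncRNA + 5 genes) share
  a bounded uniform latent profile scaled by log-normal noise (sd 0.1),
  giving pairwise r ≈ 0.95; negative pairs track the latent and its
  mirror image (0.1+u vs 1.1−u), giving r ≈ −0.95 on scaled profiles. A
  bounded latent is used instead of a log-normal factor because the
  exponential nonlinearity caps raw-scale anti-correlation near −0.8,
  too weak to plant reliably.
- **Promoters/motifs**: 60 uniform-random 3-kb promoters; a width-12 PWM
  (0.91 consensus probability per column) with the exact consensus word
  embedded at recorded offsets/strands in half the promoters. At width
  12 only exact consensus words clear p < 1e-6, so planted hits are
  recoverable and the false-positive rate per promoter is ~3.6e-4.
- **Orthologs**: 10 planted pairs with e-values in 1e-120–1e-60 in both
  directions; decoy hits (1e-40–1e-5) point only at planted subjects, so
  no spurious mutual best pair can arise and primary-tier recovery is
  exact by construction.
- **GO**: each module's genes share one synthetic term (one named
  "plant-type secondary cell wall biogenesis" to exercise keyword
  selection), plus random decoy terms.

**What passing tests do and do not show.** The simulator plants clean,
well-separated effects: uniform base composition, independent noise,
exact threshold straddles, strongly separable contamination features. A
pipeline that recovers them demonstrates the correctness of every rule,
boundary and statistic — not performance on real tissue panels, where
class-code geometry is messier, expression noise is structured,
contamination features overlap, and motif instances are degenerate. The
problem sizes (60 genes, 240 transcripts, 24 samples, 60 promoters) were
chosen as the smallest study at which every planted structure is
statistically unambiguous.

## Numerical choices and degenerate inputs

- All boundary comparisons follow the printed inequalities: overlaps and
  TOM are strict `>`, τ strict `>`, length strict `<` for removal,
  motif p strict `<`, DE criteria strict.
- TSI ties go to the lexicographically smallest sample id and are
  flagged; all-zero profiles are excluded, not imputed.
- TOM is symmetrized and clipped to [0, 1] after floating-point assembly;
  the diagonal is fixed at 1.
- k-means cluster ids are renumbered by descending size so labels are
  stable across runs at a fixed seed.
- PWM score discretization is 1e-3 bits; observed scores and the null
  distribution share the same grid, so enumeration comparisons are exact
  within a bin.
- Permutation p-values use +1 smoothing and are therefore never 0.
- The moderated-t prior falls back to infinite d₀ (all variances equal)
  when the observed log-variance spread is below the trigamma floor.

## Known limitations

- Class codes outside {=, j, i, u, x, o} (c, e, k, p, s) are not
  assigned; transcripts matching none of the six definitions resolve
  to `u`.
- GO terms are flat sets; no ancestor propagation.
- The coding-potential rule is intentionally simple; it is not a trained
  classifier and will disagree with one near the decision boundary.
- The secondary ortholog tier implements one reading of an ambiguous
  published criterion; its pairs should be treated as candidates, not
  confirmed orthologs.
- WGCNA module detection (dynamic tree cut) is out of scope; the TOM is
  used directly for partnership and enrichment.
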