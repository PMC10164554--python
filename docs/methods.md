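# Methods

## Coordinate conventions

All intervals are BED-style 0-based half-open `[start, end)`; the center
of an interval is `floor((start + end) / 2)`, which lies inside any
non-empty interval. The TSS of a transcript is strand-aware: `txStart`
on the + strand, `txEnd − 1` on the − strand. Signed peak-to-TSS
distances are strand-aware as well, with negative meaning upstream of
the gene.

## Super-enhancer calling

EP300 peaks fully contained in a ±2.5 kb zone around any TSS are removed;
remaining peaks on a chromosome are stitched whenever the gap to the
growing region is ≤ 12.5 kb and no exclusion zone intersects the interval
strictly between them. Each stitched region is scored as

    score = max(0, rpm_treatment − rpm_control),
    rpm = (#fragment midpoints in region) × 10⁶ / total tags,

i.e. total depth-normalized, input-subtracted tag mass in the region.
Scaling both tracks' depths by a common factor leaves every score, and
hence every call, unchanged.

The SE/typical-enhancer cutoff uses the rank-curve geometry: scores are
sorted ascending, both axes are rescaled to [0, 1], and the cutoff is the
score at the point maximizing the vertical gap below the y = x reference
— the tangent point of the curve with a unit-slope line, where the
discrete slope crosses 1. For noisy score distributions the "first index
whose forward slope exceeds 1" reading is unstable (a single large gap in
the upper tail of the background triggers it early), so the global
gap-maximizing form is used; ties break toward the larger rank, the
stricter cutoff. Regions scoring strictly above the cutoff are SEs; a
degenerate all-equal score vector yields zero SEs. An independent
exhaustive implementation of this construction lives in the test suite
and is asserted equal to the library's on every acceptance run.

SE target genes reuse the standard assignment rule below; using one rule
for all gene assignment keeps SE genes, co-occupancy targets and network
edges mutually consistent.

## Peak annotation and target assignment

`classify_feature` tests the peak *center* so every peak gets exactly one
class, resolving multi-gene ambiguity with the hierarchy promoter
(±2 kb of any TSS) > intron > exon > intergenic. `assign_targets` links a
peak to every gene with a transcript TSS within ±20 kb of the center, and
(by default) to genes whose body contains the center; peaks matching
nothing fall back to the gene with the nearest TSS on that chromosome
(ties: smaller TSS coordinate, then lexicographic symbol). Multi-
transcript genes are deduplicated at symbol level, keeping the smallest
|distance|. Both the TSS-only and the body+fallback variants are exposed
because feature statistics and network construction conventionally use
different rules.

## Co-occupancy groups

Peak centers of the five TFs are pooled per chromosome, sorted, and
clustered greedily left to right: a center extends the current cluster
iff the resulting span stays ≤ 500 bp. Greedy scanning is the
deterministic reading of a moving-window overlap definition; the
alternative single-linkage reading (pairwise distance ≤ 500 with
transitive closure) can produce unbounded spans and was rejected. Within
a cluster each factor counts once; a factor with several peaks keeps the
one nearest the cluster's mean center. Sites map to groups G1..G5 by
`G(6 − n_factors)`: G1 means all five TFs co-bind. A gene touched by
several sites keeps its maximum co-bound count.

Group expression uses each gene's mean TPM over the selected (stem-like)
samples. Pairwise group comparisons use the two-sided Wilcoxon rank-sum
test: exact enumeration when both sides have ≤ 25 tie-free observations,
otherwise the tie-corrected normal approximation.

Overlap with a deregulated-gene list is tested with the hypergeometric
upper tail P(X ≥ k), universe = all annotated gene symbols (configurable;
expressed-only universes shrink N and inflate significance). Being a
discrete exact test its null p-values are *super-uniform* — P(p ≤ α) ≤ α
with equality only at attainable tail values — so null calibration is
asserted as a bounded type-I error rate, not as KS-uniformity, which a
discrete statistic cannot satisfy at small N.

## Regulatory network

One edge per (TF, assigned target) pair, deduplicated. Motifs over the
assayed-TF set: autoregulation = self-edges; interconnectivity =
unordered TF pairs with edges both ways; feed-forward loops = ordered
triples (A, B, C), A ≠ B ≠ C ≠ A, with A, B TFs, C any node, and edges
A→B, A→C, B→C. EP300 participates as a network node but is excluded from
the motif TF set by default — it is a cofactor, not a sequence-specific
regulator (configurable via `motif_tfs`).

## Cross-species comparison

A required, explicit one-to-one ortholog map defines the comparable
universe; unmapped genes are excluded. Per gene and species the bound
count is the number of factors (default six: five TFs + EP300) whose
target set contains it. Classes: common = all factors in both species;
HMFB/MMFB = all factors in one species, ≤ 2 in the other; other
otherwise. Species enrichment compares pseudocounted TPM,
`(a + 1)/(b + 1) ≥ 2` (the pseudocount guards zero expression). Target-set
similarity is the Pearson correlation of binary membership vectors over
the ortholog universe (undefined for constant vectors, reported as
missing) plus the Jaccard overlap.

## Knockdown DEG integration

DEG tables are an input contract (gene, log2FC, adjusted p), filtered
upstream at padj < 0.01 and |FC| > 1; DEG calling is out of scope. A DEG
is *direct* for a TF iff the TF's target set contains it, split per
direction. The co-binding strata compare genes bound by all five TFs
against genes bound by at most one ("<2" read literally); within each
stratum the down:up ratio after knockdown is reported with both counts,
so either ratio orientation is recoverable, and a zero denominator is
flagged infinite rather than silently dropped.

## Synthetic study generator

The generator emulates the statistical structure of the study at desk
scale; defaults: 2 chromosomes × 10 Mb, 400 genes on a ~50 kb grid (the
first five cells host the TF genes), 600 co-bound sites with tier
proportions (0.25, 0.20, 0.18, 0.17, 0.20) realized exactly by
largest-remainder rounding, 12 planted SE clusters, 2×10⁵ tags per
track, expression baseline log2 TPM ~ N(3, 1), tier effect δ = 1 log2
unit per co-bound factor, peak-center jitter sd 50 bp.

Design choices that matter:

- **Sites** sit at fixed slots ±4/8/12 kb from their gene's TSS — outside
  the ±2.5 kb promoter zone, and far enough from the ~50 kb-spaced
  neighbors that the ±20 kb target rule is unambiguous. A gene's second
  site goes on the opposite TSS flank, so background stitched regions
  stay single-peak (the promoter exclusion zone separates flanks). A
  gene's sites draw factor subsets from one per-gene factor set, so the
  union over sites equals the maximum tier and bound counts stay exact.
- **Species classes** are planted by construction: common and HMFB genes
  receive a tier-5 site (all five TFs + EP300) in species A, MMFB genes
  a tier-1 site; species-B peaks are placed from the planted
  species-B counts (6 for common/MMFB, ≤ 2 for HMFB). Tier-5 sites in
  excess of the class quota promote additional genes to common, keeping
  manifest and files consistent. The ortholog map is
  identity-with-renaming so the classification logic, not the mapping,
  is under test.
- **Tag tracks**: each tag's midpoint is drawn Normal(peak center, 75 bp)
  truncated to the peak, over a 20% uniform background; this produces
  center-peaked metaprofiles without modeling fragmentation. SE
  constituents carry `signal_ratio` (10×) the weight of a background
  peak; background EP300 weight rises only mildly with tier
  (slope 0.08, lognormal sd 0.1) — enough to order the G1..G5
  metaprofiles, while keeping the background score distribution tight so
  the rank-curve tangent lands at the top of the background. SE
  constituents are evenly spaced with bounded wobble, so no internal gap
  approaches the 12.5 kb stitch distance and every planted cluster
  stitches into one region.
- **Deregulated list**: an exact, linearly tier-graded fraction of each
  tier's genes (8% at tier ≤ 1 up to 5 × 8% = 40% at tier 5), making the
  G1→G5 overlap gradient a planted property.
- **Knockdowns**: FOS, GATA2, MAFK and TEAD4 are planted activators of
  fully co-bound genes (down after KD) and derepressors of sparsely
  bound ones; TFAP2C is planted with the opposite polarity. 15% of
  responses flip sign so both ratio denominators are populated.

What the generator does *not* emulate: mappability/GC bias, read-level
noise, overlapping genes, one-to-many orthologs, promoter-proximal
enhancers (all sites are ≥ 4 kb from the TSS, so the synthetic feature
pie has no promoter slice), and continuous co-binding affinity. Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted structure under center jitter and counting
noise — not robustness to the full messiness of real ChIP-seq.

## Problem sizes and determinism

Default test/acceptance sizes (600 sites, ~3,000 peaks, 4×10⁵ tags,
500 genes for the gradient check, 1,000 null replicates at
N = 10,000) run the whole suite in a few seconds while keeping every
statistical margin wide (e.g. the G1-vs-G5 rank-sum z-gap per tier step
is ≈ 8 standard errors of the median at n = 100/tier). All randomness
flows through one `numpy.random.default_rng(seed)` per run; identical
seeds give byte-identical output trees, and the analysis pipeline itself
is fully deterministic.

## Known limitations

- The rank-curve cutoff is scale-free but not noise-free: with a
  heavy-tailed background score distribution the tangent point can admit
  a few top background regions as SEs, exactly as the original
  construction does on real data.
- Exact Wilcoxon enumeration is skipped in the presence of ties (the
  tie-corrected approximation is used instead), so very small tied
  samples get approximate p-values.
- `se_overlap_fraction` counts ≥ 1 bp intersection; it does not weight by
  overlap extent.
- The CLI's `run-all` expects the generator's directory layout; arbitrary
  file layouts are supported through the library API only.
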