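# Methods

This note documents the models and procedures implemented in `svarcall`,
the defaults and why they are set where they are, what the synthetic data
emulate (and do not), and the numerical decisions taken where the design was
genuinely open.

## Breakpoint discovery

Evidence channels. A read crossing a novel adjacency appears as (i) a
primary plus supplementary alignment pair linked by the SA tag, (ii) a
gapped alignment with a long insertion/deletion CIGAR operation, or (iii) a
long terminal soft clip when only one side of the adjacency maps. All three
are parsed into putative breakpoints carrying read name, orientation,
haplotype (HP), phase set (PS) and MAPQ.

Orientation convention. A breakend is written `+` when the retained
sequence lies to the left of the breakend (the adjacency continues
rightward) and `-` for the mirror case. With breakends ordered by genomic
position this reproduces the Pan-Cancer notation classes: (+ −)
deletion-like, (− +) duplication-like, (+ +)/(− −) inversion-like. CIGAR
deletions are typed (+ −) so gapped and split evidence for one deletion
co-cluster. All four strand-pair cases are enumerated in tests.

MAPQ gates. Tumor alignments require MAPQ ≥ 5. The normal sample's
threshold is multiplied by 0.5 and compared as a real number (2.5, so MAPQ 3
passes): missing germline evidence is costlier than admitting noisy normal
reads, because normal reads only ever veto somatic status. Similarly the
minimum indel length (30 bp) is reduced by a fraction of 0.20 for the
normal, so germline indels just below the tumor cutoff still co-cluster and
veto. Duplicate-flagged and secondary records are always excluded.

Merged deletions. Adjacent deletion operations separated by mapped
stretches shorter than 30 bp are merged; the event length is the *sum of
deleted bases* (the biologically meaningful quantity), while the reference
span of the merged region is kept separately on the breakpoint record.

Fold-back artifacts. Opposite-strand query-adjacent segments on one contig
whose reference ends lie within 200 bp are treated as fold-back-like
inversion artifacts and emit no junction. The independent artifact-rate
estimator (benchmark module) uses the stricter read-level definition:
exactly one primary and one supplementary alignment, both MAPQ ≥ 20,
overlapping in opposite orientations, read-start and read-end reference
positions < 150 bp apart.

Coverage. Per (contig, haplotype) arrays of alignment counts in 5 bp bins,
incremented by every primary and supplementary alignment overlapping the
bin. Depth before/at/after each breakend (±100 bp) feeds the classifier.

Genome binning. Discovery is organized in non-overlapping genome bins
(100 Mbp default); a read belongs to the bin containing its primary
alignment start, so multi-bin reads are never double-counted. At the scale
of the bundled fixtures this only fixes a deterministic processing order.

## Clustering

Single-linkage chaining along the genome: a breakpoint joins the open
cluster iff it lies within the window of the previous member (10 bp; 250 bp
for insertions, whose mapped position is empirically noisier). Clusters are
then partitioned by mate contig and re-chained on mate position with a 50 bp
window, and insertion clusters are split when consecutive insert sizes
differ by more than 25% of the smaller one (the size-comparability criterion
is unquantified in the literature; 0.25 is this package's choice, fixed
before any tuning). Cluster position is the member median with ties broken
to the lower value. Single-breakend clusters are dropped when a non-SBND
cluster explains the same locus (within the clustering window): other reads
resolved the full adjacency. Chaining (gap-to-previous, not
diameter-bounded) is linear-time and equals connected components of the
within-window graph, which the tests verify by brute force.

## Somatic classification

Features. Exactly 70 covariates per cluster, frozen in
`classify.FEATURE_MANIFEST` (version 1): support and allele fraction in
both samples, MAPQ summaries, SV-length summaries, positional scatter
(std/MAD/span of both breakends), per-haplotype support and depth,
before/at/after depth and depth discontinuity at both breakends,
evidence-type fractions, notation one-hot, paired-mode and
interchromosomal flags. The allele-fraction denominator is the local
maximum of the before/at/after depths: reads supporting the junction end
exactly at the breakend, so the breakend bin itself can be depleted.

Labels. For training, clusters are labeled somatic when matched within
100 bp against an orthogonal call set (in production, short-read calls; in
tests, the generative truth). Unmatched clusters are labeled noise unless
they look like genuine events the orthogonal set missed — ≥ 6 tumor reads,
AF > 10%, mean MAPQ ≥ 50, coordinate std < 15 (events > 100 bp) or
coordinate std < 1.5 and size std < 10 (events < 100 bp), and in paired mode
< 2 supporting normal reads with ≥ 5 normal reads of local depth — in which
case they are excluded from training rather than mislabeled.

Forest. `RandomForestClassifier` with `max_depth=20`, 4:1 train/test split
(grouped by tumor when tumor-of-origin labels are supplied), seeded. The
somatic probability is the fraction of trees voting somatic; an exact tie
goes to noise (conservative). Filter precedence is total and evaluated in
order: predicted noise → LIKELY_NOISE; < 3 supporting reads → LOW_SUPPORT;
AF < 0.01 → LOW_AF; else PASS.

Conformal prediction. A Mondrian (class-conditional) inductive predictor:
70% of the labeled data train a forest, the rest calibrate. Nonconformity
for class c is one minus the fraction of trees voting c;
p_c = (#{calibration scores of class c ≥ query} + 1)/(n_c + 1). The region
at significance ε is {c : p_c > ε} — "both" when both classes fit, "null"
when the instance is unlike all calibration data. Default ε = 0.05 (no
established default exists; 0.05 matches the conventional error budget).
Validity requires exchangeability; the guarantee is per class and holds in
expectation, which the acceptance suite checks empirically.

Rescue and panels. After classification, non-PASS clusters within 50 bp of
a somatic copy-number changepoint are rescued to PASS when they have ≥ 3
tumor reads, no supporting normal reads and < 3 normal reads clustering to
the locus with any breakpoint type; rescue runs exactly once (no iteration
to a fixed point) and rescued records are flagged. In tumor-only mode,
clusters within 100 bp of a population-panel SV with population AF > 0.10,
or of any panel-of-normals entry, are reclassified germline. The rescue
changepoints are this caller's own (no external segmentation is consumed).

## Copy number

Pipeline: 10 kbp bins (split at PASS breakends when available) → per-bin
primary-alignment counts (MAPQ ≥ 5, assignment by alignment start) →
exclusion of bins with > 5% blacklist overlap, > 75% N bases, zero counts,
or zero normal counts in paired mode → log2R (depth-scaled tumor/normal
ratio, or median self-normalization in tumor-only mode) → outlier smoothing
→ Anscombe transform → circular binary segmentation → segment merging.

Smoothing. A point is replaced by the median of its ±2-bin neighborhood iff
it deviates from that median by more than 2× the series' median absolute
deviation, both immediate neighbors lie strictly on the same side, *and* it
differs from each immediate neighbor by more than the same threshold. The
last condition makes the rule act only on genuinely isolated spikes: the
edge bins of a real copy-number step have one neighbor on their own level
and are left alone (without it, segment means attenuate toward neutral and
the purity fit inherits a systematic bias).

Variance stabilization. The Anscombe transform A(x) = 2√(x + 3/8) is
applied on the ratio scale r = 2^log2R — the log scale can fall below −3/8,
the ratio scale cannot. Segment means are reported back on the log2R scale
as the mean of member bins.

Segmentation. For each segment the statistic is the standardized arc-sum
deviation |S_j − S_i − k·x̄| / (σ √(k(1 − k/n))) maximized over all circular
arcs, with σ the segment-wide standard deviation (permutation-invariant, so
the permutation test needs no per-split variance). Wrapped arcs induce the
same changepoint pairs as their linear complements, so only linear arcs are
scanned; ties (an arc and its complement score identically) resolve to the
lexicographically smallest (i, j). Arc ends within 2 bins of a segment edge
snap to the edge. A split is accepted iff its permutation p-value
(1,000 seeded permutations, early-stopped in blocks once significance is
excluded — the decision is identical to the full run) is below 0.05;
recursion continues on the pieces. Validation then prunes iteratively: each
changepoint is re-tested against its current flanking segments at α = 0.01
using the permutation maximum over all linear splits as the null (the split
location was chosen by maximization, so the null must account for that
selection), and the weakest failing changepoint is removed before its
neighbors are re-tested against the widened flanks. Each sub-segment's
generator is derived from (run seed, segment offsets), so results are
deterministic given (series, seed).

Merging. Adjacent same-contig segments are merged while their mean-log2R
difference is below the 20th percentile (linear interpolation) of all
pairwise segment differences computed once from the initial segmentation;
exactly equal neighbors always merge (the strict-inequality rule alone
would leave even identical segments split). The rule presupposes a genome
with enough segments that repeated copy-number states dominate the
percentile; it is not applied to toy series with three segments.

## Purity and ploidy

Purity. Heterozygous-SNP BAFs are grouped in fixed 1.2 Mbp blocks (the
bundled fixtures pass 100 kbp to match their scale). Blocks need ≥ 10 SNPs
and mean depth ≤ 2× the genome mean (amplifications would bias the split).
Blocks are ranked by Sarle's bimodality coefficient
b = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3))) — the coefficient is named but
not defined in the SV-calling literature this follows; the SAS definition
is used — and the top ten contribute median BAFs of the upper and lower
modes (split at 0.5). In a CN-neutral LOH block BAF_B = (1−ρ)/2, giving the
estimator its closed form; fewer than ten eligible blocks are averaged with
a warning. Blocks whose BAF mode straddles 0.5 simply contribute both
half-modes; no mode-finding is attempted.

Ploidy. Grid search over purity ∈ ρ̂ ± 0.1 (step 0.01) and ploidy ∈
1.50–5.00 (step 0.01). Each point maps segment log2R to absolute CN via
CN = ψ + (2^log2R − 1)(ψ + 2/ρ − 2) and is scored by the segment-size-
weighted RMSD (or MAD, selectable) from the nearest integers. Points are
discarded when the size-weighted zero-copy fraction is ≥ 0.1, the fraction
of segments within 0.25 of an integer is ≤ 0.5 (0.25 is this package's
threshold for "close"), or the two most frequent states (by total size)
differ by ≥ 2. Among surviving points, all fits within 0.02 of the minimum
are near-equivalent — a whole-genome ±1 shift of the CN scale at a
compensating purity reproduces the integers essentially exactly — so the
lowest-ploidy basin (ploidies within 0.25 of the lowest near-tie) is kept
and its best-fitting point returned: parsimony resolves the shift
degeneracy, and the zero-state flag rejects down-shifts whenever the genome
carries a ≥ 10% single-copy compartment. Ties inside the basin prefer the
purity nearest the BAF estimate. If every point is rejected the fit raises
with a suggestion to supply purity manually.

Allele-specific CN. The detailed fitting procedure is deferred to external
work in the literature this package follows; the closed-form stand-in
inverts the BAF mixture model: with b the median segment BAF folded to
≤ 0.5 and n_T the rounded total CN,
n_B = (b(ρ n_T + 2(1−ρ)) − (1−ρ))/ρ, rounded and clamped to
[0, ⌊n_T/2⌋]. Folding removes phase dependence; LOH segments land at
minor = 0.

## Benchmarking

Breakend matching is greedy nearest-first and one-to-one within a 100 bp
buffer; insertions match only insertions (record-to-record). Precision,
recall and F-measure follow. Replicate splitting assigns whole reads (all
records of a name) by a seeded fair coin. The phasing test excludes SVs in
LOH regions, calls single-allele support concordant, and tests mixed
support with a one-tailed binomial (majority-allele count against
success probability 0.95) with Benjamini–Hochberg correction at 0.05;
non-rejections are inconclusive, not concordant — low counts simply lack
power.

## Synthetic data: what it does and does not emulate

Alignments are synthesized directly as coordinate-level records (CIGAR,
SA, HP/PS tags) with the exact geometry each SV class produces — the tests
target the caller, not an aligner. Supported planted events: gapped and
split deletions, merged-deletion patterns, tandem duplications, both
inversion orientations, translocations, insertions with sequence, single
breakends, fold-back artifact pairs, low-MAPQ chimeric junction noise and
clustered near-threshold indel noise at designated loci. Carrier counts
realize the target AF deterministically against the reads covering the
junction, and carriers share the SV's haplotype when AF ≤ 0.55.

CN/BAF tables invert the inference model: bin ratio
r = (ρ·CN + 2(1−ρ))/(ρ·ψ + 2(1−ρ)) with lognormal noise and Poisson
counting; SNP alternate counts are Binomial(depth, (ρ n_B + (1−ρ))/(ρ n_T +
2(1−ρ))) with the B allele on a random parental haplotype. The derived
ploidy is always the length-weighted mean CN of the profile, which makes
the depth normalization consistent with the absolute-CN equation.

Not emulated: base-level sequences and error profiles, mappability and GC
bias, microhomology at junctions, subclonal structure, reference N-runs,
real blacklist regions. Passing tests therefore demonstrate the
correctness of the algorithms under the stated statistical model, not
performance on real flow-cell data.

Study-scale choices (fixed as the package's own design): the worked example
uses two 1.2 Mbp contigs at 30× with 12 SVs at AF 0.7–1.0 (comfortably
above the ≥ 3-read support threshold even after a half-depth replicate
split) and a profile with ≥ 10 CN-neutral LOH blocks at the fixture's block
size plus a ≥ 10% CN-1 compartment; the recovery cohorts use 10 Mbp
single-contig genomes, 1,000 bins, SNPs every 2 kbp at depth 30. The
acceptance script scales replicate and permutation counts to run on one CPU
in under a minute.

## Known limitations

- The 70-feature manifest is this package's own frozen contract; the named
  covariates from the method it follows are included, but the exact
  production feature list of that method is not public in full.
- The conformal guarantee is marginal per class; small calibration sets
  (tens of instances) make regions conservative ("both" dominates).
- The purity estimator assumes CN-neutral LOH dominates the most-bimodal
  blocks; genomes whose bimodal blocks are mostly (1,0) or (3,1) bias it.
- The ±1 ploidy-shift degeneracy is resolved by parsimony and the
  zero-state flag; a genome with no single-copy losses and purity ≲ 0.4
  can still fit one ploidy unit high.
- CBS validation prunes with a selection-aware null but cannot remove
  find-stage false positives that reproduce under it; residual
  oversegmentation is absorbed by the merge stage on realistic genomes.
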