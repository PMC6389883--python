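# Methods

`allelescan` detects heterozygous SNPs with allele-specific chromatin
signals (AS-SNPs) and annotates them with disease/expression associations,
3D-chromatin target genes and motif-level mechanism hypotheses.  This note
documents the models, the parameters that matter, the synthetic study the
tests run against, and the numerical choices made where the design was
genuinely open.

## Allelic-imbalance model

At a heterozygous SNV the two alleles act as internal controls for each
other.  For each sample and assay, reads overlapping the site are
classified by the base they carry: haplotype-1 allele, haplotype-2 allele,
other, or discarded for base quality below Phred 20 (`min_base_q`, the
quality convention of short-read chromatin data).  Each read contributes
at most once per site; duplicate-flagged, secondary and supplementary
alignments are skipped.  Counting happens on the single reference
coordinate frame: because personalization is SNV-only, reference and both
personal haploid genomes share coordinates, and base matching at the site
is equivalent to dual-genome alignment reconciliation for these data.

The test is a two-sided exact binomial test of the (n₁, n₂) split against
a null ratio of 0.5 (`null_ratio` is configurable to absorb residual
reference bias).  Sites with fewer than `min_depth = 10` informative reads
are untestable rather than erroneous.  All tested site×assay pairs of a
sample are corrected together with Benjamini–Hochberg FDR
(`alpha = 0.05`; Bonferroni selectable); a site is a candidate when any
assay reaches q ≤ α.  Candidates are pruned against blacklist/CNV/repeat
intervals (half-open; first matching class is logged as the removal
reason) and then restricted to regulatory elements of the four retained
chromatin categories (enhancer, promoter, mixed, insulator) out of the
condensed seven-state scheme.

The defining-assay label is the single significant assay; two or more
significant histone marks give `mixed`; a histone mark beats a
co-significant architectural protein (CTCF/SA1), which keep their own
labels only when they are the sole signal; the unstated corner where both
architectural proteins and no histone mark are significant is labelled
`CTCF+SA1` because `mixed` is reserved for chromatin-mark combinations.

### Population aggregation

Allele counts are summed across all samples heterozygous at a site —
oriented to the fixed ref/alt frame first, since haplotype indices are
arbitrary per sample — and the aggregate site×assay collection is
re-tested and re-corrected as one set.  Aggregate AS-SNPs already
significant in some single sample are `case1`; those that surface only in
the aggregate are `case2`.  No minimum number of heterozygous samples is
required for aggregation (an open choice; any het sample contributes).
Rare/common classification uses the panel's population allele frequency
(VCF `INFO/AF`), not the cohort haplotype frequency — a handful of
haplotypes cannot express MAF < 0.01 (`maf_rare`, boundary value counts
as common).

## Association layer

LD is computed from phased haplotypes directly, r² = D²/(p_A p_a p_B p_b)
over all 2N haplotype indicator columns (no EM; panels are phased by
construction).  Index SNPs from the GWAS and eQTL tables are expanded to
proxies with r² strictly greater than 0.8 within a 1 Mb window
(`ld_window`, a tractability bound).  An AS-SNP equal to an index SNP
links `direct` (r² recorded as 1); one in high LD links `proxy`.  The
summary reports the unique AS-SNP counts linked to GWAS traits, to eQTL
genes, and to both.  Rare AS-SNPs within ±300 bp (inclusive at both
boundaries) of an associated common AS-SNP are reported separately as
candidate hidden drivers sharing the regulatory element.

## 3D layer

A TAD is given as its two contact-domain (anchor) intervals; the loop
domain is exactly `[a.end, b.start)`.  Degenerate or crossing pairs are
rejected with a log entry.  Genes overlapping the loop are loop genes;
genes overlapping an anchor are that anchor's genes; loops with identical
loop-gene sets are unified to one representative (the widest span — any
representative preserves the gene sets).  AS-SNP placement gives contact
domains precedence over loops, keeping the two reported classes disjoint.

Capture interactions: for each probe–fragment pair and replicate, the
p-value is the empirical upper-tail probability of the read-pair count
within control-probe counts at matched genomic distance (log-spaced bins,
10 per decade).  Control probes target regions with no annotation or
regulatory potential, so their contacts estimate the background contact
frequency.  Sparse bins are widened by pooling nearest bins until the
null holds at least 50 observations — with fewer than 20 controls an
empirical p below 0.05 is unattainable, so un-widened sparse bins would
silently veto every short-range call.  A pair is significant when it has
≥ 3 read pairs and p < 0.05 jointly in at least two of the three
replicates (the joint-per-replicate reading of the filter).  Significant
interactions form a fragment graph (fixed 4 kb fragments in synthetic
data, echoing ~5 kb distal probe regions); an AS-SNP fragment adjacent to
a promoter-probe fragment is a direct target call, paths through
intermediate distal fragments give indirect calls with hop counts
(`max_hops = 2`).  Target calls are labelled `confirmed` when a capture
target gene matches an eQTL gene of the same AS-SNP, `different` when
targets exist but none match, `no_eqtl` otherwise.

## Motif layer

Motif models are inhomogeneous variable-order Markov models: position i
may condition on up to `k_max = 2` preceding positions, with the context
depth chosen per position by BIC (penalty 3·4^d parameters) on the
training sites; conditional frequencies carry pseudocount 0.5.  This
keeps the conditional-probability semantics of parsimonious Markov models
while replacing parsimonious-context-tree structure learning with a
simpler exhaustive depth search — full contexts instead of fused ones.
With `k_max = 0` the model reduces bit-exactly to a PWM, which the tests
verify against an independent PWM scanner.

Scores are log-likelihood ratios against an order-1 background estimated
from the scanned 601 bp window set (not from the training sites, whose
composition is the motif itself and would distort — even inverted, in
experiments during development — the gain/loss polarity).  Both strands
are scanned at every offset.

Score p-values come from a Gaussian fitted (sample mean/sd) to the pooled
scores of dinucleotide-shuffled copies of all input windows (25 shuffles
per window over the first 12 windows by default; at least 1000 pooled
scores are required, zero variance is an error).  Shuffling is the exact
Eulerian-path construction: a uniformly random arborescence toward the
final character (rejection-sampled) fixes each vertex's last outgoing
edge, remaining edges are permuted, and the walk preserves all 16
adjacent-pair counts and both terminal characters.  Predictions are kept
at p ≤ 1e-3.  For each AS-SNP two 601 bp windows are scanned, one per
allele, differing only at the center base; a locus is emitted when either
allele passes, and only loci whose site interval covers the variant
(`overlaps_snp`) enter allelic-effect analysis.  `gain` means the
alternative-allele score exceeds the reference-allele score (the polarity
is a convention; exact ties are excluded with a log entry).  Per-TF
summaries report the bp-interval Jaccard between the AS-SNP positions
(1 bp intervals) and the TF's predicted-site intervals, the fraction of
predicted sites altered by an AS-SNP, and gain/loss fractions among them.

## Synthetic study

The generator emulates the study design at desk scale with one seed
determining every output byte:

- **Panel**: 7 samples, 600 SNVs on a 400 kb chromosome; allele
  frequencies from a mixture of common Uniform(0.05, 0.95) and 15% rare
  Uniform(0.001, 0.01) mass; genotypes drawn under Hardy–Weinberg, phase
  is the draw.  Three "twin" rare variants are planted 80–250 bp from
  common sites and conditioned to be heterozygous in exactly one sample,
  so the rare-variant window scan has recoverable truth.
- **Reads**: 101 bp, pre-aligned (alignment is out of scope), exactly
  `depth = 40` reads per het site per assay, start uniform among
  placements covering the site.  A read carries haplotype G1 with
  probability equal to the site's planted ratio (0.5 unplanted, 0.9 for
  planted AS sites oriented to favor the alternative allele, 0.7 for
  "weak" sites meant to surface only in aggregation); its sequence is
  copied from the chosen personal haploid genome, so reads spanning
  several het sites stay allele-consistent and the generator's own tally
  of informative counts is exact ground truth.  5% of reads carry
  base qualities below the Phred-20 cutoff and 2% are duplicate-flagged;
  neither enters the recorded truth.
- **Landscape**: ~60 non-overlapping categorized elements (retained
  categories oversampled), with forced elements covering the
  association-planted and twin sites; three het sites inside retained
  elements are deliberately covered by blacklist intervals to exercise
  pruning.  Random exclusion intervals keep ≥ 100 bp clear of the
  deliberately planted sites so pruning removes exactly the
  blacklist-planted ones.
- **Catalogs**: 5 GWAS + 5 eQTL index SNPs (one shared, creating a
  "both"-linked group; the twin commons are preferred eQTL indices), each
  with 3 engineered r² = 1 proxies (haplotype-column copies) and one
  negative redrawn until r² < 0.5.
- **3D**: 4 TADs with scaled anchor/loop geometry, 2 loop genes per TAD
  plus one anchor-overlapping gene; promoter probes at gene starts, 30
  control probes, SNP probes at selected AS sites; background read pairs
  Poisson with exponentially decaying distance rate, planted pairs
  redrawn until ≥ 12 read pairs in ≥ 2 replicates (rates far above
  background).  Planted interactions realize all three concordance
  labels plus one indirect (1-hop) chain through a SNP probe.
- **Motifs**: two 10 bp motif models — one with a planted first-order
  dependency at the central position, one independence model — provide
  500 training sites each; six planted AS sites get motif instances
  written into the reference such that the motif is intact on exactly one
  allele (three gains, three losses).

What the generator does **not** emulate: ChIP-seq peak shape and
fragment-length structure, mappability/reference bias, sequencing errors,
indels and structural variation, population stratification in LD, and
Hi-C matrix normalization.  Passing tests therefore demonstrate the
statistical and structural machinery on idealized data, not robustness to
those artifacts on real data.

### Funnel verification

`pipeline.funnel_from_manifest` recomputes the expected funnel from the
generator's in-memory truth objects and its recorded read tallies, then
runs the same staged computation the pipeline runs.  Comparing it with a
pipeline run from files verifies the full plumbing — FASTA/VCF/SAM/TSV
round-trips, pileup counting, allele orientation — end to end and exactly;
the statistics themselves are verified separately against independent
oracles (integer-arithmetic binomial tails, textbook BH step-up, 2×2
haplotype-table r², an independent PWM scanner, and an independently
coded replicate filter).

## Numerical choices and degenerate inputs

- Coordinates: VCF 1-based; all interval work 0-based half-open;
  conversion only at I/O boundaries.  Multi-allelic or non-SNV records
  are rejected; unphased heterozygotes error unless a permissive flag
  skips them with a log entry.
- G1/G2 name the left/right haplotypes of the phase bar, not
  reference/alternative: a haplotype mixes ref and alt alleles along a
  chromosome.  The substitution table preserves the mapping.
- Exact binomial p-values are cached by (k, n, ratio); BH is delegated to
  a standard multiple-testing routine and cross-checked against the
  step-up definition.
- Empirical capture p-values use the add-one estimator
  (1 + #{null ≥ x})/(1 + n), which never returns 0.
- BIC depth ties prefer the shallower context; unseen contexts fall back
  to the pseudocount prior.
- Monomorphic sites have undefined r² and return NaN rather than 0.
- Seeds: every stage derives its generator from the run seed and a stage
  tag through `SeedSequence`, so stages are independently reproducible
  and inserting a stage never reshuffles another.

## Problem sizes

Defaults are sized for a laptop-scale run: the full synthetic study
(7 samples × 5 assays × ~460 het sites, ~260k reads) generates in ~3 s
and a complete pipeline run takes ~10 s; the planted-recovery experiment
(≥ 500 null sites, depth 100) takes ~15 s.  All sizes are `SimParams`
fields and scale up directly.

## Known limitations

- The per-run empirical FDR of the recovery experiment is a noisy
  estimate at ~24 discoveries; BH controls its expectation, and single
  runs can exceed α + 2·SE (observed in roughly 7% of seeds) without
  indicating a defect.
- Aggregation assumes a shared ref/alt orientation across samples and
  errors on conflicts rather than attempting to resolve them.
- The motif layer predicts binding-affinity changes, not occupancy; no
  TF-specific binding-energy calibration is attempted.
- Capture target resolution treats fragments as fixed-size bins; real
  restriction fragments are irregular.
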