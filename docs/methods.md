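# Methods

## Problem and approach

A gene duplication can change the selective regime on the cis-regulatory
elements its product binds. The analyses here test that at the
resolution of a single short binding motif: scan two genomes for the
motif, map instances between them, and contrast fixed interspecies
differences with standing polymorphism between motif-core sites and a
neutral reference, in the spirit of the McDonald–Kreitman (MK) test.
Because suitable multi-genome data are large and external, the package
ships a generative model that produces every input with known truth;
all calibration and recovery claims below are made under that model.

## Coordinate and sequence conventions

All coordinates are 0-based half-open (BED convention). A motif
occurrence on the '-' strand is a genomic interval whose forward-strand
bases equal the reverse complement of the motif; a palindromic motif
would be reported once per strand. Scanning is exact-match: positions
containing N never match, overlapping occurrences are all reported.

## Segments, lifting, and site classification

Each instance is extended symmetrically by `flank_bp` (default 7,
giving 21-bp segments for the 7-bp core). Segments that would overrun a
chromosome end are **dropped, not trimmed**, so every segment has the
same length and per-class site totals stay proportional to segment
counts. Segments on chromosomes classed `unassembled` (chrU-like
scaffolds, heterochromatin) are excluded before mapping because
alignment there is unreliable.

Lifting uses ungapped alignment blocks
(`src_chrom src_start src_end dst_chrom dst_start dst_end dst_strand identity`)
with liftOver-like semantics: a segment maps only if it lies inside a
single block whose identity ≥ `min_match` (default 0.95). Segments
touching two blocks or hanging off a block edge are `split`; those in a
low-identity block `below_min_match`; those with no block `unmapped`.
Only `mapped` segments reach the MK stage; the five statuses partition
the input and are logged. The ungapped-block format replaces real chain
files deliberately: it is bit-reproducible, trivially simulable, and
carries the same minMatch semantics at desk scale. Within-segment gapped
alignment is out of scope.

Source and destination sequences are compared in the orientation
(forward vs reverse complement) minimizing the Hamming distance, ties
broken toward forward. Polymorphism is taken from a variant table
filtered to SNPs with minor allele frequency strictly > 5% (MAF folded
from the reported allele frequency); indels are omitted by default. A
site that is both divergent and polymorphic is counted **only as
polymorphic** — the standard way to avoid double counting; the
generative model applies the same rule, and with equal core/flank
polymorphism rates the convention cancels exactly in the expected
alpha (see below).

## The MK statistic

With D = fixed differences and P = polymorphic sites, split core/flank:

    alpha = 1 - (D_flank * P_core) / (D_core * P_flank)

alpha is undefined (signaled, never silently 0) when `D_core = 0` or
`P_flank = 0`. It is invariant to scaling all four cells, increases in
`D_core` and `P_flank`, decreases in the other two, and is at most 1.

- **Bootstrap.** The resampling unit is the segment — all 21 sites move
  together, since sites within 21 bp are effectively fully linked.
  Percentile CI at level 0.99 by default (no BCa); resamples with
  undefined alpha are excluded from the percentiles and their fraction
  logged. A one-sided +1-corrected bootstrap p for alpha > 0 is also
  reported. The default genome-wide analysis aggregates one 2×2 table;
  per-segment alphas are available through the same per-segment counts.
- **Tests.** G test (likelihood-ratio chi-square, df 1, no continuity
  correction) and two-sided Fisher's exact test on the 2×2. A zero
  margin gives Fisher p = 1 and an undefined G (NaN with a warning).
- **Strata.** Chromosome class (X / autosome / dot) from the genome
  labels; exonic vs intergenic by whether the segment's core lies within
  1 kb of an annotated exon — the same closed ≤ 1 kb rule used for the
  exon-proximity statistics, since no separate definition is natural.
  Stratum contrasts use a segment-label permutation test on
  `alpha_a - alpha_b`, two-sided with the +1 correction.
- **Specificity.** The shuffled-motif battery runs the complete
  scan → segment → lift → classify → alpha pipeline for every distinct
  two-position transposition of the motif (17 for ACTGCTT after removing
  identity swaps, duplicates, the motif itself, and its reverse
  complement, which matches the same genomic sites). Raw and
  Bonferroni-adjusted bootstrap p-values are reported per motif, plus a
  flag for whether the focal alpha exceeds every control alpha.
- **Synonymous reference.** `synonymous_reference_alpha` substitutes
  externally supplied (D_syn, P_syn) counts for the flank reference;
  extracting synonymous sites from annotation is out of scope.

## Motif distribution statistics

Genome-wide frequency is reported as a raw count and a density per Mb
(count / size in Mb), with a per-chromosome-class breakdown. Promoter
counts use a strand-aware 500-bp window immediately 5' of the TSS,
truncated at chromosome edges; an instance must lie fully inside the
window. Exon proximity uses a closed threshold (distance ≤ 1000 bp,
overlap = 0). The two-genome proximity contrast equalizes annotation
totals by randomly accumulating the larger genome's exons until the
smaller genome's total bp is reached (stopping at the first exon that
crosses the target), applies Fisher's exact test to the within/beyond
2×2, and conservatively reports the **maximum** p over 10 iterations.

## ChIP TSS-window signal

Reads are single positions; counts are taken in the closed window
[TSS − 350, TSS + 350] (700 bp of extension; 100/500/1000 bp halves are
supported for sensitivity). Each sample's vector is divided by its own
mean, which removes depth differences, makes the per-sample mean exactly
1, and is idempotent. Replicate structure is summarized by PCA over
samples and the silhouette score of factor labels in PC1–PC2.
Between-factor binding divergence is the Euclidean distance between
factor-mean normalized profiles, tested by permuting replicate-to-factor
assignment (one-sided). Chromosome-level enrichment uses the ratio of
median normalized X-linked signal to median autosomal signal (the
simplest scale-free contrast) — tested by permuting gene-to-chromosome labels; factor-vs-factor
enrichment contrasts permute replicate labels instead. No input-control
subtraction is applied anywhere, as none is defined for these inputs.
Conservative peaks are the interval intersections between two
replicates' peak sets (merged, sorted); bound genes are genes whose span
overlaps a conservative peak. Choosing the "two best" replicates is
left explicit, with a helper that ranks replicate pairs by signal
correlation. All permutation p-values use the +1 correction, so
p ∈ (0, 1].

## Phylogenetic ANOVA

Species trait values (e.g. motif density per Mb) covary through shared
ancestry, so a plain ANOVA of trait by group overstates significance.
The test simulates the null instead: the observed one-way ANOVA F of
trait-by-group at the tips is compared against F values from Brownian-
motion simulations on the tree (rate estimated from the observed tips by
phylogenetically independent contrasts — REML, mean squared standardized
contrast, with multifurcations pooled pairwise so star trees work),
keeping group labels fixed; p = (1 + #{F_sim ≥ F_obs}) / (1 + n_sim).
Zero within-group variance yields an infinite F and the minimum
attainable p. On a star tree the tips are iid under BM and the
simulated null reproduces the ordinary ANOVA p. A 9-tip synthetic
ultrametric fixture tree (3 tips labelled with the duplicate, 6 without)
mirrors the study design. Multi-rate BM and OU models are out of scope.

## The generative model

A single integer seed fans out to named substreams (annotation, genome,
divergence, polymorphism, chip, traits), so identical seed + config give
byte-identical FASTA/VCF/BED/GFF3 outputs and adding a generator never
perturbs the others.

- **Genome.** iid bases at the requested GC (default 0.42, typical of
  Drosophila euchromatin); default chromosomes chr2L (200 kb, autosome),
  chrX (150 kb), chr4 (50 kb, dot), chrU (30 kb, unassembled). Exactly
  `n_motifs` (default 300) non-overlapping motif copies are written in,
  forward/reverse-complement 50/50, placed by chromosome-length weights;
  an `exon_proximity_bias` fraction is constrained to within 1 kb of an
  exon. Chance background occurrences arise on top (~0.12/kb for a 7-mer
  counting both strands) and are deliberately *not* in the truth set:
  they evolve neutrally and dilute the genome-wide alpha below the
  planted value, which is the realistic situation the shuffle battery
  controls for.
- **Divergence.** Every site mutates independently: truth-motif cores
  with probability `mu_core`, all other sites `mu_flank`. The emitted
  block map is the identity lift (mapping error can be toggled
  independently via `block_shuffle`, which fragments blocks and jitters
  identities to exercise minMatch failures). A per-substitution log
  records the site class.
- **Polymorphism.** Biallelic SNPs at `theta_core` / `theta_flank`; each
  SNP's minor allele frequency is drawn from the configured spectrum —
  by default a folded neutral site-frequency spectrum for a 200-
  chromosome panel (weights 1/i + 1/(n−i)), approximating a DGRP-sized
  resequencing panel. An optional indel fraction supports sensitivity
  runs.
- **Default rates.** `mu_core = 0.2`, `mu_flank = 0.05`,
  `theta_core = theta_flank = 0.05`: the adaptive regime with analytic
  adaptive fraction alpha* = 1 − (mu_flank·theta_core)/(mu_core·theta_flank)
  = 0.75. Equal thetas make the polymorphic-wins convention cancel in
  alpha* exactly (effective divergence rates are mu·(1−theta) per
  class, and the (1−theta) factors cancel). Setting all four rates equal
  gives the fully neutral model used for calibration.
- **ChIP.** Background reads uniform over the genome (default 20 000 per
  replicate); bound genes get `chip_enrichment`-fold (default 8) the
  expected background count in the ±350 bp TSS window, modulated by a
  per-(factor, gene) log-normal effect shared across replicates so
  replicates cluster by factor; a per-chromosome fold plants chromosome-
  wide affinity (the X-enrichment construction). Peaks are emitted at
  bound TSSs in every replicate plus a few replicate-specific spurious
  peaks that the conservative intersection removes. No sequencer error
  model, fragment-length model, or read-level alignment is simulated.
- **Traits.** Brownian motion along the tree: independent Gaussian edge
  increments of variance sigma2 × branch length, plus an optional group
  effect at designated tips.
- **Segment-level shortcut.** `simulate_segment_records` draws per-site
  divergence/polymorphism for n segments directly at the class rates,
  emitting the exact schema of the genome pipeline's site classifier.
  The replicated calibration and recovery studies use it so that
  hundreds of replicates stay cheap; the full genome path (scan → lift →
  classify) is exercised end to end by the pipeline runs and the shuffle
  battery.

## What the synthetic model does and does not show

The generator matches the *statistical structure* the analyses assume —
distinct core/flank substitution regimes, an MAF spectrum with a 5%
filter boundary, TSS-enriched replicated ChIP signal, BM trait evolution
— but not real-data complications: alignment gaps and paralogy, base
composition heterogeneity and mutation-rate variation, linked selection
and demography (which bias MK-style alpha in real populations),
ChIP fragment-size effects, or annotation error. Passing calibration
here therefore validates the *implementation and its statistical
behaviour under the stated model*, not robustness of alpha to
demographic or alignment artefacts in real genomes; DFE/demography
corrections and asymptotic-MK extrapolation are explicit non-goals.

## Study conditions and problem sizes

The replicated studies in `motifmk.studies` (used by the test suite and
`scripts/acceptance.py`) fix: neutral and adaptive rate sets as above;
2000 segments per replicate; 100 replicates with 1000 bootstrap
resamples for CI coverage; 1000 table replicates for G-test type-I; a
1-Mb two-chromosome genome with 400 planted motifs for the shuffle
battery (large enough that each of the 17 control motifs has ~100+
chance occurrences and a stable null alpha); a 3-factor × 4-replicate
ChIP design over 120 genes with disjoint 30-gene bound sets, a planted
5× X affinity for one factor, and 5000 label permutations; and 500
phylogenetic-ANOVA runs at 199 simulations each on the 9-tip fixture
tree. These sizes are the package's standard desk-scale conditions;
every run completes in seconds to tens of seconds on one CPU.

## Numerical and degenerate-input choices

- Orientation ties in difference counting break toward forward.
- Downsampling stops at the first exon meeting/exceeding the bp target;
  the conservative max-p rule absorbs the slack.
- Normalization requires a positive per-sample mean; all-zero samples
  are an error, not a silent zero.
- Bootstrap/permutation p-values carry the +1 correction; bootstrap
  resamples and permutations with undefined alpha are excluded with a
  logged fraction, and an error is raised if more than half are
  undefined (the contrast is then meaningless).
- PCA silhouette requires ≥ 3 samples and ≥ 2 factors; ANOVA groups
  need ≥ 2 tips each.
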