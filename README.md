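# motifmk

Motif-level tests of positive selection on cis-regulatory DNA, built
around a McDonald–Kreitman (MK) test applied to a short transcription-
factor binding motif, plus the surrounding machinery: genome-wide motif
scanning, cross-genome coordinate lifting, ChIP-seq TSS-window signal
comparison, and a simulation-based phylogenetic ANOVA. A first-class
synthetic-data generator produces every input (genomes, gene models,
SNPs, alignment blocks, ChIP reads, trait values) with known ground
truth, so the whole pipeline runs end to end with no downloads.

The package is aimed at population/regulatory genomicists who want to
ask: *did natural selection act specifically on instances of a binding
motif, rather than on the sequence around them?* The motivating system
is the Drosophila CCR4–NOT subunit Caf40 and its testis-expressed
retrogene duplicate Zeus, whose shared 7-bp core binding motif
(`ACTGCTT`, the "CAZAM") shows genome-wide frequency and distribution
shifts between species with and without the duplicate.

## The statistic

Each exact motif occurrence (either strand) is extended by 7 bp on each
side into a 21-bp segment. Segments on unassembled/heterochromatic
scaffolds are discarded; the rest are lifted to a second genome through
ungapped alignment blocks with liftOver-style semantics (minMatch 0.95),
and source/destination sequences are compared in the orientation that
minimizes the number of differences. Per segment position we count

- **D** — fixed interspecies differences, split into motif-**core** and
  **flank** sites, and
- **P** — segregating polymorphisms (SNPs only, minor allele frequency
  > 5%), same split; a site that is both counts only as polymorphic.

With flanks as the neutral reference, the adaptive fraction is

```
alpha = 1 - (D_flank * P_core) / (D_core * P_flank)
```

interpreted as the proportion of core-site fixed differences driven by
positive selection. Uncertainty comes from a bootstrap that resamples
*segments* (sites within 21 bp are linked), significance from G and
Fisher's exact tests on the 2×2 table, and specificity from an empirical
null battery: all 17 distinct two-position shuffles of the motif pushed
through the identical pipeline.

Also included: promoter (500 bp upstream) motif counts, exon-proximity
(≤ 1 kb) fractions with an annotation-downsampling test, per-gene ChIP
signal in a ±350 bp TSS window (normalized to each experiment's mean)
with PCA/silhouette replicate checks and X-vs-autosome permutation
tests, and a Brownian-motion-based phylogenetic ANOVA for cross-species
motif-frequency contrasts.

## Worked example

```python
from motifmk import simulate, scan, orthomap, mk

cfg = simulate.SimConfig(seed=1)           # adaptive regime, alpha* = 0.75
genes = simulate.simulate_annotation(cfg)
genome, truth = simulate.simulate_genome(cfg, genes=genes)
derived, blocks, _ = simulate.simulate_divergence(genome, truth, cfg)
variants = simulate.simulate_polymorphism(genome, truth, cfg)

instances = scan.scan_motif(genome, cfg.motif)
segments = orthomap.build_segments(instances, genome)
pairs = orthomap.map_segments(segments, orthomap.BlockMap(blocks), genome, derived)
records = orthomap.classify_pairs(pairs, variants)

print(mk.build_mk_table(records))
est = mk.bootstrap_alpha(records, n_boot=1000, level=0.99, seed=1)
print(f"alpha = {est.alpha:.3f}  99% CI [{est.ci_low:.3f}, {est.ci_high:.3f}]")
```

prints

```
MKTable(D_core=377, D_flank=235, P_core=56, P_flank=121, stratum='all')
alpha = 0.712  99% CI [0.534, 0.821]
```

The genome planted 300 motif copies whose cores diverge at 4× the flank
rate with equal polymorphism rates, implying an expected alpha of 0.75;
the scan also picks up ~60 chance occurrences that evolve neutrally,
which dilutes the genome-wide estimate slightly below the planted value
— exactly the behaviour the shuffled-motif control battery quantifies.
The CI excludes 0: positive selection on motif cores is detected.

The same analyses are scriptable from the shell:

```sh
motifmk simulate --seed 1 --outdir sim/
motifmk scan --fasta sim/genome.fa --motif ACTGCTT --out inst.bed
motifmk map --src-fasta sim/genome.fa --dst-fasta sim/genome_derived.fa \
    --instances inst.bed --blocks sim/blocks.tsv --vcf sim/snps.vcf --out sites.tsv
motifmk mk --site-records sites.tsv --boot 1000 --level 0.99 --seed 1
motifmk run-all --seed 1 --outdir run/     # everything + manifest.json
```

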