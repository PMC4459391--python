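# ibd2scan

Mapping shared identity-by-descent (IBD2) from sibling exomes, and
prioritizing recessive candidate variants inside those regions.

## The problem

When several siblings share a presumed autosomal-recessive condition, any
causal gene must lie in a region where all affected siblings inherited *both*
parental haplotypes identical-by-descent (IBD2). For `n` affected siblings
the expected IBD2 fraction of the genome is (1/4)^(n-1) — 1/16 ≈ 6.25% for
three — so restricting the variant search to IBD2 loci shrinks the search
space enormously without needing genetic maps, population allele
frequencies, or LD pruning.

`ibd2scan` detects IBD2 directly from a multi-sample exome VCF. At each
well-covered, PASS-flagged biallelic SNV outside repeat/segmental-duplication
masks, it computes each sibling's **allelic ratio** r = (alt reads)/(total
reads) and, for every sibling pair (i, j), the track

    |Δ_ij| = | r_i − r_j |

In IBD2 regions both siblings carry the same genotype at every site, so
|Δ| converges on zero (up to binomial counting noise at depth d, the het-het
difference has SD ≈ √(1/2d)); where the pair is not IBD2, discordant
genotypes push |Δ| toward 0.5 or 1. Regions are called with a sliding-window
rule (window mean |Δ| < τ with an outlier-spike guard), merged, intersected
across all sibling pairs, and summarized with cumulative sizes and percent of
the autosomal genome.

Within (or without) the IBD2 restriction, the package then runs the
candidate-variant funnel: rare (population AF < 1%) predicted-deleterious
variants tested under compound-heterozygous, simple-recessive and
shared-de-novo segregation models, with compound-het phasing by parental
origin.

Because real family sequencing data cannot be redistributed, the package
includes a pedigree-exome **simulator** (Poisson site placement, Beta
population frequencies, Poisson-crossover meioses, negative-binomial depth,
binomial allele counts, a planted compound-het causal pair) whose exact
inheritance-vector ground truth is used to validate the caller end to end.

## Worked example

```bash
python examples/02_map_ibd2_regions.py
```

simulates a three-sibling family at 1/10 genome scale, filters ~41,600 sites
to ~40,100, maps IBD2 and scores the calls against the simulator truth:

```
chrom   start      end  n_sites     size  cumulative_size  cumulative_percent
 chr3   45588  3769268      509  3723680          3723680                1.29
 chr8 7061227 11853881      695  4792654          8516334                2.96
chr15     759 10237930     1475 10237171         18753505                6.51
chr20    1912  4722636      661  4720724         23474229                8.15
vs truth: sensitivity=0.997 precision=0.995 jaccard=0.992
```

Four regions covering 8.15% of this (scaled) genome are IBD2 in all three
siblings — single families scatter widely around the 6.25% expectation — and
the calls recover the true IBD2 intervals at >99% base-pair accuracy.
`examples/03_prioritize_variants.py` continues on the same family: of 8 rare
predicted-deleterious variants, 2 lie in IBD2 loci, and the compound-het
model reports exactly the planted gene with a paternal stop-gain and a
maternal missense variant. `examples/04_region_table_arithmetic.py` prints
the bundled nine-region published example (248,200,023 bp = 8.59% of the
2,888,135,837-bp autosome, five regions above 20 Mb).

The same pipeline is available as a CLI for real VCFs:

```bash
ibd2scan run family.vcf --father I-1 --mother I-2 \
    --child II-1 --child II-2 --child II-3 \
    --mask-bed segdup.bed --mask-bed rmsk.bed --out-dir results/
```

with `simulate`, `filter`, `map-ibd2`, `prioritize` and `evaluate`
subcommands for the individual stages.

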