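# Methods

## IBD2 detection from allelic ratios

At a biallelic SNV, a sample's allelic ratio r = v/d (alt reads over total
reads) estimates half the ALT allele dose: E[r] ≈ e, 1/2, 1−e for hom-REF,
het, hom-ALT genotypes, where e is the per-read miscall rate. Two siblings
who are IBD2 at a locus have identical genotypes, so the absolute difference
of their ratios is pure counting noise: for a shared het site at depths d₁,
d₂ the difference is approximately normal with SD 0.5·√(1/d₁ + 1/d₂)
(≈ 0.091 at 60×), and E|Δ| ≈ 0.073; hom sites contribute |Δ| ≈ 0. Where the
pair is not IBD2, a substantial fraction of sites have genotypes differing
by one dose (|Δ| ≈ 0.5) or two (|Δ| ≈ 1). The separation between the two
regimes is what the region caller exploits; it needs no genetic map,
population frequencies, or LD pruning.

### Pre-filters

The site set entering the tracks: biallelic single-nucleotide substitutions,
FILTER = PASS, outside user-supplied masks (segmental duplications,
repeat-masked sequence — these tracks are inputs, not bundled), and depth
≥ 15 in **every affected child** (parents are deliberately exempt; their
fields only serve prioritization). Each removed site is attributed to the
first failing stage, so attrition counts sum to the input count; the four
predicates are independent, so the surviving set is order-invariant. A
missing depth in any affected child fails the coverage predicate
(conservative). Multiallelic records are excluded by default rather than
split; both the NR/NV (total + variant reads) and AD (per-allele depths)
FORMAT dialects are auto-detected from the header and can be overridden.

### Region calling

Published analyses of this kind have often drawn IBD2 boundaries by eye; the
caller here makes that judgement algorithmic. A window of W = 25 consecutive
non-missing sites is an IBD2 candidate iff

* mean |Δ| < τ = 0.06, and
* the fraction of sites with |Δ| > δ = 0.35 is below 10%.

Defaults were reasoned from the noise model: an IBD2 window at 60× mean
depth has expected mean |Δ| ≈ 0.03–0.045 (het fraction ~0.4 of sites times
E|Δ|_het ≈ 0.08–0.09), well below τ, while even an IBD1 region has ≥ 20% of
sites near 0.5, far above it; the spike guard catches isolated discordant
genotypes (caller artifacts) that a mean alone would average away.
Candidate windows with gaps ≤ 1 Mb merge; merged regions are bounded by
their first and last supporting variants (no extension to midpoints or
chromosome ends), and must span ≥ 1 Mb with ≥ 50 supporting sites. Missing
|Δ| values are skipped, not imputed. Per-pair calls are merged first, then
intersected across all sibling pairs; minimum-size/-site filters are
re-applied after intersection. Lowering τ can only shrink the called
footprint (tested property).

Region size is reported as end − start (the convention of the published
nine-region example bundled in `ibd2scan.example_data`, whose printed sizes
equal exactly end − start); BED output converts the 1-based inclusive
variant-anchored bounds to 0-based half-open. Cumulative percentages are
taken against a conventional autosome size of 2,888,135,837 bp
(overridable). Tables are emitted in natural chromosome order by default,
with `lexicographic` and `given` modes for compatibility with other tools'
output ordering.

## Prioritization

"Predicted deleterious" = frameshift, in-frame insertion/deletion, stop
gained/lost, missense, splice donor/acceptor, or an intronic/splice-region
variant annotated ≤ 2 bases into the intron; a variant-database membership
flag is honored by default. Rarity is population AF strictly < 0.01; a
missing AF counts as rare (discovery intent — a variant absent from
reference panels is the most interesting kind), with a strict mode to flip
this. Sequence-based effect prediction and splice-strength models are out of
scope: annotations are read, never computed.

Segregation models operate on hard genotype calls (allelic ratios serve only
the IBD step):

* **compound het** — per gene, ≥ 2 variants het in all affected children
  with at least one paternal-only (father het, mother hom-REF) and one
  maternal-only variant; variants het in both parents are reported as
  "unphased" but count toward neither origin (no read-backed phasing);
* **simple recessive** — hom-ALT in all children, het in both parents;
* **shared de novo** — het in all children, hom-REF in both parents, each
  parent's call trusted only at depth ≥ 15 (presumed germline mosaicism).

These predicates are mutually exclusive per variant by construction.

## The simulator

The generator emulates the study design the method expects: a two-parent,
n-sibling (default 3) exome cohort.

| parameter | default | rationale |
|---|---|---|
| site spacing | Poisson process, mean 5,400 bp | typical exome inter-variant spacing; gap median is 5400·ln2 ≈ 3.7 kb |
| population ALT AF | Beta(0.8, 0.8) | U-shaped frequency spectrum; ~2% of raw sites are rare (<1%) |
| mean depth | 60× (negative binomial, size 8) | mid-range exome coverage; size 8 leaves >99% of sites above the 15× filter |
| read miscall rate | 0.005 per read | hom sites show alt fractions ≈ 0.5% |
| crossover rate | 1 × 10⁻⁸ /bp/meiosis | ≈ 1 cM/Mb sex-averaged; homogeneous Poisson, no interference |
| PASS rate | 0.97 | a few percent of sites fail caller filters |
| genome | 22 hg19 autosomes | scalable by a single factor for fast tests |

Meioses draw Poisson(L·rate) crossovers uniformly per chromosome with a fair
starting haplotype; per-child inheritance vectors label every interval with
the transmitted (paternal, maternal) haplotype pair, and true IBD2 intervals
are exactly the maximal intervals where all children's label pairs agree.
Genotype calls are truth-conditioned: caller error enters only through the
binomial allelic-count noise and the non-PASS flags, matching a method that
consumes allelic fractions rather than genotype likelihoods. Only sites
carrying at least one ALT allele among the four parental haplotypes are
emitted (a joint caller reports no evidence at family-monomorphic sites);
this ascertainment raises the median spacing of emitted sites ~30% above
the raw-process value. A compound-het causal pair (stop-gain on the shared
paternal haplotype, missense on the shared maternal one, AF 0, one synthetic
gene) is planted inside the largest true IBD2 interval holding ≥ 2 sites;
if no interval qualifies the simulation retries with a derived seed up to a
configured limit. All randomness flows from the single configured seed;
identical config + seed gives byte-identical VCF/BED/JSON output.

What the simulator does **not** model: real exome target geometry and
GC-dependent coverage, linkage disequilibrium and haplotype structure,
crossover interference and sex-specific maps, mapping artifacts from
pseudogenes/paralogs (beyond an optional ARTIFACT INFO tag), genotype-caller
errors correlated across samples, and indel/multiallelic sites. Passing
validation on simulated data therefore demonstrates correctness of the
algorithmic chain under the stated noise model, not performance on every
real-data pathology — on real exomes the mask files and the spike guard
carry the burden the simulator's clean haplotypes do not exercise.

## Validation scales and numerical choices

Sanity checks with closed-form oracles run at single-chromosome scale.
The caller's sensitivity/precision sweep uses 20 seeds of a three-sibling
family on a 1/10-scaled genome (~289 Mb, ~53,000 raw sites) at default
parameters — large enough that every chromosome spans many windows, small
enough to iterate quickly; measured base-pair sensitivity and precision
against truth average ≈ 0.99. One caveat of the scaled genome: a small
fraction of replicates produce a total truth IBD2 footprint below the
caller's 1 Mb / 50-site minimum; those replicates score zero by
construction (the caller's contract excludes sub-minimum regions) and pull
sweep averages down slightly for some seed choices. The 1/16 expectation check uses 200
replicate meiosis-only simulations of the full-size 22-autosome genome
(inheritance vectors only; sites are not needed) and tests the mean against
1/16 within three standard errors. Windows use exact prefix-sum means;
interval arithmetic is integer throughout; region intersection and mask
lookup use sorted arrays with binary search. Degenerate inputs (no
survivors, chromosomes with fewer sites than one window, empty region
lists, single-child pedigrees) produce empty-but-valid outputs rather than
errors, except where the contract demands a hard error (pedigree sample
missing from the VCF header, no supported depth dialect, median spacing of
fewer than two sites).
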