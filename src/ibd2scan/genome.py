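"""Genome constants: hg19 autosome lengths and chromosome ordering helpers."""

from __future__ import annotations

# hg19 / GRCh37 autosome lengths (bp).
HG19_AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
}

#: Conventional autosomal genome size used when expressing region totals as a
#: percent of the autosome.  This is the figure commonly quoted for the hg19
#: autosomes in exome-mapping work, not the sum of the contig lengths above.
AUTOSOME_GENOME_SIZE: int = 2_888_135_837


def natural_chrom_key(name: str) -> tuple[int, str]:
    """Sort key placing chr1..chr22 in numeric order, other names after."""
    stem = name[3:] if name.lower().startswith("chr") else name
    if stem.isdigit():
        return (int(stem), "")
    return (10_000, stem)


def scaled_lengths(factor: float, lengths: dict[str, int] | None = None) -> dict[str, int]:
    """Chromosome-length table scaled by ``factor`` (used for fast simulations)."""
    src = HG19_AUTOSOME_LENGTHS if lengths is None else lengths
    return {c: max(1, int(round(n * factor))) for c, n in src.items()}
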