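"""Small bundled example data.

``NINE_REGION_EXAMPLE`` is the published nine-region IBD2 table from a
three-sibling family exome study (hg19 coordinates, 1-based bounding-variant
positions): the worked example used throughout the docs for region-summary
arithmetic.  The conventional autosomal genome size that goes with it is
``genome.AUTOSOME_GENOME_SIZE`` (2,888,135,837 bp).
"""

from __future__ import annotations

#: (chromosome, start bp, end bp); size convention is end - start.
NINE_REGION_EXAMPLE: tuple[tuple[str, int, int], ...] = (
    ("chr1", 29_652_068, 58_939_634),
    ("chr12", 13_140_398, 29_599_225),
    ("chr2", 128_936_000, 196_663_997),
    ("chr4", 83_857_109, 151_161_470),
    ("chr9", 139_371_405, 141_213_431),
    ("chr16", 89_345_408, 90_354_753),
    ("chr18", 46_196_998, 71_989_909),
    ("chr20", 40_714_524, 52_185_814),
    ("chr22", 17_280_822, 44_586_522),
)
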