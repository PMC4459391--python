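"""Synthetic pedigree-exome simulator.

Generates a multi-sample family exome (two parents + n affected siblings) with
the statistical structure the IBD2 analysis assumes:

* biallelic SNV sites placed by a Poisson process (~5.4 kb mean spacing);
* population ALT frequencies from a Beta law; parental haplotypes carry ALT
  alleles independently at those frequencies;
* Mendelian transmission through meioses with Poisson crossovers
  (no interference, sex-averaged, ~1 cM/Mb by default);
* per-sample read depth from an overdispersed (negative binomial) law and
  alt-read counts from a binomial law around the genotype's allele dose;
* PASS / LowQual filter flags, and a planted compound-heterozygous causal
  pair (stop-gain + missense, one variant per parent) inside a region where
  all siblings are IBD2.

The ground truth (per-child inheritance vectors and the exact IBD2 intervals)
is retained so callers can be scored against it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genome import natural_chrom_key
from .pedigree import Pedigree

log = logging.getLogger(__name__)

PATERNAL_LABELS = ("A", "B")
MATERNAL_LABELS = ("C", "D")

_BASES = np.array(list("ACGT"))

# Background consequence mix for annotated simulated sites.
_CSQ_TERMS = (
    "synonymous_variant",
    "missense_variant",
    "intron_variant",
    "5_prime_UTR_variant",
    "stop_gained",
    "splice_donor_variant",
)
_CSQ_PROBS = (0.45, 0.30, 0.15, 0.08, 0.01, 0.01)


@dataclass(frozen=True)
class ParentalHaplotypes:
    """Four phased parental haplotypes on one chromosome.

    ``alleles`` has shape (4, n_sites): rows 0-1 are the father's haplotypes
    (labels A, B), rows 2-3 the mother's (labels C, D); entries are 0/1 ALT
    indicators.
    """

    positions: np.ndarray  # 1-based, strictly increasing
    freqs: np.ndarray  # population ALT frequency per site
    alleles: np.ndarray  # (4, n) int8


@dataclass(frozen=True)
class InheritanceVector:
    """Which parental haplotype a child carries along one chromosome.

    ``breakpoints`` are strictly increasing positions b; positions <= b lie in
    the interval before the crossover at b. ``labels`` has one
    (paternal, maternal) pair per interval (len(breakpoints) + 1 entries).
    """

    child: str
    chromosome: str
    length: int
    breakpoints: tuple[int, ...]
    labels: tuple[tuple[str, str], ...]

    def label_at(self, pos: int) -> tuple[str, str]:
        i = int(np.searchsorted(np.asarray(self.breakpoints), pos, side="left"))
        return self.labels[i]


@dataclass(frozen=True)
class CausalPair:
    gene: str
    chromosome: str
    paternal_pos: int  # stop-gain, carried by father + all children
    maternal_pos: int  # missense, carried by mother + all children
    interval: tuple[int, int]  # the true IBD2 interval hosting both


@dataclass
class TruthSet:
    """Simulator ground truth: inheritance vectors, IBD2 intervals, causal pair."""

    vectors: dict[str, dict[str, InheritanceVector]]  # chrom -> child -> vector
    ibd2_intervals: dict[str, list[tuple[int, int]]]  # 1-based inclusive
    causal: CausalPair | None = None

    def ibd2_fraction(self, lengths: dict[str, int]) -> float:
        """Fraction of the genome where all children are IBD2."""
        shared = sum(
            e - s + 1 for ivs in self.ibd2_intervals.values() for s, e in ivs
        )
        return shared / sum(lengths.values())


@dataclass
class SimulatedFamily:
    config: SimulationConfig
    pedigree: Pedigree
    sites: pd.DataFrame
    truth: TruthSet
    seed_used: int


# ---------------------------------------------------------------------------
# haplotypes and meiosis
# ---------------------------------------------------------------------------

def simulate_parental_haplotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[str, ParentalHaplotypes]:
    """Draw site positions and four parental haplotypes per chromosome.

    Positions follow a homogeneous Poisson process with mean gap
    ``variant_spacing_bp``; each haplotype carries ALT independently with the
    site's population frequency.  Sites monomorphic in the family are kept
    here (ascertainment happens when the callable site table is assembled).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    out: dict[str, ParentalHaplotypes] = {}
    for chrom, length in config.chromosome_lengths.items():
        # Exponential gaps; draw with head-room then trim at chromosome end.
        n_draw = max(8, int(length / config.variant_spacing_bp * 1.4) + 8)
        gaps = rng.exponential(config.variant_spacing_bp, size=n_draw)
        pos = np.cumsum(gaps)
        while pos[-1] < length:  # rare: extend until past the end
            extra = rng.exponential(config.variant_spacing_bp, size=n_draw)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        pos = np.unique(pos[pos < length].astype(np.int64) + 1)
        freqs = config.allele_freq_distribution.sample(rng, pos.size)
        alleles = (rng.random((4, pos.size)) < freqs).astype(np.int8)
        out[chrom] = ParentalHaplotypes(positions=pos, freqs=freqs, alleles=alleles)
    return out


def simulate_meiosis(
    length: int, crossover_rate_per_bp: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """One meiosis on one chromosome.

    Returns (breakpoints, start): crossover count ~ Poisson(length * rate),
    breakpoint positions uniform on [1, length-1], and the haplotype index
    (0 or 1) transmitted at the start of the chromosome, chosen fairly.
    """
    k = rng.poisson(length * crossover_rate_per_bp)
    if k > 0 and length > 1:
        bps = np.unique(rng.integers(1, length, size=k))
    else:
        bps = np.empty(0, dtype=np.int64)
    start = int(rng.integers(2))
    return bps, start


def transmitted_hap_index(
    positions: np.ndarray, breakpoints: np.ndarray, start: int
) -> np.ndarray:
    """Haplotype index (0/1) transmitted at each site position."""
    return (start + np.searchsorted(breakpoints, positions, side="left")) % 2


def build_inheritance_vector(
    child: str,
    chrom: str,
    length: int,
    paternal: tuple[np.ndarray, int],
    maternal: tuple[np.ndarray, int],
) -> InheritanceVector:
    """Combine the two meioses of one child into a labelled inheritance vector.

    If a paternal and a maternal crossover land on the same base (possible,
    though vanishingly rare, with integer positions) the maternal one is
    nudged downstream so that adjacent intervals always differ in exactly one
    of the two labels.
    """
    pat_bps, pat_start = paternal
    mat_bps, mat_start = maternal
    pat_set = set(int(b) for b in pat_bps)
    mat_list: list[int] = []
    for b in mat_bps:
        b = int(b)
        while b in pat_set or b in mat_list:
            b += 1
        if b < length:
            mat_list.append(b)
    mat_bps = np.array(sorted(mat_list), dtype=np.int64)

    merged = np.unique(np.concatenate([pat_bps, mat_bps])).astype(np.int64)
    probe = np.concatenate([merged, [length]])  # one probe per interval (its end)
    pat_idx = transmitted_hap_index(probe, pat_bps, pat_start)
    mat_idx = transmitted_hap_index(probe, mat_bps, mat_start)
    labels = tuple(
        (PATERNAL_LABELS[p], MATERNAL_LABELS[m]) for p, m in zip(pat_idx, mat_idx)
    )
    return InheritanceVector(
        child=child,
        chromosome=chrom,
        length=length,
        breakpoints=tuple(int(b) for b in merged),
        labels=labels,
    )


def simulate_inheritance(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> TruthSet:
    """Simulate the meioses only: inheritance vectors and true IBD2 intervals."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    children = [f"CHILD{i + 1}" for i in range(config.n_children)]
    vectors: dict[str, dict[str, InheritanceVector]] = {}
    ibd2: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in config.chromosome_lengths.items():
        per_child: dict[str, InheritanceVector] = {}
        for child in children:
            pat = simulate_meiosis(length, config.crossover_rate_per_bp, rng)
            mat = simulate_meiosis(length, config.crossover_rate_per_bp, rng)
            per_child[child] = build_inheritance_vector(child, chrom, length, pat, mat)
        vectors[chrom] = per_child
        ibd2[chrom] = true_ibd2_intervals(list(per_child.values()), length)
    return TruthSet(vectors=vectors, ibd2_intervals=ibd2)


def true_ibd2_intervals(
    vectors: list[InheritanceVector], length: int
) -> list[tuple[int, int]]:
    """Maximal intervals where every child carries the same (pat, mat) labels.

    Returned as 1-based inclusive (start, end) pairs covering, in the
    one-child case, the whole chromosome.
    """
    if not vectors:
        return []
    edges = sorted({b for v in vectors for b in v.breakpoints})
    starts = [1] + [b + 1 for b in edges]
    ends = [*edges, length]
    out: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if s > e:
            continue
        ref = vectors[0].label_at(s)
        if all(v.label_at(s) == ref for v in vectors[1:]):
            if out and out[-1][1] + 1 == s:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
    return out


def pair_label_agreement_fraction(
    v1: InheritanceVector, v2: InheritanceVector, lineage: str = "paternal"
) -> float:
    """Fraction of the chromosome where two children carry the same haplotype
    from one parent (``lineage`` in {"paternal", "maternal", "both"})."""
    idx = {"paternal": 0, "maternal": 1}.get(lineage)
    edges = sorted(set(v1.breakpoints) | set(v2.breakpoints))
    starts = [1] + [b + 1 for b in edges]
    ends = [*edges, v1.length]
    agree = 0
    for s, e in zip(starts, ends):
        l1, l2 = v1.label_at(s), v2.label_at(s)
        same = l1 == l2 if idx is None else l1[idx] == l2[idx]
        if same:
            agree += e - s + 1
    return agree / v1.length


# ---------------------------------------------------------------------------
# reads and genotypes
# ---------------------------------------------------------------------------

def simulate_reads_and_genotypes(
    genotypes: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Depth and alt-read counts for a genotype matrix (n_samples, n_sites).

    Depth ~ NegBin(mean=mean_depth, size=depth_dispersion); alt reads ~
    Binomial(depth, p) with p = e, 0.5, 1-e for allele dose 0, 1, 2
    (e = base_error_rate).  Genotype calls themselves are the truth.
    """
    m, r = config.mean_depth, config.depth_dispersion
    dp = rng.negative_binomial(r, r / (r + m), size=genotypes.shape)
    e = config.base_error_rate
    p_alt = np.choose(genotypes, [e, 0.5, 1.0 - e])
    nv = rng.binomial(dp, p_alt)
    return dp.astype(np.int64), nv.astype(np.int64)


# ---------------------------------------------------------------------------
# full family simulation
# ---------------------------------------------------------------------------

def _sample_columns(samples: tuple[str, ...]) -> list[str]:
    cols: list[str] = []
    for s in samples:
        cols += [f"gt_{s}", f"dp_{s}", f"nv_{s}"]
    return cols


def _simulate_once(config: SimulationConfig, seed: int) -> SimulatedFamily:
    rng = np.random.default_rng(seed)
    pedigree = Pedigree.default(config.n_children)
    haps = simulate_parental_haplotypes(config, rng)

    vectors: dict[str, dict[str, InheritanceVector]] = {}
    ibd2: dict[str, list[tuple[int, int]]] = {}
    frames: list[pd.DataFrame] = []
    for chrom, length in config.chromosome_lengths.items():
        hp = haps[chrom]
        per_child: dict[str, InheritanceVector] = {}
        child_gt = []
        for child in pedigree.children:
            pat = simulate_meiosis(length, config.crossover_rate_per_bp, rng)
            mat = simulate_meiosis(length, config.crossover_rate_per_bp, rng)
            vec = build_inheritance_vector(child, chrom, length, pat, mat)
            per_child[child] = vec
            # recover per-site transmitted indices from the merged vector
            probe_idx = np.searchsorted(np.asarray(vec.breakpoints), hp.positions, "left")
            pat_idx = np.fromiter(
                (PATERNAL_LABELS.index(vec.labels[i][0]) for i in probe_idx),
                dtype=np.int64, count=hp.positions.size,
            )
            mat_idx = np.fromiter(
                (MATERNAL_LABELS.index(vec.labels[i][1]) for i in probe_idx),
                dtype=np.int64, count=hp.positions.size,
            )
            site_ix = np.arange(hp.positions.size)
            child_gt.append(
                hp.alleles[pat_idx, site_ix] + hp.alleles[2 + mat_idx, site_ix]
            )
        vectors[chrom] = per_child
        ibd2[chrom] = true_ibd2_intervals(list(per_child.values()), length)

        father_gt = hp.alleles[0] + hp.alleles[1]
        mother_gt = hp.alleles[2] + hp.alleles[3]
        gt = np.vstack([father_gt, mother_gt, *child_gt]).astype(np.int64)

        # joint-caller ascertainment: only sites variant in the family appear
        keep = hp.alleles.any(axis=0)
        pos = hp.positions[keep]
        gt = gt[:, keep]
        freqs = hp.freqs[keep]
        n = pos.size
        if n == 0:
            continue

        dp, nv = simulate_reads_and_genotypes(gt, config, rng)
        ref_i = rng.integers(0, 4, size=n)
        alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
        csq = rng.choice(_CSQ_TERMS, size=n, p=_CSQ_PROBS)
        spd = np.full(n, np.nan)
        intronic = csq == "intron_variant"
        spd[intronic] = rng.integers(1, 51, size=int(intronic.sum()))
        flt = np.where(rng.random(n) < config.pass_rate, "PASS", "LowQual")
        artifact = rng.random(n) < config.artifact_fraction

        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": _BASES[ref_i],
                "alt": _BASES[alt_i],
                "filter": flt,
                "gene": [f"{chrom}_g{p // 30000:06d}" for p in pos],
                "csq": csq,
                "spd": spd,
                "af": np.round(freqs, 6),
                "db": False,
                "artifact": artifact,
            }
        )
        for i, s in enumerate(pedigree.samples):
            frame[f"gt_{s}"] = gt[i]
            frame[f"dp_{s}"] = dp[i]
            frame[f"nv_{s}"] = nv[i]
        frames.append(frame)

    if not frames:
        raise RuntimeError("simulation produced no variant sites")
    sites = pd.concat(frames, ignore_index=True)
    truth = TruthSet(vectors=vectors, ibd2_intervals=ibd2)

    if config.plant_causal:
        sites = plant_causal_pair(truth, sites, config, rng)
        if truth.causal is None:
            raise _NoQualifyingInterval()

    order = sites["chrom"].map(natural_chrom_key)
    sites = (
        sites.assign(_k=order)
        .sort_values(["_k", "pos"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    return SimulatedFamily(
        config=config, pedigree=pedigree, sites=sites, truth=truth, seed_used=seed
    )


class _NoQualifyingInterval(Exception):
    pass


def plant_causal_pair(
    truth: TruthSet,
    sites: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Insert a compound-het causal pair inside the largest true IBD2 interval.

    The stop-gain variant is heterozygous in the father and every child; the
    missense variant is heterozygous in the mother and every child; each sits
    on the parental haplotype all children share within the interval, so the
    two never co-occur on one parental haplotype.  On success ``truth.causal``
    is set; if no interval contains at least two simulated sites the table is
    returned unchanged and ``truth.causal`` stays None.
    """
    best: tuple[int, str, tuple[int, int]] | None = None
    for chrom, intervals in truth.ibd2_intervals.items():
        pos = sites.loc[sites["chrom"] == chrom, "pos"].to_numpy()
        for s, e in intervals:
            n_inside = int(np.searchsorted(pos, e, "right") - np.searchsorted(pos, s, "left"))
            if n_inside >= 2:
                span = e - s
                if best is None or span > best[0]:
                    best = (span, chrom, (s, e))
    if best is None:
        return sites

    span, chrom, (s, e) = best
    existing = set(sites.loc[sites["chrom"] == chrom, "pos"].tolist())
    p1 = s + span // 3
    p2 = s + 2 * span // 3
    while p1 in existing:
        p1 += 1
    while p2 in existing or p2 == p1:
        p2 += 1

    ped = Pedigree.default(config.n_children)
    rows = []
    for pos_, carrier, csq in (
        (p1, "father", "stop_gained"),
        (p2, "mother", "missense_variant"),
    ):
        gt = {s_: 1 for s_ in ped.children}
        gt[ped.father] = 1 if carrier == "father" else 0
        gt[ped.mother] = 1 if carrier == "mother" else 0
        g = np.array([[gt[s_]] for s_ in ped.samples])
        dp, nv = simulate_reads_and_genotypes(g, config, rng)
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + int(rng.integers(1, 4))) % 4
        row: dict = {
            "chrom": chrom,
            "pos": pos_,
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "filter": "PASS",
            "gene": config.causal_gene,
            "csq": csq,
            "spd": np.nan,
            "af": 0.0,
            "db": False,
            "artifact": False,
        }
        for i, s_ in enumerate(ped.samples):
            row[f"gt_{s_}"] = int(g[i, 0])
            row[f"dp_{s_}"] = int(dp[i, 0])
            row[f"nv_{s_}"] = int(nv[i, 0])
        rows.append(row)

    truth.causal = CausalPair(
        gene=config.causal_gene,
        chromosome=chrom,
        paternal_pos=p1,
        maternal_pos=p2,
        interval=(s, e),
    )
    return pd.concat([sites, pd.DataFrame(rows)], ignore_index=True)


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Simulate a family exome; retries with derived seeds when the planted
    causal pair cannot be placed (no IBD2 interval with >= 2 sites)."""
    last_err: Exception | None = None
    for attempt in range(config.max_plant_retries + 1):
        seed = (config.seed + 7919 * attempt) % 2**31
        try:
            fam = _simulate_once(config, seed)
        except _NoQualifyingInterval as err:
            log.warning(
                "no IBD2 interval with >=2 sites at seed %d (attempt %d); retrying",
                seed, attempt,
            )
            last_err = err
            continue
        if attempt:
            log.info("causal pair planted after %d retries (seed %d)", attempt, seed)
        return fam
    raise RuntimeError(
        f"could not plant the causal pair in {config.max_plant_retries + 1} attempts"
    ) from last_err


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_VCF_HEADER_META = """\
##fileformat=VCFv4.2
##source=ibd2scan-simulator
##FILTER=<ID=LowQual,Description="Site failed the simulated caller filter">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Predicted consequence">
##INFO=<ID=AF,Number=A,Type=Float,Description="Population alternate allele frequency">
##INFO=<ID=SPD,Number=1,Type=Integer,Description="Distance into intron from nearest exon (bp)">
##INFO=<ID=DB,Number=0,Type=Flag,Description="Present in a variant database">
##INFO=<ID=ARTIFACT,Number=0,Type=Flag,Description="Simulated mismapping artifact">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=NR,Number=1,Type=Integer,Description="Total reads covering the site">
##FORMAT=<ID=NV,Number=1,Type=Integer,Description="Reads supporting the alternate allele">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_outputs(
    fam: SimulatedFamily, out_dir: str | Path, basename: str = "family"
) -> dict[str, Path]:
    """Write the multi-sample VCF, truth IBD2 BED, and a JSON sidecar.

    Output is a pure function of (config, seed): identical inputs produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / f"{basename}.vcf",
        "truth_bed": out / f"{basename}.truth_ibd2.bed",
        "sidecar": out / f"{basename}.sidecar.json",
    }

    samples = fam.pedigree.samples
    lines = [_VCF_HEADER_META.rstrip("\n")]
    for chrom in sorted(fam.config.chromosome_lengths, key=natural_chrom_key):
        lines.append(
            f"##contig=<ID={chrom},length={fam.config.chromosome_lengths[chrom]}>"
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for row in fam.sites.itertuples(index=False):
        info = [f"GENE={row.gene}", f"CSQ={row.csq}", f"AF={row.af:.6f}"]
        if not np.isnan(row.spd):
            info.append(f"SPD={int(row.spd)}")
        if row.db:
            info.append("DB")
        if row.artifact:
            info.append("ARTIFACT")
        fields = [
            row.chrom, str(row.pos), ".", row.ref, row.alt, ".", row.filter,
            ";".join(info), "GT:NR:NV",
        ]
        for s in samples:
            gt = _GT_STR[getattr(row, f"gt_{s}")]
            fields.append(f"{gt}:{getattr(row, f'dp_{s}')}:{getattr(row, f'nv_{s}')}")
        lines.append("\t".join(fields))
    paths["vcf"].write_text("\n".join(lines) + "\n")

    bed_lines = []
    for chrom in sorted(fam.truth.ibd2_intervals, key=natural_chrom_key):
        for s, e in fam.truth.ibd2_intervals[chrom]:
            bed_lines.append(f"{chrom}\t{s - 1}\t{e}")
    paths["truth_bed"].write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))

    causal = fam.truth.causal
    sidecar = {
        "seed_used": fam.seed_used,
        "samples": list(samples),
        "causal_pair": None
        if causal is None
        else {
            "gene": causal.gene,
            "chromosome": causal.chromosome,
            "paternal_variant_pos": causal.paternal_pos,
            "maternal_variant_pos": causal.maternal_pos,
            "ibd2_interval": list(causal.interval),
        },
        "config": _jsonable(fam.config.to_dict()),
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
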