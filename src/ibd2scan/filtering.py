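"""Multi-sample VCF loading and pre-IBD filtering.

Reproduces the pre-mapping funnel used for allelic-ratio IBD analysis:
biallelic single-nucleotide substitutions flagged PASS, outside masked
regions (segmental duplications, repeat-masked sequence), with adequate
coverage in every affected sibling — followed by per-sample allelic ratios.

The in-memory container is a pandas DataFrame ("site table") with one row
per site and columns::

    chrom, pos (1-based), ref, alt, filter, gene, csq, spd, af, db, artifact,
    gt_<sample>, dp_<sample>, nv_<sample>   (per pedigree sample)

Genotypes are coded 0/1/2 = ALT-allele dose, -1 = missing; depths and alt
counts are -1 when the VCF field is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genome import natural_chrom_key
from .pedigree import Pedigree

log = logging.getLogger(__name__)

FILTER_STAGES = ("snv", "pass", "mask", "coverage")

_SNV_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

@dataclass
class MaskSet:
    """Named genomic interval masks (BED convention: 0-based, half-open).

    A 1-based variant position ``pos`` is masked iff ``start < pos <= end``
    for some interval — i.e. its single base lies inside the interval.
    Intervals are merged per chromosome at construction.
    """

    intervals: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> (k,2)
    names: tuple[str, ...] = ()

    @classmethod
    def from_bed_files(cls, paths: dict[str, str | Path] | list[str | Path]) -> "MaskSet":
        if isinstance(paths, (list, tuple)):
            paths = {Path(p).stem: p for p in paths}
        per_chrom: dict[str, list[np.ndarray]] = {}
        for _, path in sorted(paths.items()):
            bed = pd.read_csv(
                path, sep="\t", header=None, usecols=[0, 1, 2],
                names=["chrom", "start", "end"], comment="#",
                dtype={"chrom": str, "start": np.int64, "end": np.int64},
            )
            for chrom, grp in bed.groupby("chrom", sort=False):
                per_chrom.setdefault(str(chrom), []).append(
                    grp[["start", "end"]].to_numpy()
                )
        merged = {
            chrom: _merge_intervals(np.vstack(chunks))
            for chrom, chunks in per_chrom.items()
        }
        return cls(intervals=merged, names=tuple(sorted(paths)))

    def is_masked(self, chrom: str, pos: np.ndarray | int) -> np.ndarray | bool:
        """Vectorized membership test for 1-based positions on one chromosome."""
        iv = self.intervals.get(chrom)
        scalar = np.isscalar(pos)
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if iv is None or iv.size == 0:
            out = np.zeros(pos.shape, dtype=bool)
        else:
            # masked iff start < pos <= end for the interval preceding pos
            idx = np.searchsorted(iv[:, 0], pos - 1, side="right") - 1
            out = (idx >= 0) & (pos <= iv[np.clip(idx, 0, None), 1])
        return bool(out[0]) if scalar else out


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# VCF loading
# ---------------------------------------------------------------------------

def _detect_depth_dialect(vcf: VCF) -> str:
    """'NRNV' (total + variant reads) or 'AD' (per-allele depths)."""
    has = {h.info().get("ID") for h in vcf.header_iter() if h.type == "FORMAT"}
    if {"NR", "NV"} <= has:
        return "NRNV"
    if "AD" in has:
        return "AD"
    raise ValueError(
        "no supported per-sample depth dialect in VCF header "
        "(need FORMAT fields NR+NV or AD)"
    )


def load_variants(
    vcf_path: str | Path,
    pedigree: Pedigree,
    multiallelic: str = "exclude",
    dialect: str | None = None,
) -> pd.DataFrame:
    """Read a multi-sample VCF into a site table ordered by (chrom, pos).

    Per-sample depth fields are auto-detected (NR/NV or AD dialect) unless
    ``dialect`` is given.  ``multiallelic`` is "exclude" (drop records with
    more than one ALT, the default) or "keep" (retain the first ALT's counts).
    Unparseable per-sample fields become -1 (missing), never 0.
    """
    if multiallelic not in ("exclude", "keep"):
        raise ValueError("multiallelic must be 'exclude' or 'keep'")
    vcf = VCF(str(vcf_path), gts012=True)
    missing = [s for s in pedigree.samples if s not in vcf.samples]
    if missing:
        raise ValueError(
            f"pedigree sample(s) not in VCF header: {', '.join(missing)}"
        )
    dialect = dialect or _detect_depth_dialect(vcf)
    sample_idx = [vcf.samples.index(s) for s in pedigree.samples]

    rows: dict[str, list] = {
        k: [] for k in ("chrom", "pos", "ref", "alt", "filter", "gene",
                        "csq", "spd", "af", "db", "artifact")
    }
    gt_rows, dp_rows, nv_rows = [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            if multiallelic == "exclude":
                n_multi += 1
                continue
        rows["chrom"].append(v.CHROM)
        rows["pos"].append(v.POS)
        rows["ref"].append(v.REF)
        rows["alt"].append(v.ALT[0] if v.ALT else ".")
        rows["filter"].append(v.FILTER or "PASS")
        rows["gene"].append(v.INFO.get("GENE"))
        rows["csq"].append(v.INFO.get("CSQ"))
        spd = v.INFO.get("SPD")
        rows["spd"].append(np.nan if spd is None else float(spd))
        af = v.INFO.get("AF")
        rows["af"].append(np.nan if af is None else float(af))
        rows["db"].append(bool(v.INFO.get("DB")))
        rows["artifact"].append(bool(v.INFO.get("ARTIFACT")))

        gts = v.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt_rows.append([(-1 if gts[i] == 3 else int(gts[i])) for i in sample_idx])
        dp, nv = _extract_depths(v, dialect)
        dp_rows.append([dp[i] for i in sample_idx])
        nv_rows.append([nv[i] for i in sample_idx])
    if n_multi:
        log.info("excluded %d multiallelic record(s)", n_multi)

    df = pd.DataFrame(rows)
    df["pos"] = df["pos"].astype(np.int64)
    gt = np.array(gt_rows, dtype=np.int64).reshape(len(df), -1)
    dp = np.array(dp_rows, dtype=np.int64).reshape(len(df), -1)
    nv = np.array(nv_rows, dtype=np.int64).reshape(len(df), -1)
    for i, s in enumerate(pedigree.samples):
        df[f"gt_{s}"] = gt[:, i] if len(df) else np.array([], dtype=np.int64)
        df[f"dp_{s}"] = dp[:, i] if len(df) else np.array([], dtype=np.int64)
        df[f"nv_{s}"] = nv[:, i] if len(df) else np.array([], dtype=np.int64)
    key = df["chrom"].map(natural_chrom_key)
    df = (
        df.assign(_k=key)
        .sort_values(["_k", "pos"], kind="mergesort")
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    return df


def _extract_depths(v, dialect: str) -> tuple[list[int], list[int]]:
    def _col(arr):
        if arr is None:
            return None
        a = np.asarray(arr)
        return a.reshape(a.shape[0], -1)

    if dialect == "NRNV":
        nr, nv = _col(v.format("NR")), _col(v.format("NV"))
        n = len(v.gt_types)
        dp_out, nv_out = [], []
        for i in range(n):
            d = int(nr[i, 0]) if nr is not None else -1
            a = int(nv[i, 0]) if nv is not None else -1
            dp_out.append(d if d >= 0 else -1)
            nv_out.append(a if a >= 0 else -1)
        return dp_out, nv_out
    ad = _col(v.format("AD"))
    n = len(v.gt_types)
    dp_out, nv_out = [], []
    for i in range(n):
        if ad is None or ad.shape[1] < 2 or ad[i, 0] < 0:
            dp_out.append(-1)
            nv_out.append(-1)
        else:
            ref_d, alt_d = int(ad[i, 0]), int(ad[i, 1])
            dp_out.append(ref_d + max(alt_d, 0))
            nv_out.append(alt_d if alt_d >= 0 else -1)
    return dp_out, nv_out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def is_biallelic_snv(df: pd.DataFrame) -> pd.Series:
    return (
        df["ref"].str.len().eq(1)
        & df["alt"].str.len().eq(1)
        & df["ref"].isin(_SNV_BASES)
        & df["alt"].isin(_SNV_BASES)
    )


def filter_for_ibd(
    sites: pd.DataFrame,
    masks: MaskSet | None,
    pedigree: Pedigree,
    min_depth: int = 15,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four pre-IBD predicates; report per-stage attrition.

    Stages, in order: biallelic SNV; FILTER == PASS; outside every mask
    interval; depth >= ``min_depth`` in every affected child (a missing depth
    fails).  Each removed site is attributed to the first stage it fails, so
    the attrition counts sum to the input count.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    n = len(sites)
    fail_snv = ~is_biallelic_snv(sites)
    fail_pass = sites["filter"].ne("PASS")
    if masks is None:
        fail_mask = pd.Series(False, index=sites.index)
    else:
        fail_mask = pd.Series(False, index=sites.index)
        for chrom, grp in sites.groupby("chrom", sort=False):
            fail_mask.loc[grp.index] = masks.is_masked(
                str(chrom), grp["pos"].to_numpy()
            )
    fail_cov = pd.Series(False, index=sites.index)
    for child in pedigree.children:
        dp = sites[f"dp_{child}"]
        fail_cov |= (dp < min_depth) | dp.isna()

    stage = np.full(n, -1, dtype=np.int64)  # -1 = survivor
    for i, fail in enumerate([fail_snv, fail_pass, fail_mask, fail_cov]):
        stage = np.where((stage == -1) & fail.to_numpy(), i, stage)

    attrition = {"input": n}
    for i, name in enumerate(FILTER_STAGES):
        attrition[f"removed_{name}"] = int((stage == i).sum())
    survivors = sites.loc[stage == -1].reset_index(drop=True)
    attrition["survivors"] = len(survivors)
    if not len(survivors):
        log.warning("no variants survive the IBD pre-filter")
    return survivors, attrition


# ---------------------------------------------------------------------------
# allelic ratios and spacing
# ---------------------------------------------------------------------------

def allelic_ratio(alt_reads: float, depth: float) -> float:
    """Alt-read fraction; NaN when depth is zero/missing."""
    if depth is None or alt_reads is None or depth <= 0 or alt_reads < 0:
        return float("nan")
    return alt_reads / depth


def add_allelic_ratios(sites: pd.DataFrame, pedigree: Pedigree) -> pd.DataFrame:
    """Add an ``ar_<sample>`` column per pedigree sample (NaN where missing)."""
    out = sites.copy()
    for s in pedigree.samples:
        dp = out[f"dp_{s}"].to_numpy(dtype=float)
        nv = out[f"nv_{s}"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ar = np.where((dp > 0) & (nv >= 0), nv / np.where(dp > 0, dp, 1), np.nan)
        out[f"ar_{s}"] = ar
    return out


def median_spacing(sites: pd.DataFrame) -> float:
    """Median of successive intra-chromosome position gaps, pooled genome-wide."""
    gaps = [
        np.diff(np.sort(grp["pos"].to_numpy()))
        for _, grp in sites.groupby("chrom", sort=False)
        if len(grp) >= 2
    ]
    if not gaps:
        raise ValueError("median spacing undefined: no chromosome has >= 2 sites")
    return float(np.median(np.concatenate(gaps)))
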