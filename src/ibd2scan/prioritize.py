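"""Rare-deleterious variant prioritization under recessive inheritance models.

Implements the candidate funnel: rare (population AF below threshold)
predicted-deleterious variants, optionally restricted to IBD2 loci, then
tested for segregation under three models:

* compound heterozygous — two variants in one gene, each heterozygous in all
  affected children, with at least one inherited from each parent;
* simple recessive — homozygous-ALT in all affected children, heterozygous
  in both parents;
* shared de novo — heterozygous in all affected children, confidently
  absent from both parents (presumed parental germline mosaicism).

Phasing for the compound-het model is by parental origin only (a variant het
in the father and absent in the mother is paternal, and vice versa);
variants het in both parents cannot be assigned an origin and are listed as
"unphased" rather than silently dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .config import (
    PrioritizationParams,
    SPLICE_DISTANCE_CONSEQUENCES,
)
from .ibd import IBDRegion
from .pedigree import Pedigree

log = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Variants in one gene consistent with one inheritance model."""

    model: str  # compound_het | simple_recessive | shared_denovo
    gene: str
    variants: pd.DataFrame  # site-table rows plus an "origin" column

    @property
    def origins(self) -> list[str]:
        return list(self.variants["origin"])


# ---------------------------------------------------------------------------
# deleteriousness and rarity
# ---------------------------------------------------------------------------

def is_predicted_deleterious(
    consequence: str | None,
    params: PrioritizationParams | None = None,
    database_flag: bool = False,
    splice_distance: float | None = None,
) -> bool:
    """Whether a consequence term counts as predicted deleterious.

    True when the term is in the deleterious set; or when the term is
    intronic/splice-region and the annotated distance into the intron is at
    most ``max_splice_distance`` bases; or when the variant carries a
    database-membership flag and the params honor it.  Unannotated variants
    are never deleterious (callers should tally them).
    """
    params = params or PrioritizationParams()
    if database_flag and params.honor_database_flag:
        return True
    if consequence is None or (isinstance(consequence, float) and math.isnan(consequence)):
        return False
    if consequence in params.deleterious_consequences:
        return True
    if consequence in SPLICE_DISTANCE_CONSEQUENCES and splice_distance is not None:
        if not math.isnan(splice_distance) and splice_distance <= params.max_splice_distance:
            return True
    return False


def filter_rare_deleterious(
    sites: pd.DataFrame, params: PrioritizationParams | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rare (AF strictly below threshold) predicted-deleterious sites.

    Missing AF is treated as rare when ``missing_af_is_rare`` (discovery
    mode); unannotated consequences are counted and dropped.
    """
    params = params or PrioritizationParams()
    af = sites["af"]
    rare = af < params.max_allele_freq
    if params.missing_af_is_rare:
        rare |= af.isna()
    unannotated = sites["csq"].isna()
    deleterious = pd.Series(
        [
            is_predicted_deleterious(
                row.csq, params, database_flag=bool(row.db), splice_distance=row.spd
            )
            for row in sites[["csq", "db", "spd"]].itertuples(index=False)
        ],
        index=sites.index,
        dtype=bool,
    )
    keep = rare & deleterious
    counts = {
        "input": len(sites),
        "unannotated": int(unannotated.sum()),
        "rare": int(rare.sum()),
        "rare_deleterious": int(keep.sum()),
    }
    if counts["unannotated"]:
        log.info("%d site(s) lack a consequence annotation", counts["unannotated"])
    return sites.loc[keep].reset_index(drop=True), counts


def restrict_to_regions(
    sites: pd.DataFrame, regions: list[IBDRegion] | list[tuple[str, int, int]]
) -> pd.DataFrame:
    """Sites whose position lies within any region ([start, end], inclusive)."""
    if not regions:
        return sites.iloc[0:0].reset_index(drop=True)
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        if isinstance(r, IBDRegion):
            per_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        else:
            per_chrom.setdefault(r[0], []).append((int(r[1]), int(r[2])))
    keep = pd.Series(False, index=sites.index)
    for chrom, ivs in per_chrom.items():
        sel = sites["chrom"] == chrom
        if not sel.any():
            continue
        pos = sites.loc[sel, "pos"]
        inside = pd.Series(False, index=pos.index)
        for s, e in ivs:
            inside |= pos.between(s, e)
        keep.loc[pos.index] = inside
    return sites.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# segregation models
# ---------------------------------------------------------------------------

def _gt(sites: pd.DataFrame, sample: str) -> pd.Series:
    return sites[f"gt_{sample}"]


def _het_in_all_children(sites: pd.DataFrame, ped: Pedigree) -> pd.Series:
    out = pd.Series(True, index=sites.index)
    for c in ped.children:
        out &= _gt(sites, c).eq(1)
    return out


def assign_parental_origin(sites: pd.DataFrame, ped: Pedigree) -> pd.Series:
    """Parental origin of each variant: paternal, maternal, unphased, or none.

    paternal = het in father and hom-REF in mother; maternal = the converse;
    unphased = het in both parents (origin indeterminable without read-backed
    phasing); none = any other parental pattern.
    """
    f, m = _gt(sites, ped.father), _gt(sites, ped.mother)
    origin = pd.Series("none", index=sites.index)
    origin[f.eq(1) & m.eq(0)] = "paternal"
    origin[m.eq(1) & f.eq(0)] = "maternal"
    origin[f.eq(1) & m.eq(1)] = "unphased"
    return origin


def find_compound_het(sites: pd.DataFrame, ped: Pedigree) -> list[CandidateSet]:
    """Genes with >= 2 variants het in all children, covering both parental origins.

    Candidate variants must be heterozygous in every affected child and carry
    a determinable parental origin; a gene qualifies when at least one
    paternal and at least one maternal variant remain.  Unphased variants
    (het in both parents) are listed with the candidate but do not count
    toward either origin.
    """
    usable = sites.loc[sites["gene"].notna() & _het_in_all_children(sites, ped)].copy()
    if usable.empty:
        return []
    usable["origin"] = assign_parental_origin(usable, ped)
    usable = usable[usable["origin"].isin(["paternal", "maternal", "unphased"])]
    out = []
    for gene, grp in usable.groupby("gene", sort=True):
        origins = set(grp["origin"])
        if {"paternal", "maternal"} <= origins:
            out.append(
                CandidateSet(model="compound_het", gene=str(gene),
                             variants=grp.reset_index(drop=True))
            )
    return out


def find_simple_recessive(sites: pd.DataFrame, ped: Pedigree) -> list[CandidateSet]:
    """Variants homozygous-ALT in all affected children and het in both parents."""
    keep = pd.Series(True, index=sites.index)
    for c in ped.children:
        keep &= _gt(sites, c).eq(2)
    keep &= _gt(sites, ped.father).eq(1) & _gt(sites, ped.mother).eq(1)
    hits = sites.loc[keep].copy()
    hits["origin"] = "biparental"
    return [
        CandidateSet(model="simple_recessive",
                     gene=str(row_gene) if pd.notna(row_gene) else ".",
                     variants=grp.reset_index(drop=True))
        for row_gene, grp in hits.groupby("gene", sort=True, dropna=False)
    ]


def find_shared_denovo(
    sites: pd.DataFrame, ped: Pedigree, params: PrioritizationParams | None = None
) -> list[CandidateSet]:
    """Variants het in all affected children and confidently absent in both parents.

    A parental hom-REF call only counts when that parent's depth is at least
    ``min_parent_depth``; sites unevaluable in a parent are excluded and
    tallied in the log.
    """
    params = params or PrioritizationParams()
    keep = _het_in_all_children(sites, ped)
    evaluable = pd.Series(True, index=sites.index)
    for p in (ped.father, ped.mother):
        evaluable &= sites[f"dp_{p}"].ge(params.min_parent_depth)
        keep &= _gt(sites, p).eq(0)
    n_unevaluable = int((keep & ~evaluable).sum())
    if n_unevaluable:
        log.info(
            "%d de novo candidate(s) excluded: parental depth < %d",
            n_unevaluable, params.min_parent_depth,
        )
    hits = sites.loc[keep & evaluable].copy()
    hits["origin"] = "de_novo"
    return [
        CandidateSet(model="shared_denovo",
                     gene=str(row_gene) if pd.notna(row_gene) else ".",
                     variants=grp.reset_index(drop=True))
        for row_gene, grp in hits.groupby("gene", sort=True, dropna=False)
    ]


def run_models(
    sites: pd.DataFrame, ped: Pedigree, params: PrioritizationParams | None = None
) -> list[CandidateSet]:
    """All three inheritance models over one site table."""
    return (
        find_compound_het(sites, ped)
        + find_simple_recessive(sites, ped)
        + find_shared_denovo(sites, ped, params)
    )


def candidates_table(candidates: list[CandidateSet]) -> pd.DataFrame:
    """Flat TSV-ready table: one row per candidate variant."""
    rows = []
    for cand in candidates:
        for v in cand.variants.itertuples(index=False):
            rows.append(
                {
                    "model": cand.model,
                    "gene": cand.gene,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "csq": v.csq,
                    "af": v.af,
                    "origin": v.origin,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["model", "gene", "chrom", "pos", "ref", "alt", "csq", "af", "origin"],
    )
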