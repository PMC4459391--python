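"""End-to-end pipeline: filter -> pairwise differences -> IBD2 regions ->
summary -> prioritization, with reproducible, machine-readable outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import IBDCallParams, PrioritizationParams
from .filtering import (
    MaskSet,
    add_allelic_ratios,
    filter_for_ibd,
    load_variants,
    median_spacing,
)
from .genome import AUTOSOME_GENOME_SIZE, natural_chrom_key
from .ibd import (
    IBDRegion,
    call_ibd2_per_pair,
    intersect_pairs,
    pairwise_difference,
    plot_tracks,
    summarize_regions,
    write_region_outputs,
)
from .pedigree import Pedigree
from .prioritize import candidates_table, filter_rare_deleterious, restrict_to_regions, run_models

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    vcf: str
    out_dir: str
    pedigree: Pedigree
    mask_beds: list[str] = field(default_factory=list)
    min_child_depth: int = 15
    ibd_params: IBDCallParams = field(default_factory=IBDCallParams)
    prior_params: PrioritizationParams = field(default_factory=PrioritizationParams)
    autosome_size: int = AUTOSOME_GENOME_SIZE
    region_order: str = "natural"
    skip_ibd: bool = False
    make_plot: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        ped = raw.pop("pedigree")
        pedigree = Pedigree(
            father=ped["father"], mother=ped["mother"], children=tuple(ped["children"])
        )
        ibd = IBDCallParams(**raw.pop("ibd_params", {}))
        pri = PrioritizationParams(**raw.pop("prior_params", {}))
        return cls(pedigree=pedigree, ibd_params=ibd, prior_params=pri, **raw)

    def echo(self) -> dict:
        return {
            "vcf": self.vcf,
            "out_dir": self.out_dir,
            "pedigree": {
                "father": self.pedigree.father,
                "mother": self.pedigree.mother,
                "children": list(self.pedigree.children),
            },
            "mask_beds": list(self.mask_beds),
            "min_child_depth": self.min_child_depth,
            "ibd_params": self.ibd_params.to_dict(),
            "prior_params": self.prior_params.to_dict(),
            "autosome_size": self.autosome_size,
            "region_order": self.region_order,
            "skip_ibd": self.skip_ibd,
            "make_plot": self.make_plot,
        }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; write a report bundle; return the summary.

    Outputs in ``config.out_dir``: filtered site table, attrition report,
    IBD2 region BED + summary TSV, |delta ratio| track plot, candidate
    table, machine-readable ``summary.json``, and a verbatim config echo.
    Identical config + inputs produce byte-identical JSON.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.yaml").write_text(
        yaml.safe_dump(config.echo(), sort_keys=True)
    )

    ped = config.pedigree
    log.info("stage load: reading %s", config.vcf)
    sites = load_variants(config.vcf, ped)
    log.info("stage load: %d records", len(sites))

    masks = MaskSet.from_bed_files(config.mask_beds) if config.mask_beds else None
    filtered, attrition = filter_for_ibd(
        sites, masks, ped, min_depth=config.min_child_depth
    )
    for k, v in attrition.items():
        log.info("stage filter: %s=%d", k, v)
    pd.DataFrame([attrition]).T.rename(columns={0: "count"}).to_csv(
        out / "attrition.tsv", sep="\t", header=True
    )

    filtered = add_allelic_ratios(filtered, ped)
    filtered.to_csv(out / "filtered_sites.tsv", sep="\t", index=False, na_rep="NA")

    summary: dict = {
        "attrition": attrition,
        "n_samples": len(ped.samples),
        "pairs": [],
        "regions": [],
        "region_total_bp": 0,
        "region_percent_autosome": 0.0,
        "candidates": [],
    }
    if len(filtered) >= 2:
        summary["median_spacing_bp"] = median_spacing(filtered)

    regions: list[IBDRegion] = []
    if not config.skip_ibd and ped.n_children >= 2 and len(filtered):
        tracks = pairwise_difference(filtered, ped)
        summary["pairs"] = [t.name for t in tracks]
        per_pair = [call_ibd2_per_pair(t, config.ibd_params) for t in tracks]
        for t, regs in zip(tracks, per_pair):
            log.info("stage call: pair %s -> %d region(s)", t.name, len(regs))
        regions = intersect_pairs(per_pair, tracks, config.ibd_params)
        log.info("stage intersect: %d shared region(s)", len(regions))
        table = summarize_regions(
            regions, autosome_size=config.autosome_size, order=config.region_order
        )
        write_region_outputs(
            regions, out, autosome_size=config.autosome_size, order=config.region_order
        )
        summary["regions"] = [
            {
                "chrom": r.chrom,
                "start": int(r.start),
                "end": int(r.end),
                "size": int(r.size),
                "n_sites": int(r.n_sites),
            }
            for r in _ordered(regions, config.region_order)
        ]
        if len(table):
            summary["region_total_bp"] = int(table["cumulative_size"].iloc[-1])
            summary["region_percent_autosome"] = float(
                table["cumulative_percent"].iloc[-1]
            )
        if config.make_plot:
            plot_tracks(tracks, regions, out / "tracks.png")

    # prioritization funnel runs on all loaded sites (it has its own filters)
    rare, funnel = filter_rare_deleterious(sites, config.prior_params)
    summary["funnel"] = funnel
    if config.prior_params.restrict_to_regions and not config.skip_ibd:
        in_regions = restrict_to_regions(rare, regions)
        summary["funnel"]["rare_deleterious_in_ibd2"] = len(in_regions)
    else:
        in_regions = rare
    candidates = run_models(in_regions, ped, config.prior_params)
    ctable = candidates_table(candidates)
    ctable.to_csv(out / "candidates.tsv", sep="\t", index=False, na_rep="NA")
    summary["candidates"] = [
        {
            "model": c.model,
            "gene": c.gene,
            "n_variants": len(c.variants),
            "origins": c.origins,
        }
        for c in candidates
    ]
    log.info("stage prioritize: %d candidate set(s)", len(candidates))

    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
    )
    return summary


def _ordered(regions: list[IBDRegion], order: str) -> list[IBDRegion]:
    if order == "lexicographic":
        return sorted(regions, key=lambda r: (r.chrom, r.start))
    return sorted(regions, key=lambda r: (natural_chrom_key(r.chrom), r.start))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read a 3+ column BED into merged, sorted per-chromosome intervals."""
    per: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, s, e = line.split("\t")[:3]
        per.setdefault(chrom, []).append((int(s), int(e)))
    out = {}
    for chrom, ivs in per.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def _overlap_bp(a: np.ndarray, b: np.ndarray) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            total += e - s
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def evaluate_against_truth(
    called: dict[str, np.ndarray] | str | Path,
    truth: dict[str, np.ndarray] | str | Path,
    strict_namespace: bool = False,
) -> dict:
    """Base-pair sensitivity, precision and Jaccard of called vs truth intervals.

    Both inputs are BED paths or {chrom: (k,2) interval array} dicts in the
    0-based half-open convention.  With ``strict_namespace`` a chromosome
    present in only one input raises instead of counting as pure miss/false
    call.
    """
    if not isinstance(called, dict):
        called = read_bed(called)
    if not isinstance(truth, dict):
        truth = read_bed(truth)
    only_called = set(called) - set(truth)
    only_truth = set(truth) - set(called)
    if strict_namespace and (only_called or only_truth):
        raise ValueError(
            "chromosome namespace mismatch: "
            f"called-only={sorted(only_called)}, truth-only={sorted(only_truth)}"
        )
    per_chrom = {}
    tot_called = tot_truth = tot_overlap = 0
    empty = np.empty((0, 2), dtype=np.int64)
    for chrom in sorted(set(called) | set(truth), key=natural_chrom_key):
        a = called.get(chrom, empty)
        t = truth.get(chrom, empty)
        cbp = int((a[:, 1] - a[:, 0]).sum()) if len(a) else 0
        tbp = int((t[:, 1] - t[:, 0]).sum()) if len(t) else 0
        obp = _overlap_bp(a, t) if len(a) and len(t) else 0
        per_chrom[chrom] = {
            "called_bp": cbp,
            "truth_bp": tbp,
            "overlap_bp": obp,
        }
        tot_called += cbp
        tot_truth += tbp
        tot_overlap += obp
    union = tot_called + tot_truth - tot_overlap
    return {
        "sensitivity": tot_overlap / tot_truth if tot_truth else 0.0,
        "precision": tot_overlap / tot_called if tot_called else 0.0,
        "jaccard": tot_overlap / union if union else 0.0,
        "called_bp": tot_called,
        "truth_bp": tot_truth,
        "overlap_bp": tot_overlap,
        "per_chromosome": per_chrom,
    }
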