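"""IBD2 mapping from pairwise allelic-ratio differences.

For each unordered pair of affected siblings, the absolute difference of
alt-allele read fractions is computed at every filtered site.  Where the two
siblings inherited the same haplotype from both parents (IBD2) they have the
same genotype at every site, so |delta| scatters tightly around zero with
only binomial counting noise; elsewhere discordant genotypes push |delta|
toward 0.5 or 1.  Regions of IBD2 are called with a sliding-window rule on
the |delta| track, intersected across all sibling pairs, and summarized as a
region table with cumulative sizes and percent of the autosomal genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import IBDCallParams
from .genome import AUTOSOME_GENOME_SIZE, natural_chrom_key
from .pedigree import Pedigree

log = logging.getLogger(__name__)


@dataclass
class PairDifferenceTrack:
    """Per-site |allelic-ratio difference| for one sibling pair, genome-ordered."""

    pair: tuple[str, str]
    sites: pd.DataFrame  # columns: chrom, pos, absdiff (NaN allowed)

    @property
    def name(self) -> str:
        return f"{self.pair[0]}~{self.pair[1]}"


@dataclass
class IBDRegion:
    """A called IBD2 segment, bounded by its first/last supporting variants.

    ``start``/``end`` are the 1-based positions of the bounding variants;
    by convention the printed size is ``end - start``.
    """

    chrom: str
    start: int
    end: int
    n_sites: int = 0
    mean_absdiff: dict[str, float] = dc_field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.end - self.start


def pairwise_difference(
    sites: pd.DataFrame, pedigree: Pedigree
) -> list[PairDifferenceTrack]:
    """One |delta allelic ratio| track per unordered pair of affected siblings.

    ``sites`` must carry ``ar_<child>`` columns (see ``add_allelic_ratios``).
    |delta| is NaN wherever either sibling's ratio is missing.
    """
    if pedigree.n_children < 2:
        raise ValueError(
            "pairwise IBD2 analysis needs >= 2 affected children; "
            "run prioritization without region restriction instead"
        )
    tracks = []
    for a, b in pedigree.sibling_pairs():
        absdiff = (sites[f"ar_{a}"] - sites[f"ar_{b}"]).abs()
        tracks.append(
            PairDifferenceTrack(
                pair=(a, b),
                sites=pd.DataFrame(
                    {"chrom": sites["chrom"], "pos": sites["pos"], "absdiff": absdiff}
                ),
            )
        )
    return tracks


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[w:] - c[:-w]) / w


def call_ibd2_per_pair(
    track: PairDifferenceTrack, params: IBDCallParams | None = None
) -> list[IBDRegion]:
    """Call IBD2 regions on one pair's |delta| track.

    Sliding windows of ``window`` consecutive non-missing sites are IBD2
    candidates when the window mean |delta| < ``mean_threshold`` and the
    fraction of sites with |delta| > ``spike_cutoff`` is below
    ``max_spike_fraction``.  Candidate windows are merged when separated by
    at most ``merge_gap_bp``; merged regions are bounded by their first and
    last supporting variants and must meet the minimum size and site count.
    """
    params = params or IBDCallParams()
    w = params.window
    regions: list[IBDRegion] = []
    for chrom, grp in track.sites.groupby("chrom", sort=False):
        ok = grp["absdiff"].notna()
        d = grp.loc[ok, "absdiff"].to_numpy()
        pos = grp.loc[ok, "pos"].to_numpy()
        if d.size < w:
            log.debug("%s: %d usable sites < window %d, no calls", chrom, d.size, w)
            continue
        means = _moving_mean(d, w)
        spikes = _moving_mean((d > params.spike_cutoff).astype(float), w)
        cand = (means < params.mean_threshold) & (spikes < params.max_spike_fraction)
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            continue
        # candidate window i supports sites i .. i+w-1
        starts = pos[idx]
        ends = pos[idx + w - 1]
        merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] <= params.merge_gap_bp:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            inside = (pos >= s) & (pos <= e)
            region = IBDRegion(
                chrom=str(chrom),
                start=s,
                end=e,
                n_sites=int(inside.sum()),
                mean_absdiff={track.name: float(d[inside].mean())},
            )
            if region.size >= params.min_region_bp and region.n_sites >= params.min_sites:
                regions.append(region)
    return regions


def intersect_pairs(
    per_pair: list[list[IBDRegion]],
    tracks: list[PairDifferenceTrack] | None = None,
    params: IBDCallParams | None = None,
) -> list[IBDRegion]:
    """Regions called IBD2 in *every* sibling pair (interval intersection).

    Support statistics are pooled from ``tracks`` when given (per-pair mean
    |delta| inside each shared region; the site count is the minimum across
    pairs).  Minimum-size and minimum-site filters are re-applied.
    """
    if not per_pair:
        raise ValueError("need at least one pair's region list")
    params = params or IBDCallParams()
    shared = [
        (r.chrom, r.start, r.end) for r in per_pair[0]
    ]
    for regions in per_pair[1:]:
        other = [(r.chrom, r.start, r.end) for r in regions]
        shared = _intersect_interval_lists(shared, other)
    out: list[IBDRegion] = []
    for chrom, s, e in shared:
        region = IBDRegion(chrom=chrom, start=s, end=e)
        if tracks:
            counts = []
            for t in tracks:
                grp = t.sites[t.sites["chrom"] == chrom]
                ok = grp["absdiff"].notna()
                inside = ok & grp["pos"].between(s, e)
                counts.append(int(inside.sum()))
                if inside.any():
                    region.mean_absdiff[t.name] = float(
                        grp.loc[inside, "absdiff"].mean()
                    )
            region.n_sites = min(counts) if counts else 0
            if region.size < params.min_region_bp or region.n_sites < params.min_sites:
                continue
        elif region.size < params.min_region_bp:
            continue
        out.append(region)
    return out


def _intersect_interval_lists(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    out = []
    for chrom in sorted({c for c, _, _ in a} & {c for c, _, _ in b}, key=natural_chrom_key):
        ia = sorted((s, e) for c, s, e in a if c == chrom)
        ib = sorted((s, e) for c, s, e in b if c == chrom)
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if s < e:
                out.append((chrom, s, e))
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
    return out


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def summarize_regions(
    regions,
    autosome_size: int = AUTOSOME_GENOME_SIZE,
    order: str = "natural",
) -> pd.DataFrame:
    """Region table with sizes, cumulative sizes and cumulative % of autosome.

    ``regions`` is a list of IBDRegion or (chrom, start, end) tuples; size is
    ``end - start`` exactly; cumulative % = cumulative size / autosome_size *
    100, rounded to two decimals.  ``order`` is "natural" (chr1, chr2, ...,
    default), "lexicographic" (chr1, chr12, chr2, ... as some tools emit), or
    "given" (keep the caller's display order).
    """
    if autosome_size <= 0:
        raise ValueError("autosome_size must be positive")
    rows = []
    for r in regions:
        if isinstance(r, IBDRegion):
            rows.append((r.chrom, r.start, r.end, r.n_sites))
        else:
            chrom, s, e = r[:3]
            rows.append((chrom, int(s), int(e), None))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites"])
    if df.empty:
        df = df.astype(
            {"chrom": str, "start": np.int64, "end": np.int64, "n_sites": "float64"}
        )
    if order == "natural":
        df = df.sort_values(
            ["chrom", "start"],
            key=lambda col: col.map(natural_chrom_key) if col.name == "chrom" else col,
            kind="mergesort",
        ).reset_index(drop=True)
    elif order == "lexicographic":
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    elif order != "given":
        raise ValueError("order must be 'natural', 'lexicographic' or 'given'")
    df["size"] = df["end"] - df["start"]
    df["cumulative_size"] = df["size"].cumsum()
    df["cumulative_percent"] = (
        df["cumulative_size"] / autosome_size * 100.0
    ).round(2)
    if df["n_sites"].isna().all():
        df = df.drop(columns="n_sites")
    return df


def write_region_outputs(
    regions: list[IBDRegion],
    out_dir: str | Path,
    autosome_size: int = AUTOSOME_GENOME_SIZE,
    order: str = "natural",
    basename: str = "ibd2_regions",
) -> dict[str, Path]:
    """Write regions as BED (0-based half-open) and as a summary TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = summarize_regions(regions, autosome_size=autosome_size, order=order)
    bed_path = out / f"{basename}.bed"
    tsv_path = out / f"{basename}.tsv"
    with open(bed_path, "w") as fh:
        for row in table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\n")
    table.to_csv(tsv_path, sep="\t", index=False)
    return {"bed": bed_path, "tsv": tsv_path}


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_tracks(
    tracks: list[PairDifferenceTrack],
    regions: list[IBDRegion] | None,
    out_path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> Path:
    """Panel-per-pair plot of |delta allelic ratio| vs genome position, with
    called shared IBD2 regions shaded.  Deterministic for identical inputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not tracks:
        raise ValueError("need at least one track to plot")
    chroms = sorted(
        {c for t in tracks for c in t.sites["chrom"].unique()}, key=natural_chrom_key
    )
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(max(t.sites.loc[t.sites["chrom"] == c, "pos"].max() for t in tracks))
            for c in chroms
        }
    offsets, off = {}, 0
    for c in chroms:
        offsets[c] = off
        off += chrom_lengths.get(c, 0)

    fig, axes = plt.subplots(
        len(tracks), 1, figsize=(12, 2.2 * len(tracks)), sharex=True, squeeze=False
    )
    for ax, t in zip(axes[:, 0], tracks):
        x = t.sites["pos"].to_numpy() + t.sites["chrom"].map(offsets).to_numpy()
        ax.plot(x, t.sites["absdiff"], ".", ms=1, color="0.2", rasterized=True)
        for r in regions or []:
            if r.chrom in offsets:
                ax.axvspan(
                    offsets[r.chrom] + r.start,
                    offsets[r.chrom] + r.end,
                    color="tab:orange",
                    alpha=0.3,
                    lw=0,
                )
        ax.set_ylabel(f"|Δ ratio|\n{t.name}", fontsize=8)
        ax.set_ylim(-0.02, 1.02)
    for c in chroms[1:]:
        axes[-1, 0].axvline(offsets[c], color="0.8", lw=0.5)
    axes[-1, 0].set_xlabel("genome position (bp, chromosomes concatenated)")
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120, metadata=_stable_metadata(out_path.suffix))
    plt.close(fig)
    return out_path


def _stable_metadata(suffix: str) -> dict:
    if suffix.lower() == ".png":
        return {"Software": "ibd2scan"}
    if suffix.lower() == ".svg":
        return {"Date": None}
    return {}
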