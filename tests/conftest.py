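import numpy as np
import pandas as pd
import pytest

from ibd2scan import (
    Pedigree,
    SimulationConfig,
    scaled_lengths,
    simulate_family,
)
from ibd2scan.simulate import write_outputs


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 1/20-genome, three-sibling simulation used by many tests."""
    return SimulationConfig(chromosome_lengths=scaled_lengths(0.05), seed=3)


@pytest.fixture(scope="session")
def small_family(small_config):
    return simulate_family(small_config)


@pytest.fixture(scope="session")
def family_dir(tmp_path_factory, small_family):
    """The small family written out as VCF + truth BED + sidecar."""
    out = tmp_path_factory.mktemp("family")
    return write_outputs(small_family, out)


def make_site_table(
    records: list[dict], pedigree: Pedigree, fill: dict | None = None
) -> pd.DataFrame:
    """Build a site-table DataFrame from terse per-site dicts.

    Each record may give chrom, pos, ref, alt, filter, gene, csq, spd, af,
    db, artifact and per-sample gt/dp/nv as e.g. ``{"gt": {...}}`` maps;
    anything missing falls back to benign defaults (PASS SNV, depth 60).
    """
    fill = fill or {}
    rows = []
    for rec in records:
        row = {
            "chrom": rec.get("chrom", "chr1"),
            "pos": rec["pos"],
            "ref": rec.get("ref", "A"),
            "alt": rec.get("alt", "G"),
            "filter": rec.get("filter", "PASS"),
            "gene": rec.get("gene", "GENE1"),
            "csq": rec.get("csq", "missense_variant"),
            "spd": rec.get("spd", np.nan),
            "af": rec.get("af", 0.2),
            "db": rec.get("db", False),
            "artifact": rec.get("artifact", False),
        }
        for s in pedigree.samples:
            row[f"gt_{s}"] = rec.get("gt", fill.get("gt", {})).get(s, 1)
            row[f"dp_{s}"] = rec.get("dp", fill.get("dp", {})).get(s, 60)
            row[f"nv_{s}"] = rec.get("nv", fill.get("nv", {})).get(s, 30)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree.default(3)
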