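"""VCF loading, pre-IBD filters, allelic ratios, median spacing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ibd2scan import (
    MaskSet,
    Pedigree,
    SimulationConfig,
    add_allelic_ratios,
    allelic_ratio,
    filter_for_ibd,
    load_variants,
    median_spacing,
)
from ibd2scan.filtering import is_biallelic_snv
from ibd2scan.simulate import simulate_parental_haplotypes

from conftest import make_site_table

TRIO = Pedigree(father="F", mother="M", children=("C1", "C2"))


def _write_vcf(path, records, fmt="GT:NR:NV", samples=("F", "M", "C1", "C2")):
    header = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=LowQual,Description="x">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="x">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="x">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
        '##FORMAT=<ID=NR,Number=1,Type=Integer,Description="x">',
        '##FORMAT=<ID=NV,Number=1,Type=Integer,Description="x">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">',
        "##contig=<ID=chr1,length=100000000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines = header + [
        "\t".join([r[0], str(r[1]), ".", r[2], r[3], ".", r[4], r[5], fmt, *r[6:]])
        for r in records
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadVariants:
    def test_missing_pedigree_sample_raises_with_name(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "a.vcf",
            [("chr1", 100, "A", "G", "PASS", ".", *["0/1:30:15"] * 4)],
        )
        bad = Pedigree(father="F", mother="M", children=("C1", "NOPE"))
        with pytest.raises(ValueError, match="NOPE"):
            load_variants(vcf, bad)

    def test_ad_dialect_depths(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "ad.vcf",
            [
                ("chr1", 100, "A", "G", "PASS", ".", "0/1:20,10", "0/0:30,0",
                 "0/1:15,15", "1/1:0,40"),
            ],
            fmt="GT:AD",
        )
        # header declares both dialects; override auto-detection
        df = load_variants(vcf, TRIO, dialect="AD")
        assert df.loc[0, "dp_F"] == 30 and df.loc[0, "nv_F"] == 10
        assert df.loc[0, "dp_M"] == 30 and df.loc[0, "nv_M"] == 0
        assert df.loc[0, "dp_C2"] == 40 and df.loc[0, "nv_C2"] == 40
        assert df.loc[0, "gt_C2"] == 2

    def test_missing_per_sample_fields_become_missing_not_zero(self, tmp_path):
        vcf = _write_vcf(
            tmp_path / "m.vcf",
            [("chr1", 100, "A", "G", "PASS", ".", "0/1:30:15", "0/1:30:15",
              "./.:.:.", "0/1:30:15")],
        )
        df = load_variants(vcf, TRIO)
        assert df.loc[0, "gt_C1"] == -1
        assert df.loc[0, "dp_C1"] == -1
        # the coverage filter then removes the site
        surv, att = filter_for_ibd(df, None, TRIO)
        assert att["removed_coverage"] == 1 and len(surv) == 0

    def test_multiallelic_records_excluded_by_default(self, tmp_path):
        records = []
        for i in range(10):
            alt = "G,T" if i in (2, 7) else "G"
            records.append(
                ("chr1", 100 + i, "A", alt, "PASS", ".", *["0/1:30:15"] * 4)
            )
        vcf = _write_vcf(tmp_path / "multi.vcf", records)
        assert len(load_variants(vcf, TRIO)) == 8
        assert len(load_variants(vcf, TRIO, multiallelic="keep")) == 10

    def test_unsupported_depth_dialect_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF\tM\tC1\tC2\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t0/1\t0/1\n"
        )
        with pytest.raises(ValueError, match="depth dialect"):
            load_variants(path, TRIO)


def twenty_site_fixture():
    """20 sites with distinct single-stage failures: 5 non-PASS, 3 masked,
    2 indels, 2 low-depth in one child -> 8 survivors."""
    recs = []
    for i in range(20):
        rec = {"pos": 1000 * (i + 1)}
        if i < 5:
            rec["filter"] = "LowQual"
        elif i in (8, 9):
            rec["ref"] = "AT"  # indel
        elif i in (10, 11):
            rec["dp"] = {"C2": 14}
        recs.append(rec)
    # mask covers positions 6000-8000 (sites 5,6,7): BED half-open (5500, 8500)
    masks = MaskSet(intervals={"chr1": np.array([[5500, 8500]])}, names=("segdup",))
    return make_site_table(recs, TRIO), masks


class TestFilterForIbd:
    def test_twenty_site_fixture_attrition(self):
        sites, masks = twenty_site_fixture()
        surv, att = filter_for_ibd(sites, masks, TRIO, min_depth=15)
        assert att == {
            "input": 20,
            "removed_snv": 2,
            "removed_pass": 5,
            "removed_mask": 3,
            "removed_coverage": 2,
            "survivors": 8,
        }
        assert len(surv) == 8

    def test_brute_force_set_equivalence(self):
        # independent oracle: evaluate the four predicates per site in a loop
        sites, masks = twenty_site_fixture()
        surv, _ = filter_for_ibd(sites, masks, TRIO, min_depth=15)
        expected = set()
        for _, row in sites.iterrows():
            snv = len(row["ref"]) == 1 and len(row["alt"]) == 1
            passed = row["filter"] == "PASS"
            masked = 5500 < row["pos"] <= 8500
            covered = all(row[f"dp_{c}"] >= 15 for c in TRIO.children)
            if snv and passed and not masked and covered:
                expected.add(row["pos"])
        assert set(surv["pos"]) == expected

    def test_predicate_order_independence(self):
        # survivors equal the intersection of the four predicates applied
        # one at a time in any order
        sites, masks = twenty_site_fixture()
        surv, _ = filter_for_ibd(sites, masks, TRIO)
        preds = {
            "snv": is_biallelic_snv(sites),
            "pass": sites["filter"].eq("PASS"),
            "unmasked": ~pd.Series(
                masks.is_masked("chr1", sites["pos"].to_numpy()), index=sites.index
            ),
            "covered": pd.concat(
                [sites[f"dp_{c}"].ge(15) for c in TRIO.children], axis=1
            ).all(axis=1),
        }
        for perm in itertools.permutations(preds):
            step = sites
            for name in perm:
                step = step[preds[name].loc[step.index]]
            assert set(step["pos"]) == set(surv["pos"])

    def test_coverage_applies_to_children_only(self):
        sites = make_site_table([{"pos": 100, "dp": {"F": 2, "M": 2}}], TRIO)
        surv, _ = filter_for_ibd(sites, None, TRIO)
        assert len(surv) == 1  # parental depth never removes a site

    def test_site_at_depth_14_in_one_child_removed(self):
        sites = make_site_table([{"pos": 100, "dp": {"C1": 14}}], TRIO)
        _, att = filter_for_ibd(sites, None, TRIO, min_depth=15)
        assert att["removed_coverage"] == 1

    def test_empty_survivor_set_is_valid(self):
        sites = make_site_table([{"pos": 100, "filter": "LowQual"}], TRIO)
        surv, att = filter_for_ibd(sites, None, TRIO)
        assert len(surv) == 0 and att["survivors"] == 0


class TestMaskConventions:
    def test_bed_half_open_vs_one_based_positions(self):
        masks = MaskSet(intervals={"chr1": np.array([[10, 20]])})
        # BED (10,20) covers 0-based bases 10..19 = 1-based positions 11..20
        assert not masks.is_masked("chr1", 10)
        assert masks.is_masked("chr1", 11)
        assert masks.is_masked("chr1", 20)
        assert not masks.is_masked("chr1", 21)
        assert not masks.is_masked("chr2", 15)

    def test_bed_files_merged(self, tmp_path):
        bed1 = tmp_path / "segdup.bed"
        bed1.write_text("chr1\t100\t200\nchr1\t150\t300\n")
        bed2 = tmp_path / "rmsk.bed"
        bed2.write_text("chr1\t250\t400\nchr2\t0\t50\n")
        masks = MaskSet.from_bed_files([bed1, bed2])
        np.testing.assert_array_equal(masks.intervals["chr1"], [[100, 400]])
        np.testing.assert_array_equal(masks.intervals["chr2"], [[0, 50]])


class TestAllelicRatio:
    @pytest.mark.parametrize(
        "alt,depth,expected",
        [(0, 40, 0.0), (40, 40, 1.0), (21, 42, 0.5)],
    )
    def test_ratio_values(self, alt, depth, expected):
        assert allelic_ratio(alt, depth) == expected

    def test_zero_or_missing_depth_is_nan(self):
        assert math.isnan(allelic_ratio(0, 0))
        assert math.isnan(allelic_ratio(-1, -1))

    def test_hom_ref_ratio_converges_to_error_rate(self, small_family):
        fam = small_family
        ped = fam.pedigree
        df = add_allelic_ratios(fam.sites, ped)
        child = ped.children[0]
        hom_ref = df[df[f"gt_{child}"] == 0]
        mean = hom_ref[f"ar_{child}"].dropna().mean()
        assert abs(mean - fam.config.base_error_rate) < 0.002


class TestMedianSpacing:
    def test_single_chromosome(self):
        sites = make_site_table([{"pos": p} for p in (100, 200, 400)], TRIO)
        assert median_spacing(sites) == 150

    def test_pooled_across_chromosomes(self):
        recs = [
            {"chrom": "chr1", "pos": 10}, {"chrom": "chr1", "pos": 20},
            {"chrom": "chr2", "pos": 100}, {"chrom": "chr2", "pos": 130},
        ]
        assert median_spacing(make_site_table(recs, TRIO)) == 20

    def test_undefined_without_two_sites_anywhere(self):
        with pytest.raises(ValueError, match="undefined"):
            median_spacing(make_site_table([{"pos": 100}], TRIO))

    def test_poisson_process_median_matches_exponential_closed_form(self):
        # gaps are Exponential(mean=spacing): median = spacing * ln 2
        cfg = SimulationConfig(
            chromosome_lengths={"chrA": 60_000_000}, seed=13, plant_causal=False
        )
        haps = simulate_parental_haplotypes(cfg)
        gaps = np.diff(haps["chrA"].positions)
        assert abs(np.median(gaps) - 5400 * np.log(2)) / (5400 * np.log(2)) < 0.1
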