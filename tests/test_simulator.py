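"""Simulator: haplotypes, meioses, read model, planted causal pair, output."""

import numpy as np
import pytest

from ibd2scan import (
    AlleleFrequencyModel,
    SimulationConfig,
    load_variants,
    simulate_family,
)
from ibd2scan.simulate import (
    build_inheritance_vector,
    pair_label_agreement_fraction,
    simulate_inheritance,
    simulate_meiosis,
    simulate_parental_haplotypes,
    simulate_reads_and_genotypes,
    write_outputs,
)

ONE_MB = {"chrA": 1_000_000}


def test_config_rejects_chromosome_shorter_than_spacing():
    with pytest.raises(ValueError, match="shorter than one"):
        SimulationConfig(chromosome_lengths={"tiny": 1000}, variant_spacing_bp=5400)


class TestParentalHaplotypes:
    def test_site_count_matches_poisson_expectation(self):
        cfg = SimulationConfig(chromosome_lengths=ONE_MB, seed=11, plant_causal=False)
        haps = simulate_parental_haplotypes(cfg)
        n = haps["chrA"].positions.size
        # ~185 expected; allow 4 sigma of Poisson noise
        assert abs(n - 185) < 4 * np.sqrt(185)
        assert np.all(np.diff(haps["chrA"].positions) > 0)
        assert haps["chrA"].positions[0] >= 1
        assert haps["chrA"].positions[-1] <= 1_000_000

    def test_degenerate_frequency_zero_gives_all_ref_haplotypes(self):
        cfg = SimulationConfig(
            chromosome_lengths=ONE_MB,
            allele_freq_distribution=AlleleFrequencyModel(fixed=0.0),
            seed=1,
            plant_causal=False,
        )
        haps = simulate_parental_haplotypes(cfg)
        assert not haps["chrA"].alleles.any()

    def test_same_seed_reproduces_haplotypes(self):
        cfg = SimulationConfig(chromosome_lengths=ONE_MB, seed=7, plant_causal=False)
        a = simulate_parental_haplotypes(cfg)
        b = simulate_parental_haplotypes(cfg)
        np.testing.assert_array_equal(a["chrA"].positions, b["chrA"].positions)
        np.testing.assert_array_equal(a["chrA"].alleles, b["chrA"].alleles)


class TestMeiosis:
    def test_zero_crossover_rate_transmits_one_parent_haplotype(self):
        rng = np.random.default_rng(0)
        bps, start = simulate_meiosis(250_000_000, 0.0, rng)
        assert bps.size == 0
        assert start in (0, 1)

    def test_crossover_count_has_poisson_mean(self):
        rng = np.random.default_rng(0)
        counts = [simulate_meiosis(250_000_000, 1e-8, rng)[0].size for _ in range(2000)]
        se = np.sqrt(2.5 / 2000)
        assert abs(np.mean(counts) - 2.5) < 4 * se

    def test_siblings_share_paternal_haplotype_half_the_genome(self):
        # independent-oracle check: label agreement measured directly along
        # the inheritance vectors of many simulated sibling pairs
        rng = np.random.default_rng(42)
        length, rate = 100_000_000, 2e-8
        fracs = []
        for _ in range(400):
            vecs = []
            for child in ("s1", "s2"):
                pat = simulate_meiosis(length, rate, rng)
                mat = simulate_meiosis(length, rate, rng)
                vecs.append(build_inheritance_vector(child, "c", length, pat, mat))
            fracs.append(pair_label_agreement_fraction(*vecs, lineage="paternal"))
        assert abs(np.mean(fracs) - 0.5) < 0.04

    def test_inheritance_vector_invariants(self):
        rng = np.random.default_rng(5)
        length = 200_000_000
        for _ in range(50):
            vec = build_inheritance_vector(
                "c1", "chr1", length,
                simulate_meiosis(length, 3e-8, rng),
                simulate_meiosis(length, 3e-8, rng),
            )
            bps = np.array(vec.breakpoints)
            assert np.all(np.diff(bps) > 0)
            assert bps.size == 0 or (bps[0] >= 1 and bps[-1] <= length)
            assert len(vec.labels) == bps.size + 1
            for prev, cur in zip(vec.labels, vec.labels[1:]):
                # exactly one of the (paternal, maternal) labels flips
                assert (prev[0] != cur[0]) + (prev[1] != cur[1]) == 1


@pytest.fixture(scope="module")
def truth():
    cfg = SimulationConfig(seed=9, plant_causal=False)
    return simulate_inheritance(cfg), cfg


class TestTruthIntervals:
    def test_ibd2_intervals_match_pointwise_label_oracle(self, truth):
        ts, cfg = truth
        for chrom, length in cfg.chromosome_lengths.items():
            vecs = list(ts.vectors[chrom].values())
            ivs = ts.ibd2_intervals[chrom]
            probes = np.linspace(1, length, 300).astype(int)
            for p in probes:
                labels = {v.label_at(int(p)) for v in vecs}
                in_interval = any(s <= p <= e for s, e in ivs)
                assert in_interval == (len(labels) == 1)

    def test_intervals_sorted_disjoint_and_maximal(self, truth):
        ts, _ = truth
        for ivs in ts.ibd2_intervals.values():
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 < s2 - 1  # gap > 0, else they would have merged
                assert s1 <= e1 and s2 <= e2

    def test_label_agreement_is_transitive(self, truth):
        ts, cfg = truth
        for chrom, length in cfg.chromosome_lengths.items():
            v1, v2, v3 = list(ts.vectors[chrom].values())
            for p in np.linspace(1, length, 100).astype(int):
                a, b, c = v1.label_at(int(p)), v2.label_at(int(p)), v3.label_at(int(p))
                if a == b and b == c:
                    assert a == c


class TestReadModel:
    def test_depth_mean_within_two_percent(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(1)
        g = np.zeros((1, 20_000), dtype=np.int64)
        dp, _ = simulate_reads_and_genotypes(g, cfg, rng)
        assert abs(dp.mean() - cfg.mean_depth) / cfg.mean_depth < 0.02

    def test_hom_ref_alt_fraction_near_error_rate(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(2)
        g = np.zeros((1, 20_000), dtype=np.int64)
        dp, nv = simulate_reads_and_genotypes(g, cfg, rng)
        ratio = nv[dp > 0] / dp[dp > 0]
        assert abs(ratio.mean() - cfg.base_error_rate) < 0.002

    def test_het_alt_fraction_centred_on_half(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(3)
        g = np.ones((1, 20_000), dtype=np.int64)
        dp, nv = simulate_reads_and_genotypes(g, cfg, rng)
        assert abs((nv[dp > 0] / dp[dp > 0]).mean() - 0.5) < 0.005

    def test_default_dispersion_keeps_coverage_filter_nondegenerate(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(4)
        dp, _ = simulate_reads_and_genotypes(
            np.ones((1, 20_000), dtype=np.int64), cfg, rng
        )
        assert (dp > 15).mean() >= 0.90


class TestPlantedPair:
    def test_planted_genotypes_and_annotations(self, small_family):
        fam = small_family
        causal = fam.truth.causal
        assert causal is not None
        ped = fam.pedigree
        sites = fam.sites
        pat = sites[(sites["chrom"] == causal.chromosome) & (sites["pos"] == causal.paternal_pos)].iloc[0]
        mat = sites[(sites["chrom"] == causal.chromosome) & (sites["pos"] == causal.maternal_pos)].iloc[0]
        assert pat["csq"] == "stop_gained" and mat["csq"] == "missense_variant"
        assert pat["af"] == 0.0 and mat["af"] == 0.0
        assert pat[f"gt_{ped.father}"] == 1 and pat[f"gt_{ped.mother}"] == 0
        assert mat[f"gt_{ped.mother}"] == 1 and mat[f"gt_{ped.father}"] == 0
        for c in ped.children:
            assert pat[f"gt_{c}"] == 1 and mat[f"gt_{c}"] == 1
        s, e = causal.interval
        assert s <= causal.paternal_pos <= e and s <= causal.maternal_pos <= e
        assert (s, e) in [
            tuple(iv) for iv in fam.truth.ibd2_intervals[causal.chromosome]
        ]

    def test_planting_with_single_child_spans_whole_genome_ibd2(self):
        cfg = SimulationConfig(
            chromosome_lengths={"chrA": 2_000_000}, n_children=1, seed=2
        )
        fam = simulate_family(cfg)
        assert fam.truth.causal is not None
        assert fam.truth.ibd2_intervals["chrA"] == [(1, 2_000_000)]


class TestOutputs:
    def test_vcf_round_trip_reproduces_site_table(self, small_family, family_dir):
        fam = small_family
        df = load_variants(family_dir["vcf"], fam.pedigree)
        a = fam.sites.reset_index(drop=True)
        assert len(a) == len(df)
        for col in ("chrom", "pos", "ref", "alt", "filter", "gene", "csq"):
            assert (a[col].astype(str) == df[col].astype(str)).all()
        for s in fam.pedigree.samples:
            for p in ("gt", "dp", "nv"):
                np.testing.assert_array_equal(a[f"{p}_{s}"], df[f"{p}_{s}"])
        # AF is serialized to 6 decimals and parsed back as float32
        np.testing.assert_allclose(a["af"], df["af"], atol=1e-6)

    def test_truth_bed_sorted_and_nonoverlapping(self, family_dir):
        last = {}
        for line in family_dir["truth_bed"].read_text().splitlines():
            chrom, s, e = line.split("\t")
            s, e = int(s), int(e)
            assert s < e
            if chrom in last:
                assert s >= last[chrom]
            last[chrom] = e

    def test_identical_seed_gives_byte_identical_outputs(self, tmp_path):
        from ibd2scan import scaled_lengths

        cfg = SimulationConfig(chromosome_lengths=scaled_lengths(0.02), seed=7)
        p1 = write_outputs(simulate_family(cfg), tmp_path / "a")
        p2 = write_outputs(simulate_family(cfg), tmp_path / "b")
        for key in ("vcf", "truth_bed", "sidecar"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_pass_rate_one_flags_every_record_pass(self, tmp_path):
        cfg = SimulationConfig(
            chromosome_lengths={"chrA": 2_000_000}, pass_rate=1.0, seed=5
        )
        fam = simulate_family(cfg)
        assert (fam.sites["filter"] == "PASS").all()
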