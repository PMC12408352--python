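"""Forward simulator: variant placement, linkage model, read sampling."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import bsascan as b
from bsascan.simulate import EMS_PAIRS, simulate_population


def _config(**kw):
    defaults = dict(chrom_lengths={"chr1": 10_000_000}, seed=1)
    defaults.update(kw)
    return b.SimConfig(**defaults)


DESIGN = b.CrossDesign(causal_chrom="chr1", causal_pos=5_000_000)


class TestPlaceVariants:
    def test_zero_density_leaves_only_the_causal_site(self):
        variants = b.place_variants(_config(variant_density=0.0), DESIGN)
        assert variants == [("chr1", 5_000_000, "G", "A")]

    def test_degenerate_ems_fraction_gives_pure_transition_spectrum(self):
        variants = b.place_variants(_config(ems_gc_to_at_fraction=1.0), DESIGN)
        assert len(variants) > 50
        assert all((ref, alt) in EMS_PAIRS for _, _, ref, alt in variants)

    def test_positions_unique_sorted_and_in_range(self):
        variants = b.place_variants(_config(seed=3), DESIGN)
        keys = [(c, p) for c, p, _, _ in variants]
        assert keys == sorted(keys) and len(set(keys)) == len(keys)
        assert all(1 <= p <= 10_000_000 for _, p, _, _ in variants)

    def test_poisson_mean_count(self):
        """Mean variant count over 200 seeds ~ Poisson(density x length) = 200."""
        counts = [
            len(b.place_variants(_config(seed=s), DESIGN)) - 1  # minus forced causal
            for s in range(200)
        ]
        se = math.sqrt(200 / 200)  # sd of Poisson(200) mean over 200 reps
        assert abs(np.mean(counts) - 200) < 3 * se

    def test_overcrowded_genome_is_fatal(self):
        cfg = b.SimConfig(chrom_lengths={"chr1": 10}, variant_density=2.0, seed=0)
        des = b.CrossDesign(causal_chrom="chr1", causal_pos=5)
        with pytest.raises(ValueError, match="duplicates"):
            b.place_variants(cfg, des)


class TestRecombFraction:
    def test_map_function_limits(self):
        assert b.recomb_fraction(0, 4.0) == 0.0
        assert b.recomb_fraction(math.inf, 4.0) == 0.5
        assert b.recomb_fraction(10**12, 4.0) == pytest.approx(0.5, abs=1e-12)

    def test_haldane_closed_form(self):
        # 25 Mb at 0.4 cM/Mb = 0.1 Morgan -> r = (1 - e^-0.2)/2
        assert b.recomb_fraction(25_000_000, 0.4) == pytest.approx(0.5 * (1 - math.exp(-0.2)))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            b.recomb_fraction(-1, 4.0)


class TestSimulatePopulation:
    def test_causal_site_fixed_in_mutant_bulk(self):
        cfg = _config(variant_density=0.0)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth = simulate_population(DESIGN, b.place_variants(cfg, DESIGN), cfg, rng)
            assert truth.loc[truth.is_causal, "f_mut"].item() == 1.0

    def test_wt_bulk_frequency_at_causal_is_one_third(self):
        """WT-phenotype class is 1 AA : 2 Aa, so E[f_wt] = 1/3 at the causal site."""
        cfg = _config(variant_density=0.0)
        variants = b.place_variants(cfg, DESIGN)
        vals = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            vals.append(simulate_population(DESIGN, variants, cfg, rng)["f_wt"].item())
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1 / 3) < 3 * se

    def test_unlinked_sites_have_half_frequency_in_both_pools(self):
        cfg = b.SimConfig(
            chrom_lengths={"chr1": 1000, "chr2": 1000}, variant_density=0.0, seed=0
        )
        des = b.CrossDesign(causal_chrom="chr2", causal_pos=500)
        variants = [("chr1", 500, "G", "A")]
        fm, fw = [], []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            t = simulate_population(des, variants, cfg, rng)
            assert t["recomb_fraction"].item() == 0.5
            fm.append(t["f_mut"].item())
            fw.append(t["f_wt"].item())
        for vals in (fm, fw):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - 0.5) < 3 * se

    def test_frequencies_within_unit_interval(self, causal_dataset):
        _, _, _, truth = causal_dataset
        assert truth["f_mut"].between(0, 1).all()
        assert truth["f_wt"].between(0, 1).all()
        assert truth["recomb_fraction"].between(0, 0.5).all()

    def test_monotone_linkage_decay(self):
        """E[f_mut] decays with distance from the causal locus (Spearman <= 0)."""
        cfg = b.SimConfig(chrom_lengths={"chr1": 40_000_000}, variant_density=0.0, seed=0)
        des = b.CrossDesign(causal_chrom="chr1", causal_pos=1)
        dists = [0, 1, 2, 4, 8, 16, 32]  # Mb
        variants = [("chr1", 1 + d * 10**6, "G", "A") for d in dists]
        sums = np.zeros(len(dists))
        for seed in range(200):
            rng = np.random.default_rng(seed)
            sums += simulate_population(des, variants, cfg, rng)["f_mut"].to_numpy()
        rho = sps.spearmanr(dists, sums).statistic
        assert rho <= 0


class TestSimulateReads:
    def test_zero_depth_mean_gives_empty_counts(self, rng):
        cfg = _config(depth_mean=0.0, variant_density=0.0)
        truth = simulate_population(DESIGN, b.place_variants(cfg, DESIGN), cfg, rng)
        (site,) = b.simulate_reads(truth, cfg, rng)
        assert site.mut_depth == 0 and site.wt_depth == 0

    def test_fixed_frequency_without_error_gives_pure_alt_reads(self, rng):
        cfg = _config(error_rate=0.0, variant_density=0.0)
        truth = simulate_population(DESIGN, b.place_variants(cfg, DESIGN), cfg, rng)
        (site,) = b.simulate_reads(truth, cfg, rng)  # causal: f_mut = 1
        assert site.mut_ref == 0 and site.mut_alt == site.mut_depth

    def test_binomial_sampling_mean(self, rng):
        """At f = 1/2 the mean SNP index over many sites is 1/2."""
        import pandas as pd

        n = 10_000
        truth = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, n + 1),
                "ref": "G",
                "alt": "A",
                "distance_morgans": np.inf,
                "recomb_fraction": 0.5,
                "f_mut": 0.5,
                "f_wt": 0.5,
                "is_causal": False,
            }
        )
        sites = b.simulate_reads(truth, _config(error_rate=0.0), rng)
        idx = np.array([s.mut_alt / s.mut_depth for s in sites if s.mut_depth > 0])
        se = idx.std(ddof=1) / np.sqrt(idx.size)
        assert abs(idx.mean() - 0.5) < 3 * se


class TestGenerateDataset:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = b.SimConfig(chrom_lengths={"chr1": 2_000_000}, seed=9)
        des = b.CrossDesign(causal_chrom="chr1", causal_pos=1_000_000)
        p1 = b.generate_dataset(des, cfg, tmp_path / "run_a", write_vcf=True)
        p2 = b.generate_dataset(des, cfg, tmp_path / "run_b", write_vcf=True)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        des = b.CrossDesign(causal_chrom="chr1", causal_pos=1_000_000)
        p1 = b.generate_dataset(
            des, b.SimConfig(chrom_lengths={"chr1": 2_000_000}, seed=1), tmp_path / "a"
        )
        p2 = b.generate_dataset(
            des, b.SimConfig(chrom_lengths={"chr1": 2_000_000}, seed=2), tmp_path / "b"
        )
        assert p1["variants"].read_bytes() != p2["variants"].read_bytes()

    def test_truth_contains_exactly_one_causal_row_fixed_in_mut_pool(self, tmp_path):
        import pandas as pd

        cfg = b.SimConfig(chrom_lengths={"chr1": 2_000_000}, seed=3)
        des = b.CrossDesign(causal_chrom="chr1", causal_pos=1_000_000)
        paths = b.generate_dataset(des, cfg, tmp_path / "d")
        truth = pd.read_csv(paths["truth"], sep="\t")
        causal = truth[truth.is_causal == 1]
        assert len(causal) == 1
        assert causal["f_mut"].item() == 1.0

    def test_vcf_output_round_trips_through_the_vcf_reader(self, tmp_path):
        cfg = b.SimConfig(chrom_lengths={"chr1": 2_000_000}, seed=4)
        des = b.CrossDesign(causal_chrom="chr1", causal_pos=1_000_000)
        paths = b.generate_dataset(des, cfg, tmp_path / "d", write_vcf=True)
        from_tsv = b.read_variants_tsv(paths["variants"])
        from_vcf, skipped = b.read_variants_vcf(paths["vcf"], "mut_pool", "wt_pool")
        assert sum(skipped.values()) == 0
        assert [
            (s.chrom, s.pos, s.ref, s.alt, s.mut_ref, s.mut_alt, s.wt_ref, s.wt_alt)
            for s in from_vcf
        ] == [
            (s.chrom, s.pos, s.ref, s.alt, s.mut_ref, s.mut_alt, s.wt_ref, s.wt_alt)
            for s in from_tsv
        ]


def test_invalid_design_and_config_rejected():
    with pytest.raises(ValueError):
        b.CrossDesign(causal_chrom="c", causal_pos=1, mut_bulk_size=0)
    with pytest.raises(ValueError):
        b.CrossDesign(causal_chrom="c", causal_pos=1, segregation_model="BACKCROSS")
    with pytest.raises(ValueError):
        b.SimConfig(chrom_lengths={})
    with pytest.raises(ValueError):
        b.SimConfig(chrom_lengths={"c": 100}, ems_gc_to_at_fraction=1.5)
    with pytest.raises(ValueError):
        b.place_variants(
            b.SimConfig(chrom_lengths={"c": 100}),
            b.CrossDesign(causal_chrom="c", causal_pos=500),
        )
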