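"""Synthetic study generator: determinism, generative structure, truth."""
import numpy as np
import pandas as pd
import pytest

from mscc.quant import CONTROL, SPIKEIN_FRACTIONS, TREATED
from mscc.simulate import (
    ConfigError,
    SimulationConfig,
    simulate_dataset,
    simulate_genome,
    simulate_methylome,
    simulate_site_counts,
)

SMALL = dict(n_chrom=2, chrom_length=300_000, n_genes=40, n_islands=20, n_sites=800)


class TestConfig:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(de_fraction=1.5)

    def test_infeasible_density_rejected(self):
        with pytest.raises(ConfigError, match="base pairs"):
            SimulationConfig(n_chrom=1, chrom_length=100, n_sites=200, n_genes=1,
                             n_islands=1)


class TestGenome:
    def test_deterministic_under_fixed_seed(self):
        a1, s1 = simulate_genome(SimulationConfig(seed=1, **SMALL))
        a2, s2 = simulate_genome(SimulationConfig(seed=1, **SMALL))
        assert s1 == s2
        assert a1.genes == a2.genes and a1.islands == a2.islands

    def test_seed_changes_outputs(self):
        _, s1 = simulate_genome(SimulationConfig(seed=1, **SMALL))
        _, s2 = simulate_genome(SimulationConfig(seed=2, **SMALL))
        assert s1 != s2

    def test_no_islands_means_no_island_sites(self):
        cfg = SimulationConfig(seed=3, **{**SMALL, "n_islands": 0})
        ann, sites = simulate_genome(cfg)
        assert not any(ann.site_in_island(s) for s in sites)

    def test_unique_positions_and_tss(self):
        ann, sites = simulate_genome(SimulationConfig(seed=5, **SMALL))
        assert len({(s.chrom, s.pos) for s in sites}) == len(sites)
        tss = [(g.chrom, g.tss) for g in ann.genes]
        assert len(set(tss)) == len(tss)

    def test_island_density_ratio_matches_configuration(self):
        """Observed in-island site share within 3 binomial SD of the
        configured generative probability at n_sites = 10^4."""
        cfg = SimulationConfig(
            seed=11, n_chrom=2, chrom_length=1_000_000, n_genes=50,
            n_islands=60, n_sites=10_000, island_site_density_ratio=5.0,
        )
        ann, sites = simulate_genome(cfg)
        # recompute the generative probability from the realized island union
        union_bp = 0
        for chrom in ann.chromosomes:
            ivs = sorted(
                (i.start, i.end) for i in ann.islands if i.chrom == chrom
            )
            last = -1
            for s, e in ivs:
                s = max(s, last)
                if e > s:
                    union_bp += e - s
                    last = e
        total_bp = sum(ann.chromosomes.values())
        r = cfg.island_site_density_ratio
        p = r * union_bp / (r * union_bp + (total_bp - union_bp))
        n_in = sum(ann.site_in_island(s) for s in sites)
        sd = np.sqrt(len(sites) * p * (1 - p))
        assert abs(n_in - len(sites) * p) <= 3 * sd

    def test_promoter_site_boost_guarantees_sites(self):
        cfg = SimulationConfig(seed=7, promoter_site_boost=5, **SMALL)
        ann, sites = simulate_genome(cfg)
        pos = {(s.chrom, s.pos) for s in sites}
        for g in ann.genes:
            w = ann.promoter_window(g)
            n = sum(1 for c, p in pos if c == w.chrom and w.start <= p < w.end)
            assert n >= 5


class TestMethylome:
    def _base(self, **over):
        cfg = SimulationConfig(seed=13, **{**SMALL, **over})
        rng = np.random.default_rng(cfg.seed)
        ann, sites = simulate_genome(cfg, rng)
        return cfg, rng, ann, sites

    def test_zero_shift_zero_noise_identical_conditions(self):
        cfg, rng, ann, sites = self._base(shift_size=0.0, noise_sd=0.0,
                                          fraction_of_promoters_shifted=1.0)
        truth = simulate_methylome(ann, sites, cfg, rng)
        assert np.array_equal(
            truth.sites["m_control"].to_numpy(), truth.sites["m_treated"].to_numpy()
        )

    def test_shift_arithmetic_and_clamp(self):
        cfg, rng, ann, sites = self._base(shift_size=-0.4, noise_sd=0.0,
                                          fraction_of_promoters_shifted=1.0)
        truth = simulate_methylome(ann, sites, cfg, rng)
        shifted = truth.sites[truth.sites["shifted"]]
        assert len(shifted) > 0
        expected = np.clip(shifted["m_control"] - 0.4, 0.0, 1.0)
        assert np.allclose(shifted["m_treated"], expected)

    def test_island_sites_hypomethylated_at_baseline(self):
        cfg, rng, ann, sites = self._base()
        truth = simulate_methylome(ann, sites, cfg, rng)
        m = truth.sites
        assert m.loc[m["in_island"], "m_control"].mean() < 0.3
        assert m.loc[~m["in_island"], "m_control"].mean() > 0.6

    def test_fractions_stay_in_unit_interval(self):
        cfg, rng, ann, sites = self._base(shift_size=-0.9,
                                          fraction_of_promoters_shifted=0.5)
        truth = simulate_methylome(ann, sites, cfg, rng)
        for col in ("m_control", "m_treated"):
            v = truth.sites[col]
            assert ((0 <= v) & (v <= 1)).all()


class TestCounts:
    def _truth(self, **over):
        cfg = SimulationConfig(seed=17, **{**SMALL, **over})
        rng = np.random.default_rng(cfg.seed)
        ann, sites = simulate_genome(cfg, rng)
        truth = simulate_methylome(ann, sites, cfg, rng)
        return cfg, rng, truth

    def test_counts_nonnegative_integers_and_totals(self):
        cfg, rng, truth = self._truth()
        counts, lib, standards = simulate_site_counts(truth, cfg, rng)
        for col in ("sensitive_count", "insensitive_count"):
            assert (counts[col] >= 0).all()
            assert pd.api.types.is_integer_dtype(counts[col])
        for cond in (CONTROL, TREATED):
            sub = counts[counts["condition"] == cond]
            assert lib[cond].sensitive_total >= sub["sensitive_count"].sum()
            assert lib[cond].insensitive_total >= sub["insensitive_count"].sum()

    def test_extreme_fractions_silence_one_library(self):
        cfg, rng, truth = self._truth()
        truth.sites["m_control"] = 0.0
        truth.sites["m_treated"] = 1.0
        counts, _, _ = simulate_site_counts(truth, cfg, rng)
        site_rows = counts[~counts["site_id"].str.startswith("spikein")]
        ctl = site_rows[site_rows["condition"] == CONTROL]
        trt = site_rows[site_rows["condition"] == TREATED]
        assert (ctl["insensitive_count"] == 0).all()  # m=0: no methylated tags
        assert (trt["sensitive_count"] == 0).all()  # m=1: no unmethylated tags

    def test_four_spikeins_per_condition(self):
        cfg, rng, truth = self._truth()
        counts, _, standards = simulate_site_counts(truth, cfg, rng)
        assert len(standards) == 4
        assert sorted(s.true_fraction for s in standards) == sorted(
            SPIKEIN_FRACTIONS.values()
        )
        spike = counts[counts["site_id"].str.startswith("spikein")]
        assert len(spike) == 8  # 4 standards x 2 conditions

    def test_estimator_unbiased_at_half_over_replicates(self):
        """Mean of M/(M+U) over 10^4 replicate sites at m=0.5, depth 200,
        within ±0.01 of 0.5 (Monte-Carlo check against the generative value)."""
        rng = np.random.default_rng(19)
        u = rng.poisson(200 * 0.5, size=10_000)
        m = rng.poisson(200 * 0.5, size=10_000)
        ok = (u + m) > 0
        est = m[ok] / (m[ok] + u[ok])
        assert abs(est.mean() - 0.5) <= 0.01


class TestDeTable:
    def test_truth_up_genes_exceed_fold_threshold(self):
        cfg = SimulationConfig(seed=23, de_fraction=0.3, **SMALL)
        ds = simulate_dataset(cfg)
        merged = ds.de_table.merge(ds.truth.genes, on="gene_id")
        up = merged[merged["de_status"] == "up"]
        down = merged[merged["de_status"] == "down"]
        assert (up["fold_change"] > 1.5).all()
        assert (up["p_value"] < 0.05).all()
        assert (down["fold_change"] < 1 / 1.5).all()

    def test_no_de_truth_means_no_passing_genes(self):
        from mscc.de import filter_de

        cfg = SimulationConfig(seed=29, de_fraction=0.0, **SMALL)
        ds = simulate_dataset(cfg)
        assert len(filter_de(ds.de_table)) == 0

    def test_truth_label_count_reproducible_from_seed(self):
        cfg = SimulationConfig(seed=31, n_chrom=1, chrom_length=2_000_000,
                               n_genes=1_000, n_islands=5, n_sites=100,
                               de_fraction=0.1)
        n1 = (simulate_dataset(cfg).truth.genes["de_status"] == "up").sum()
        n2 = (simulate_dataset(cfg).truth.genes["de_status"] == "up").sum()
        assert n1 == n2 and n1 > 0


class TestDatasetDeterminism:
    def test_full_dataset_reproducible(self):
        cfg = SimulationConfig(seed=37, **SMALL)
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.counts, d2.counts)
        pd.testing.assert_frame_equal(d1.de_table, d2.de_table)
        pd.testing.assert_frame_equal(d1.truth.sites, d2.truth.sites)
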