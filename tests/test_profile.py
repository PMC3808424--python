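"""Methylome change profile: deltas, strata summaries, TSS profile."""
import numpy as np
import pandas as pd
import pytest

from mscc.annotation import CcggSite
from mscc.profile import (
    site_deltas,
    summarize_all,
    summarize_region,
    tss_profile,
)
from mscc.quant import CONTROL, TREATED

from _oracles import brute_direction_counts


def make_meth(sites, m_ctl, m_hyp, reads=100):
    n = len(sites)
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            f"m_{CONTROL}": m_ctl,
            f"m_{TREATED}": m_hyp,
            f"reads_{CONTROL}": [reads] * n,
            f"reads_{TREATED}": [reads] * n,
        }
    )


class TestSiteDeltas:
    def test_arithmetic_direction_and_substantial_flag(self, toy_annotation):
        sites = [CcggSite("s1", "chr1", 100), CcggSite("s2", "chr1", 9_500)]
        meth = make_meth(sites, [0.8, 0.4], [0.3, 0.4])
        d = site_deltas(meth, sites, toy_annotation, change_cutoff=0.2)
        r1 = d.set_index("site_id").loc["s1"]
        assert r1["delta"] == pytest.approx(-0.5)
        assert r1["direction"] == "hypo" and bool(r1["substantial"])
        r2 = d.set_index("site_id").loc["s2"]
        assert r2["direction"] == "none" and not bool(r2["substantial"])

    def test_annotation_context_populated(self, toy_annotation):
        sites = [CcggSite("s1", "chr1", 9_500)]
        meth = make_meth(sites, [0.5], [0.1])
        r = site_deltas(meth, sites, toy_annotation).iloc[0]
        assert bool(r["in_island"])
        assert r["promoter_gene"] == "gA"
        assert r["tss_distance"] == -500

    def test_unannotated_chromosome_kept_in_genome_stratum(self, toy_annotation):
        sites = [CcggSite("s1", "chrZ", 10)]
        meth = make_meth(sites, [0.1], [0.6])
        d = site_deltas(meth, sites, toy_annotation)
        assert summarize_region(d, "genome").n_total == 1
        assert summarize_region(d, "island").n_total == 0
        assert len(tss_profile(d)) == 0

    def test_direction_counts_match_brute_force(self, toy_annotation):
        rng = np.random.default_rng(17)
        n = 300
        sites = [CcggSite(f"s{i}", "chr1", 20_000 + i) for i in range(n)]
        m_ctl = rng.uniform(0, 1, n).round(2)
        m_hyp = rng.uniform(0, 1, n).round(2)
        d = site_deltas(make_meth(sites, m_ctl, m_hyp), sites, toy_annotation)
        hyper, hypo, none = brute_direction_counts((m_hyp - m_ctl).tolist())
        assert (d["direction"] == "hyper").sum() == hyper
        assert (d["direction"] == "hypo").sum() == hypo
        assert (d["direction"] == "none").sum() == none


class TestRegionSummaries:
    @pytest.fixture
    def deltas(self, toy_annotation):
        rng = np.random.default_rng(23)
        n = 500
        pos = rng.choice(np.arange(0, 100_000), size=n, replace=False)
        sites = [CcggSite(f"s{i}", "chr1", int(p)) for i, p in enumerate(sorted(pos))]
        m_ctl = rng.uniform(0, 1, n)
        m_hyp = np.clip(m_ctl + rng.normal(0, 0.2, n), 0, 1)
        meth = make_meth(sites, m_ctl, m_hyp)
        meth[f"reads_{CONTROL}"] = rng.integers(30, 150, n)
        meth[f"reads_{TREATED}"] = rng.integers(30, 150, n)
        return site_deltas(meth, sites, toy_annotation)

    def test_counts_partition_at_zero_cutoff(self, deltas):
        """At cutoff 0 the hyper/hypo/zero-change tallies partition n_total."""
        for stratum in ("genome", "promoter", "island", "island_near_tss"):
            s = summarize_region(deltas, stratum, 30, 0.0)
            assert s.n_hyper + s.n_hypo <= s.n_total
        g = summarize_region(deltas, "genome", 30, 0.0)
        cov = (deltas[f"reads_{CONTROL}"] >= 30) & (deltas[f"reads_{TREATED}"] >= 30)
        n_zero = int(((deltas["delta"] == 0) & cov).sum())
        assert g.n_hyper + g.n_hypo + n_zero == g.n_total

    def test_cutoff_drops_small_changes_from_both_tallies(self, deltas):
        s0 = summarize_region(deltas, "genome", 30, 0.0)
        s2 = summarize_region(deltas, "genome", 30, 0.2)
        small = (deltas["delta"].abs() < 0.2) & (deltas["delta"] != 0)
        cov = (deltas[f"reads_{CONTROL}"] >= 30) & (deltas[f"reads_{TREATED}"] >= 30)
        assert (s0.n_hyper + s0.n_hypo) - (s2.n_hyper + s2.n_hypo) == int(
            (small & cov).sum()
        )
        assert s0.n_total == s2.n_total

    def test_raising_coverage_threshold_never_adds_sites(self, deltas):
        totals = [
            summarize_region(deltas, "genome", t).n_total for t in (30, 60, 100)
        ]
        assert totals[0] >= totals[1] >= totals[2]

    def test_summarize_all_agrees_with_single_calls(self, deltas):
        """Batch summarization must not perturb the input table: every row of
        summarize_all equals an independent summarize_region call."""
        batch = summarize_all(deltas)
        for r in batch.itertuples(index=False):
            single = summarize_region(
                deltas, r.stratum, r.coverage_threshold, r.change_cutoff
            )
            assert (single.n_total, single.n_hyper, single.n_hypo) == (
                r.n_total, r.n_hyper, r.n_hypo,
            )

    def test_substrata_bounded_by_genome(self, deltas):
        g = summarize_region(deltas, "genome", 30).n_total
        for stratum in ("promoter", "island", "island_near_tss"):
            assert summarize_region(deltas, stratum, 30).n_total <= g

    def test_empty_stratum_all_zero(self, toy_annotation):
        sites = [CcggSite("s1", "chr1", 25_000)]  # not in any island/promoter
        d = site_deltas(make_meth(sites, [0.5], [0.9]), sites, toy_annotation)
        s = summarize_region(d, "island")
        assert (s.n_total, s.n_hyper, s.n_hypo) == (0, 0, 0)

    def test_unknown_stratum_rejected(self, deltas):
        with pytest.raises(ValueError, match="unknown stratum"):
            summarize_region(deltas, "exon")

    def test_island_shift_dominates_hypo_fraction(self):
        """A simulation hypomethylating island sites by 0.4 yields an island
        stratum that is >=85% hypo at the 20% cutoff, matching the
        generative design."""
        from mscc.simulate import SimulationConfig, simulate_dataset
        from mscc.quant import filter_coverage, methylation_table

        cfg = SimulationConfig(
            seed=9, n_chrom=1, chrom_length=600_000, n_genes=60, n_islands=40,
            n_sites=3_000, mean_site_depth=100.0,
            island_meth_mean=0.6, nonisland_meth_mean=0.75,
            fraction_of_promoters_shifted=1.0, shift_size=-0.4,
            island_promoter_overlap_prob=1.0,
        )
        ds = simulate_dataset(cfg)
        meth = filter_coverage(methylation_table(ds.counts, ds.library_info))
        deltas = site_deltas(meth, ds.sites, ds.annotation)
        # restrict to island sites inside shifted promoters via truth
        shifted = ds.truth.sites.loc[ds.truth.sites["shifted"], "site_id"]
        sub = deltas[deltas["site_id"].isin(set(shifted)) & deltas["in_island"]]
        s = summarize_region(sub.reset_index(drop=True), "island", 30, 0.2)
        assert s.n_total > 50
        assert s.n_hypo / s.n_total >= 0.85


class TestTssProfile:
    def test_row_bookkeeping_and_distance_zero(self, toy_annotation):
        sites = [
            CcggSite("at_tss", "chr1", 10_000),
            CcggSite("far", "chr1", 70_000),
            CcggSite("orphan", "chrZ", 5),
        ]
        meth = make_meth(sites, [0.5, 0.5, 0.5], [0.6, 0.6, 0.6])
        d = site_deltas(meth, sites, toy_annotation)
        prof = tss_profile(d)
        assert len(prof) == 2  # orphan excluded
        assert prof.set_index("site_id").loc["at_tss", "tss_distance"] == 0

    def test_island_near_tss_consistency(self, toy_annotation):
        rng = np.random.default_rng(29)
        pos = rng.choice(np.arange(0, 100_000), size=400, replace=False)
        sites = [CcggSite(f"s{i}", "chr1", int(p)) for i, p in enumerate(sorted(pos))]
        m = rng.uniform(0, 1, 400)
        d = site_deltas(make_meth(sites, m, np.clip(m + 0.3, 0, 1)), sites, toy_annotation)
        prof = tss_profile(d)
        from_profile = set(
            prof.loc[prof["in_island"] & (prof["tss_distance"].abs() <= 1500), "site_id"]
        )
        stratum = summarize_region(d, "island_near_tss", 30, 0.0)
        assert len(from_profile) == stratum.n_total
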