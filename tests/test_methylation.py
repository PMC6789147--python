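import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from allopoly.methylation import (
    GenomeMethylationStats,
    body_methylation_P,
    call_mcg,
    conserved_sites,
    dmcg_change_rate,
    gene_region_extents,
    gene_methylation_summaries,
    genome_pcg,
    metagene_profile,
    methylated_fraction,
    promoter_bias_test,
    site_level,
)


def _report(counts, chrom="c1", context="CG"):
    """counts: list of (C, T) per site, positions 1..n."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, len(counts) + 1),
            "strand": "+",
            "context": context,
            "count_methylated": [c for c, _ in counts],
            "count_unmethylated": [t for _, t in counts],
        }
    )


class TestConservedSites:
    def test_kept_when_all_replicates_reach_five(self):
        reps = [_report([(3, 2)]), _report([(0, 6)]), _report([(7, 0)])]
        assert len(conserved_sites(reps)) == 1

    def test_dropped_when_one_replicate_fails(self):
        reps = [_report([(3, 2)]), _report([(2, 2)]), _report([(4, 5)])]
        assert len(conserved_sites(reps)) == 0

    def test_poisson_tail_oracle(self, rng):
        n = 30000
        reps = []
        for _ in range(3):
            cov = rng.poisson(10, n)
            c = rng.binomial(cov, 0.5)
            rep = _report([(0, 0)] * n)
            rep["count_methylated"] = c
            rep["count_unmethylated"] = cov - c
            reps.append(rep)
        kept = len(conserved_sites(reps)) / n
        expected = stats.poisson.sf(4, 10) ** 3  # 0.9707^3 = 0.9147
        assert expected == pytest.approx(0.9147, abs=1e-3)
        assert kept == pytest.approx(expected, abs=0.01)

    def test_mismatched_coordinates_error(self):
        rep2 = _report([(5, 1)])
        rep2["pos"] = [99]
        with pytest.raises(ValueError, match="different site coordinates"):
            conserved_sites([_report([(5, 1)]), rep2])


class TestSiteLevel:
    def test_formula(self):
        assert site_level(3, 1) == pytest.approx(0.75)

    def test_extremes(self):
        assert site_level(0, 5) == 0.0
        assert site_level(5, 0) == 1.0

    def test_zero_coverage_error(self):
        with pytest.raises(ValueError):
            site_level(0, 0)


class TestCallMcg:
    @staticmethod
    def _called(counts_per_rep):
        reps = [_report(counts) for counts in counts_per_rep]
        sites = conserved_sites(reps, min_cov=1)
        return call_mcg(sites)

    def test_fully_methylated_site_called(self):
        out = self._called([[(10, 0)], [(10, 0)], [(10, 0)]])
        assert out["methylated"].iloc[0]

    def test_fully_unmethylated_not_called(self):
        out = self._called([[(0, 10)]])
        assert not out["methylated"].iloc[0]

    def test_one_of_ten_below_threshold(self):
        # P(X >= 1 | n=10, p=0.01) = 1 - 0.99^10 = 0.0956 > 0.05
        assert 1 - 0.99**10 == pytest.approx(0.0956, abs=1e-4)
        out = self._called([[(1, 9)]])
        assert not out["methylated"].iloc[0]

    def test_consensus_requires_all_replicates(self):
        out = self._called([[(10, 0)], [(0, 10)], [(10, 0)]])
        assert not out["methylated"].iloc[0]
        assert out["methylated_1"].iloc[0] and not out["methylated_2"].iloc[0]

    def test_invalid_error_rate(self):
        sites = conserved_sites([_report([(5, 5)])], min_cov=1)
        with pytest.raises(ValueError):
            call_mcg(sites, error_rate=0.0)


class TestGenomePcg:
    def test_paper_counts(self):
        stats_ = GenomeMethylationStats(n_cg_sites=42911370, n_mcg_sites=21275948)
        assert round(100 * stats_.pcg, 2) == 49.58

    def test_all_cytosine_fraction(self):
        assert round(100 * methylated_fraction(21724824, 309953955), 2) == 7.01

    def test_none_and_all(self):
        assert GenomeMethylationStats(100, 0).pcg == 0.0
        assert GenomeMethylationStats(100, 100).pcg == 1.0

    def test_from_called_sites(self):
        sites = conserved_sites([_report([(10, 0), (0, 10)])], min_cov=1)
        out = call_mcg(sites)
        stats_ = genome_pcg(out)
        assert stats_.n_cg_sites == 2 and stats_.n_mcg_sites == 1
        assert stats_.pcg == 0.5

    def test_no_cg_error(self):
        sites = conserved_sites([_report([(5, 5)], context="CHH")], min_cov=1)
        with pytest.raises(ValueError):
            genome_pcg(call_mcg(sites))


class TestBodyMethylationP:
    def test_all_methylated_closed_form(self):
        assert body_methylation_P(10, 10, 0.5) == pytest.approx(0.5**10, rel=1e-9)

    def test_zero_mcg_is_one(self):
        assert body_methylation_P(10, 0, 0.37) == pytest.approx(1.0)

    def test_brute_force_sum_oracle(self):
        ncg, mcg, pcg = 20, 15, 0.4958
        expected = sum(
            stats.binom.pmf(i, ncg, pcg) for i in range(mcg, ncg + 1)
        )
        assert body_methylation_P(ncg, mcg, pcg) == pytest.approx(expected, abs=1e-12)

    @given(
        st.integers(min_value=1, max_value=200),
        st.integers(min_value=0, max_value=200),
        st.floats(min_value=0.01, max_value=0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_summation(self, ncg, mcg, pcg):
        mcg = min(mcg, ncg)
        expected = float(
            np.sum(stats.binom.pmf(np.arange(mcg, ncg + 1), ncg, pcg))
        )
        assert body_methylation_P(ncg, mcg, pcg) == pytest.approx(expected, abs=1e-12)

    def test_monotone_non_increasing_in_mcg(self):
        values = [body_methylation_P(50, m, 0.4958) for m in range(51)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_mcg_above_ncg_error(self):
        with pytest.raises(ValueError):
            body_methylation_P(5, 6, 0.5)


class TestDmcg:
    @staticmethod
    def _called_from(levels_per_rep, chrom):
        reps = [
            _report([(10, 0) if lvl else (0, 10) for lvl in levels], chrom=chrom)
            for levels in levels_per_rep
        ]
        return call_mcg(conserved_sites(reps, min_cov=1))

    def _site_map(self, n):
        return pd.DataFrame(
            {
                "chrom_a": "cA",
                "pos_a": np.arange(1, n + 1),
                "chrom_b": "cB",
                "pos_b": np.arange(1, n + 1),
            }
        )

    def test_methylated_vs_unmethylated_counted(self):
        called_a = self._called_from([[1], [1], [1]], "cA")
        called_b = self._called_from([[0], [0], [0]], "cB")
        res = dmcg_change_rate(self._site_map(1), called_a, called_b)
        assert res.n_dmcg == 1 and res.change_rate == 1.0

    def test_two_of_three_replicates_not_counted(self):
        called_a = self._called_from([[1], [1], [0]], "cA")
        called_b = self._called_from([[0], [0], [0]], "cB")
        res = dmcg_change_rate(self._site_map(1), called_a, called_b)
        assert res.n_dmcg == 0

    def test_self_comparison_zero(self):
        called = self._called_from([[1, 0, 1], [1, 0, 1], [1, 0, 1]], "cA")
        site_map = pd.DataFrame(
            {
                "chrom_a": "cA",
                "pos_a": [1, 2, 3],
                "chrom_b": "cA",
                "pos_b": [1, 2, 3],
            }
        )
        res = dmcg_change_rate(site_map, called, called)
        assert res.n_dmcg == 0 and res.change_rate == 0.0

    def test_empty_map_error(self):
        called = self._called_from([[1]], "cA")
        with pytest.raises(ValueError):
            dmcg_change_rate(self._site_map(0), called, called)


def _uniform_sites(chrom, start, end, level, rng, cov=50):
    pos = np.arange(start, end, 3) + 1
    c = rng.binomial(cov, level, size=pos.size)
    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": "+",
            "context": "CG",
            "count_methylated": c,
            "count_unmethylated": cov - c,
        }
    )
    return frame


class TestMetagene:
    def _genes(self, strand="+"):
        return pd.DataFrame(
            [{"chrom": "c1", "start": 1000, "end": 2000, "strand": strand, "gene_id": "g1"}]
        )

    def test_uniform_level_flat_profile(self, rng):
        genes = self._genes()
        regions = gene_region_extents(genes, promoter_len=1000, downstream_len=1000)
        table = _uniform_sites("c1", 0, 3000, 0.5, rng)
        called = call_mcg(conserved_sites([table], min_cov=1))
        profiles, n_missing = metagene_profile(genes, called, regions, n_bins=10)
        assert n_missing == 0
        for region in ("promoter", "body", "downstream"):
            np.testing.assert_allclose(profiles[region], 0.5, atol=0.06)

    def test_promoter_body_step_recovered(self, rng):
        genes = self._genes()
        regions = gene_region_extents(genes, promoter_len=1000, downstream_len=1000)
        table = pd.concat(
            [
                _uniform_sites("c1", 0, 1000, 0.3, rng),
                _uniform_sites("c1", 1000, 3000, 0.8, rng),
            ],
            ignore_index=True,
        )
        called = call_mcg(conserved_sites([table], min_cov=1))
        profiles, _ = metagene_profile(genes, called, regions, n_bins=10)
        np.testing.assert_allclose(profiles["promoter"], 0.3, atol=0.05)
        np.testing.assert_allclose(profiles["body"], 0.8, atol=0.05)

    def test_minus_strand_promoter_is_downstream_of_coords(self, rng):
        genes = self._genes(strand="-")
        regions = gene_region_extents(genes, promoter_len=1000, downstream_len=1000)
        prom = regions[regions["region"] == "promoter"].iloc[0]
        assert prom.start == 2000 and prom.end == 3000
        # plant a gradient inside the promoter; on the minus strand the bin
        # order must run from the TSS (coordinate end) leftwards
        table = _uniform_sites("c1", 2000, 3000, 0.0, rng)
        table.loc[table["pos"] > 2900, "count_methylated"] = 50
        table.loc[table["pos"] > 2900, "count_unmethylated"] = 0
        called = call_mcg(conserved_sites([table], min_cov=1))
        profiles, _ = metagene_profile(genes, called, regions, n_bins=10)
        assert profiles["promoter"][0] > 0.9  # 5'-most bin
        assert profiles["promoter"][-1] < 0.1


class TestPromoterBiasTest:
    def test_identical_sets(self, rng):
        levels = rng.uniform(0.2, 0.8, 100)
        p, diff, low_power = promoter_bias_test(levels, levels.copy())
        assert p == pytest.approx(0.5, abs=0.05)
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert not low_power

    def test_planted_delta_detected(self, rng):
        dom = np.clip(rng.normal(0.3, 0.1, 200), 0, 1)
        sup = np.clip(rng.normal(0.7, 0.1, 200), 0, 1)
        p, diff, _ = promoter_bias_test(dom, sup)
        assert p < 1e-6
        assert diff < -0.3

    def test_type_i_error_calibration(self, rng):
        n_sim, alpha = 400, 0.05
        rejections = 0
        for _ in range(n_sim):
            a = rng.normal(0.5, 0.1, 50)
            b = rng.normal(0.5, 0.1, 50)
            p, _, _ = promoter_bias_test(a, b)
            rejections += p < alpha
        rate = rejections / n_sim
        assert 0.02 <= rate <= 0.09  # ~0.05 within 4 binomial sd

    def test_small_set_low_power_warning(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            p, _, low_power = promoter_bias_test([0.1, 0.2], [0.5, 0.6, 0.7])
        assert low_power and 0 <= p <= 1

    def test_students_t_option(self, rng):
        dom = rng.normal(0.3, 0.05, 50)
        sup = rng.normal(0.7, 0.05, 50)
        p, _, _ = promoter_bias_test(dom, sup, test="ttest")
        assert p < 1e-10


class TestOnSyntheticData:
    def test_planted_levels_recovered(self, default_dataset, default_config):
        dataset, truth = default_dataset
        sites = conserved_sites(dataset.cytosine_reports)
        called = call_mcg(sites)
        genes = dataset.genes[dataset.genes["chrom"].isin(dataset.sequences)]
        regions = gene_region_extents(
            genes,
            promoter_len=default_config.flank_len,
            downstream_len=default_config.flank_len,
        )
        summaries = gene_methylation_summaries(called, regions, genome_pcg(called).pcg)
        by_gene = {(s.gene_id, s.region): s for s in summaries}
        errors = []
        for gene, planted in truth.gene_methylation.items():
            for region, level in planted.items():
                s = by_gene[(gene, region)]
                if s.ncg >= 5:
                    errors.append(s.level - level)
        assert len(errors) > 100
        assert np.mean(np.abs(errors)) < 0.05

    def test_promoter_direction_on_silenced_pairs(self, default_dataset, default_config):
        dataset, truth = default_dataset
        sites = conserved_sites(dataset.cytosine_reports)
        called = call_mcg(sites)
        genes = dataset.genes[dataset.genes["chrom"].isin(dataset.sequences)]
        regions = gene_region_extents(
            genes,
            promoter_len=default_config.flank_len,
            downstream_len=default_config.flank_len,
        )
        summaries = gene_methylation_summaries(called, regions, genome_pcg(called).pcg)
        prom = {s.gene_id: s.level for s in summaries if s.region == "promoter"}
        dom_levels, sup_levels = [], []
        for row in truth.pairs.itertuples(index=False):
            label = truth.pair_dominance[row.pair_id]
            if label == "silenced-A":
                sup_levels.append(prom[row.gene_a])
                dom_levels.append(prom[row.gene_b])
            elif label == "silenced-B":
                sup_levels.append(prom[row.gene_b])
                dom_levels.append(prom[row.gene_a])
        p, diff, _ = promoter_bias_test(dom_levels, sup_levels)
        assert diff < 0
        assert p < 0.05
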