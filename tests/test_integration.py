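"""DMR-gene linking, correlation classification, enhancer cascade and
network ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdeg import integration
from methdeg.dmr import DMR


def mk_dmr(i, chrom, start, end, direction="hypo"):
    sign = 1 if direction == "hyper" else -1
    return DMR(f"d{i}", chrom, start, end, 5, 0.5, 0.5 + sign * 0.2, sign * 0.2,
               direction, sign * 5.0, wilcoxon_p=0.03, passed_wilcoxon=True)


def de_frame(genes, degs, tested=None):
    df = pd.DataFrame(index=genes)
    df["log2_fc"] = 1.0
    df["p"] = 0.01
    if tested is not None:
        df.loc[[g for g in genes if g not in tested], "p"] = np.nan
    df["padj"] = df["p"]
    df["deg"] = [g in degs for g in genes]
    return df


class TestAssignPromoterDmrs:
    def test_overlap_with_window_edge_links(self, toy_genes):
        # GA TSS at 10,000 (+); window 6 kb: [4,000, 16,000]
        links = integration.assign_promoter_dmrs(
            [mk_dmr(1, "chr1", 15_500, 16_500)], toy_genes
        )
        assert list(links["gene_id"]) == ["GA"]

    def test_outside_window_not_linked(self, toy_genes):
        links = integration.assign_promoter_dmrs(
            [mk_dmr(1, "chr1", 17_000, 18_000)], toy_genes
        )
        assert links.empty

    def test_spanning_tss_distance_sign_by_midpoint(self, toy_genes):
        links = integration.assign_promoter_dmrs(
            [mk_dmr(1, "chr1", 9_000, 13_000)], toy_genes
        )
        # midpoint 11,000 is 1 kb downstream of the + strand TSS
        assert links.iloc[0]["distance"] == 1_000

    def test_minus_strand_distance_sign_reflects(self, toy_genes):
        # GB TSS at 47,999 (-): a DMR centred at 46,999 is downstream
        links = integration.assign_promoter_dmrs(
            [mk_dmr(1, "chr1", 46_500, 47_500)], toy_genes
        )
        row = links[links["gene_id"] == "GB"].iloc[0]
        assert row["distance"] == 999

    def test_zero_window_requires_tss_overlap(self, toy_genes):
        inside = integration.assign_promoter_dmrs(
            [mk_dmr(1, "chr1", 9_500, 10_500)], toy_genes, window=0
        )
        outside = integration.assign_promoter_dmrs(
            [mk_dmr(1, "chr1", 10_500, 11_500)], toy_genes, window=0
        )
        assert list(inside["gene_id"]) == ["GA"] and outside.empty


class TestDmrDegFisher:
    def test_odds_ratio_cross_formula(self):
        genes = [f"g{i}" for i in range(200)]
        degs = set(genes[:100])
        linked = set(genes[:20]) | set(genes[100:105])   # 20 DEG, 5 non-DEG
        links = pd.DataFrame({"gene_id": sorted(linked)})
        table, odds, p = integration.dmr_deg_fisher(links, de_frame(genes, degs))
        assert table.tolist() == [[20, 80], [5, 95]]
        assert odds == pytest.approx((20 * 95) / (80 * 5))

    def test_extreme_table_matches_hypergeometric_tail(self):
        """All DEGs linked, no non-DEG linked: two-sided Fisher p equals the
        single hypergeometric point mass (the most extreme table)."""
        genes = [f"g{i}" for i in range(12)]
        degs = set(genes[:4])
        links = pd.DataFrame({"gene_id": sorted(degs)})
        _, _, p = integration.dmr_deg_fisher(links, de_frame(genes, degs))
        expected = 1.0 / stats.binom(12, 0).pmf(0) / math.comb(12, 4)
        assert p == pytest.approx(1.0 / math.comb(12, 4))

    def test_null_p_uniform(self):
        """Independent random link assignment: Fisher p roughly uniform
        across seeds (KS test not rejecting at 0.01)."""
        genes = [f"g{i}" for i in range(60)]
        degs = set(genes[:20])
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            linked = rng.choice(genes, size=15, replace=False)
            links = pd.DataFrame({"gene_id": linked})
            _, _, p = integration.dmr_deg_fisher(links, de_frame(genes, degs))
            ps.append(p)
        # discrete conservatism makes Fisher p super-uniform; check only
        # that it is not anti-conservative
        assert np.mean(np.array(ps) < 0.05) <= 0.07

    def test_degenerate_margin_warns_and_returns_one(self):
        genes = ["a", "b"]
        links = pd.DataFrame({"gene_id": []})
        with pytest.warns(UserWarning):
            _, odds, p = integration.dmr_deg_fisher(links, de_frame(genes, set()))
        assert p == 1.0


class TestCorrelateLinks:
    def _inputs(self, expr_vals, beta_vals, samples=None):
        samples = samples or [f"s{i}" for i in range(len(expr_vals))]
        dmr_beta = pd.DataFrame([beta_vals], index=["d1"], columns=samples)
        expr = pd.DataFrame([expr_vals], index=["g1"], columns=samples)
        links = pd.DataFrame({"dmr_id": ["d1"], "gene_id": ["g1"]})
        return links, dmr_beta, expr

    def test_reversed_ranks_give_minus_one(self):
        links, b, e = self._inputs([8, 7, 6, 5, 4, 3, 2, 1],
                                   [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        out = integration.correlate_links(links, b, e)
        assert out.iloc[0]["spearman_rho"] == pytest.approx(-1.0)
        assert out.iloc[0]["corr_class"] == "negative"

    def test_identical_ranks_give_plus_one(self):
        links, b, e = self._inputs([1, 2, 3, 4, 5, 6, 7, 8],
                                   [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        out = integration.correlate_links(links, b, e)
        assert out.iloc[0]["corr_class"] == "positive"

    def test_tie_handled_by_average_ranks(self):
        """rho with one tie equals the direct average-rank computation."""
        x = np.array([0.1, 0.2, 0.2, 0.4, 0.5, 0.6, 0.7, 0.8])
        y = np.array([10, 9, 8, 7, 6, 5, 4, 3.0])
        links, b, e = self._inputs(list(y), list(x))
        out = integration.correlate_links(links, b, e)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out.iloc[0]["spearman_rho"] == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        x = np.random.default_rng(0).random(8)
        y = np.random.default_rng(1).random(8)
        links, b, e = self._inputs(list(y), list(x))
        r1 = integration.correlate_links(links, b, e).iloc[0]["spearman_rho"]
        links, b2, e2 = self._inputs(list(np.exp(5 * y)), list(x**3))
        r2 = integration.correlate_links(links, b2, e2).iloc[0]["spearman_rho"]
        assert r1 == pytest.approx(r2)

    def test_zero_variance_unclassified(self):
        links, b, e = self._inputs([5, 5, 5, 5, 5, 5, 5, 5],
                                   [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        out = integration.correlate_links(links, b, e)
        assert math.isnan(out.iloc[0]["spearman_rho"])
        assert out.iloc[0]["corr_class"] == "unclassified"

    def test_too_few_shared_samples_rejected(self):
        links, b, e = self._inputs([1, 2, 3], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            integration.correlate_links(links, b, e)


class TestCorrelationSummary:
    def test_printed_counts_reproduce_published_shares(self):
        """492 negative / 151 positive classified genes -> 76.5% / 23.5%."""
        assert integration.class_shares(492, 151) == (76.5, 23.5)

    def test_linked_share_one_decimal(self):
        assert integration.linked_share(755, 2261 + 916) == 23.8

    def test_zero_classified_no_crash(self):
        links = pd.DataFrame(
            {"gene_id": ["g1"], "dmr_id": ["d1"], "corr_class": ["unclassified"]}
        )
        out = integration.correlation_summary(links)
        assert math.isnan(out["pct_negative"])
        assert out["n_unclassified"] == 1

    def test_summary_counts_by_gene(self):
        links = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2", "g3"],
                "dmr_id": ["d1", "d2", "d3", "d4"],
                "corr_class": ["negative", "unclassified", "positive", "negative"],
            }
        )
        out = integration.correlation_summary(links)
        assert (out["n_negative"], out["n_positive"]) == (2, 1)


class TestEnhancerCascade:
    def _toy(self):
        """The documented 6-association toy table: 2 non-coding-gene, 2
        non-elite, 1 non-DEG association -> stage counts 6/4/2/1."""
        dmrs = [mk_dmr(i, "chr1", 1_000 * i, 1_000 * i + 500) for i in range(1, 7)]
        enh = pd.DataFrame(
            [
                # two associations to non-coding genes (filtered at stage 2)
                {"element_id": "E1", "chrom": "chr1", "start": 1_000, "end": 1_400,
                 "gene_id": "gX", "biotype": "other", "score": 10, "elite": True},
                {"element_id": "E2", "chrom": "chr1", "start": 2_000, "end": 2_400,
                 "gene_id": "gY", "biotype": "other", "score": 10, "elite": True},
                # two non-elite associations (filtered at stage 3)
                {"element_id": "E3", "chrom": "chr1", "start": 3_000, "end": 3_400,
                 "gene_id": "gA", "biotype": "protein_coding", "score": 5, "elite": False},
                {"element_id": "E4", "chrom": "chr1", "start": 4_000, "end": 4_400,
                 "gene_id": "gB", "biotype": "lncRNA", "score": 5, "elite": False},
                # elite association to a non-DEG (filtered at stage 4)
                {"element_id": "E5", "chrom": "chr1", "start": 5_000, "end": 5_400,
                 "gene_id": "gC", "biotype": "protein_coding", "score": 20, "elite": True},
                # elite association to a DEG (survives)
                {"element_id": "E6", "chrom": "chr1", "start": 6_000, "end": 6_400,
                 "gene_id": "gD", "biotype": "protein_coding", "score": 20, "elite": True},
            ]
        )
        de = de_frame(["gA", "gB", "gC", "gD", "gX", "gY"], {"gD"})
        return dmrs, enh, de

    def test_stage_counts_6_4_2_1(self):
        dmrs, enh, de = self._toy()
        links, counts = integration.enhancer_cascade(dmrs, enh, de)
        assert counts["associations"] == 6
        assert counts["coding_or_lncRNA"] == 4
        assert counts["elite"] == 2
        assert counts["deg_linked"] == 1
        assert list(links["gene_id"]) == ["gD"]

    def test_stage_counts_non_increasing(self):
        dmrs, enh, de = self._toy()
        _, c = integration.enhancer_cascade(dmrs, enh, de)
        seq = [c["associations"], c["coding_or_lncRNA"], c["elite"], c["deg_linked"]]
        assert seq == sorted(seq, reverse=True)

    def test_empty_table_all_zero(self):
        dmrs, _, de = self._toy()
        empty = pd.DataFrame(columns=["element_id", "chrom", "start", "end",
                                      "gene_id", "biotype", "score", "elite"])
        _, c = integration.enhancer_cascade(dmrs, empty, de)
        assert set(c.values()) == {0}

    def test_two_elements_same_gene_counted_as_two_associations(self):
        dmrs = [mk_dmr(1, "chr1", 1_000, 2_000)]
        enh = pd.DataFrame(
            [
                {"element_id": "E1", "chrom": "chr1", "start": 900, "end": 1_200,
                 "gene_id": "gA", "biotype": "protein_coding", "score": 9, "elite": True},
                {"element_id": "E2", "chrom": "chr1", "start": 1_500, "end": 1_900,
                 "gene_id": "gA", "biotype": "protein_coding", "score": 9, "elite": True},
            ]
        )
        de = de_frame(["gA"], {"gA"})
        _, c = integration.enhancer_cascade(dmrs, enh, de)
        assert c["associations"] == 2 and c["dmrs_overlapping"] == 1


class TestMasterRegulatorRank:
    def test_path_intermediary(self):
        out = integration.master_regulator_rank([("A", "B"), ("B", "C")])
        assert out.loc["B", "betweenness"] == 1.0
        assert out.loc["A", "betweenness"] == 0.0

    def test_star_hub_pair_count(self):
        edges = [("hub", f"leaf{i}") for i in range(4)]
        out = integration.master_regulator_rank(edges)
        assert out.loc["hub", "betweenness"] == 6.0    # C(4,2) leaf pairs

    def test_empty_graph_all_zero(self):
        ann = pd.DataFrame({"deg": [True, False]}, index=["A", "B"])
        out = integration.master_regulator_rank([], ann)
        assert (out["betweenness"] == 0).all()
        assert set(out.index) == {"A", "B"}

    def test_annotations_passed_through(self):
        ann = pd.DataFrame({"deg": [True, False, True]}, index=["A", "B", "C"])
        out = integration.master_regulator_rank([("A", "B"), ("B", "C")], ann)
        assert bool(out.loc["A", "deg"]) is True
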