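"""Smoothed-t DMR calling: smoother, t-track, run caller, rank-sum filter,
stitching and summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdeg import dmr
from methdeg.dmr import DMR
from methdeg.io import FilteredMatrix

from conftest import make_matrix


def make_track(positions, t, beta_control, beta_severe, chrom="chr1"):
    """Build a TStatTrack directly: 3 control and 5 severe samples whose raw
    betas equal the stated group means (zero within-group spread)."""
    positions = np.asarray(positions, int)
    bc = np.asarray(beta_control, float)
    bs = np.asarray(beta_severe, float)
    beta = np.column_stack([np.tile(bc, (3, 1)).T, np.tile(bs, (5, 1)).T])
    samples = [f"c{i}" for i in range(3)] + [f"s{i}" for i in range(5)]
    mat = make_matrix(positions, beta, chrom=chrom, samples=samples)
    return dmr.TStatTrack(
        matrix=mat, t=np.asarray(t, float), mean_control=bc, mean_severe=bs,
        raw_delta=bs - bc, control_ids=samples[:3], severe_ids=samples[3:],
        sd_floor=0.1,
    )


class TestSmooth:
    def test_constant_track_is_fixed_point(self):
        mat = make_matrix(np.arange(50) * 100, np.full((50, 4), 0.5))
        out = dmr.smooth(mat, h=500, min_cpgs_window=10)
        assert np.allclose(out.smoothed, 0.5, atol=1e-12)

    def test_tiny_chromosome_passes_raw_betas(self):
        mat = make_matrix([100], [[0.37, 0.62]])
        out = dmr.smooth(mat)
        assert np.allclose(out.smoothed, [[0.37, 0.62]])

    def test_linear_ramp_reproduced_in_interior(self):
        """A local-linear fit follows a linear methylation gradient."""
        n = 200
        beta = np.linspace(0, 1, n)
        mat = make_matrix(np.arange(n) * 100, beta[:, None])
        out = dmr.smooth(mat, h=1000, min_cpgs_window=20)
        interior = slice(20, n - 20)
        dev = np.abs(out.smoothed[interior, 0] - beta[interior])
        assert dev.max() < 0.05

    def test_estimates_bounded(self, small_study):
        from methdeg import io

        *_, callsets = small_study
        mat = io.filter_cpgs(list(callsets.values()))
        out = dmr.smooth(mat, h=1000, min_cpgs_window=20)
        assert np.isfinite(out.smoothed).all()
        assert out.smoothed.min() >= 0 and out.smoothed.max() <= 1


class TestGroupTstat:
    def _track(self, control_vals, severe_vals):
        beta = np.array([control_vals + severe_vals])
        samples = [f"c{i}" for i in range(len(control_vals))] + [
            f"s{i}" for i in range(len(severe_vals))
        ]
        mat = make_matrix([100], beta, samples=samples)
        sm = dmr.SmoothedTrack(mat, beta.copy(), h=1000, min_cpgs_window=70)
        return sm, samples[: len(control_vals)], samples[len(control_vals):]

    def test_identical_groups_give_zero(self):
        sm, c, s = self._track([0.5, 0.5, 0.5], [0.5, 0.5, 0.5, 0.5, 0.5])
        out = dmr.group_tstat(sm, c, s, sd_floor=0.1)
        assert out.t[0] == 0.0

    def test_label_swap_negates(self):
        sm, c, s = self._track([0.2, 0.3, 0.25], [0.6, 0.7, 0.65, 0.6, 0.7])
        a = dmr.group_tstat(sm, c, s, sd_floor=0.05)
        b = dmr.group_tstat(sm, s, c, sd_floor=0.05)
        assert a.t[0] == pytest.approx(-b.t[0])

    def test_matches_hand_computed_pooled_sd_t(self):
        """With flooring disabled, t is the mean difference over the pooled
        within-group SD, computed here independently."""
        ctrl = [0.30, 0.40, 0.35]
        sev = [0.60, 0.70, 0.65, 0.75, 0.55]
        sm, c, s = self._track(ctrl, sev)
        out = dmr.group_tstat(sm, c, s, sd_floor=0.0)
        v1, v2 = np.var(ctrl, ddof=1), np.var(sev, ddof=1)
        sd_pool = math.sqrt((2 * v1 + 4 * v2) / 6)
        expected = (np.mean(sev) - np.mean(ctrl)) / sd_pool
        assert out.t[0] == pytest.approx(expected)

    def test_small_group_rejected(self):
        sm, c, s = self._track([0.5], [0.5, 0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            dmr.group_tstat(sm, c, s)


def brute_force_runs(positions, sign, max_gap):
    """Independent maximal-run enumerator over the threshold-exceeding
    subsequence: test every (start, end) pair of exceeding CpGs for the run
    property (same sign throughout, successive member gaps <= max_gap) and
    keep only the maximal intervals.  O(n^2) by construction — deliberately
    different from the caller's linear scan."""
    members = [i for i in range(len(positions)) if sign[i] != 0]

    def is_run(a, b):
        """members[a..b] form a valid run."""
        s = sign[members[a]]
        for k in range(a, b + 1):
            if sign[members[k]] != s:
                return False
        for k in range(a, b):
            if positions[members[k + 1]] - positions[members[k]] > max_gap:
                return False
        return True

    runs = []
    m = len(members)
    for a in range(m):
        for b in range(a, m):
            if not is_run(a, b):
                continue
            left_ext = a > 0 and is_run(a - 1, b)
            right_ext = b < m - 1 and is_run(a, b + 1)
            if not left_ext and not right_ext:
                runs.append((members[a], members[b], b - a + 1))
    return sorted(set(runs))


class TestCallCandidateDmrs:
    def test_two_qualifying_cpgs_insufficient(self):
        track = make_track([0, 100], [5.0, 5.0], [0.3, 0.3], [0.6, 0.6])
        assert dmr.call_candidate_dmrs(track, quantile=0.5, min_cpg=3) == []

    def test_five_consecutive_cpgs_form_one_hyper_dmr(self):
        pos = [1000, 1100, 1200, 1300, 1400]
        # background CpGs keep the t quantiles away from the signal
        pos_all = pos + list(range(10_000, 30_000, 200))
        t = [5.0] * 5 + [0.0] * 100
        bc = [0.3] * 5 + [0.5] * 100
        bs = [0.5] * 5 + [0.5] * 100
        track = make_track(pos_all, t, bc, bs)
        out = dmr.call_candidate_dmrs(track, quantile=0.05, min_delta=0.1,
                                      min_cpg=3, max_gap=300)
        assert len(out) == 1
        d = out[0]
        assert (d.n_cpg, d.direction) == (5, "hyper")
        assert (d.start, d.end) == (1000, 1401)
        assert d.delta == pytest.approx(0.2)

    def test_wide_gap_splits_run_below_min_cpg(self):
        pos = [1000, 1100, 1500, 1600, 1700]
        pos_all = pos + list(range(10_000, 30_000, 200))
        t = [5.0] * 2 + [5.0] * 3 + [0.0] * 100
        bc = [0.3] * 5 + [0.5] * 100
        bs = [0.5] * 5 + [0.5] * 100
        track = make_track(pos_all, t, bc, bs)
        out = dmr.call_candidate_dmrs(track, quantile=0.05, min_delta=0.1,
                                      min_cpg=3, max_gap=300)
        # 1000-1100 gap to 1500 is 400 bp: runs of 2 and 3; only the run of
        # 3 survives min_cpg
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (1500, 1701)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        n = 1000
        pos = np.cumsum(rng.integers(10, 500, n))
        t = rng.normal(0, 1, n) * rng.choice([1, 4], n, p=[0.9, 0.1])
        beta_c = np.clip(rng.random(n), 0, 1)
        beta_s = np.clip(beta_c + rng.normal(0, 0.3, n), 0, 1)
        track = make_track(pos, t, beta_c, beta_s)
        out = dmr.call_candidate_dmrs(track, quantile=0.05, min_delta=0.0,
                                      min_cpg=3, max_gap=300)

        lo, hi = np.quantile(t, [0.025, 0.975])
        sign = np.where(t >= hi, 1, np.where(t <= lo, -1, 0))
        expected = [
            (pos[i], pos[j] + 1, k)
            for i, j, k in brute_force_runs(pos, sign, 300)
            if k >= 3
        ]
        got = [(d.start, d.end, d.n_cpg) for d in out]
        assert got == expected


class TestWilcoxonFilter:
    def test_complete_separation_three_vs_five(self):
        """Exact two-sided p for complete separation is 2/56."""
        x = [0.1, 0.2, 0.3]
        y = [0.4, 0.5, 0.6, 0.7, 0.8]
        p = dmr.exact_ranksum_p(x, y)
        assert p == pytest.approx(2 / 56)

    def test_identical_group_means_removed(self):
        p = dmr.exact_ranksum_p([0.5, 0.5, 0.5], [0.5, 0.5, 0.5, 0.5, 0.5])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_exact_mwu_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(3)
        y = rng.random(5)
        ours = dmr.exact_ranksum_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_filter_sets_p_and_drops_nonpassing(self):
        pos = np.arange(5) * 100
        ctrl = np.tile([[0.1], [0.15], [0.2]], (1, 5)).T
        sev = np.tile([[0.6], [0.7], [0.65], [0.75], [0.8]], (1, 5)).T
        mat = make_matrix(pos, np.column_stack([ctrl, sev]),
                          samples=[f"c{i}" for i in range(3)] + [f"s{i}" for i in range(5)])
        good = DMR("d1", "chr1", 0, 401, 5, 0.15, 0.7, 0.55, "hyper", 10.0)
        flat = DMR("d2", "chr1", 0, 401, 5, 0.15, 0.7, 0.0, "hyper", 10.0)
        kept = dmr.wilcoxon_filter([good], mat, [f"c{i}" for i in range(3)],
                                   [f"s{i}" for i in range(5)], alpha=0.1)
        assert len(kept) == 1 and kept[0].wilcoxon_p == pytest.approx(2 / 56)


def _two_dmr_matrix(delta_a, delta_b, gap_beta_ctrl=0.5, gap_beta_sev=0.5):
    """Matrix with two 5-CpG blocks at [1000,1500) and [4000,4500) plus
    intervening CpGs; group betas differ by delta inside the blocks."""
    pos = list(range(1000, 1500, 100)) + list(range(2000, 4000, 500)) + list(
        range(4000, 4500, 100)
    )
    n = len(pos)
    bc = np.full(n, 0.5)
    bs = np.full(n, 0.5)
    bc[:5], bs[:5] = 0.5, 0.5 + delta_a
    bc[-5:], bs[-5:] = 0.5, 0.5 + delta_b
    bc[5:-5], bs[5:-5] = gap_beta_ctrl, gap_beta_sev
    beta = np.column_stack([np.tile(bc, (3, 1)).T, np.tile(bs, (5, 1)).T])
    samples = [f"c{i}" for i in range(3)] + [f"s{i}" for i in range(5)]
    return make_matrix(pos, beta, samples=samples), samples[:3], samples[3:]


class TestStitch:
    def _dmrs(self, direction):
        sign = 1 if direction == "hyper" else -1
        return [
            DMR("a", "chr1", 1000, 1500, 5, 0.5, 0.5, sign * 0.2, direction, sign * 5.0,
                wilcoxon_p=0.03, passed_wilcoxon=True),
            DMR("b", "chr1", 4000, 4500, 5, 0.5, 0.5, sign * 0.2, direction, sign * 5.0,
                wilcoxon_p=0.03, passed_wilcoxon=True),
        ]

    def test_same_direction_close_pair_merges(self):
        """Merged span keeps |delta| >= 0.1 -> single region [1000, 4500)."""
        mat, c, s = _two_dmr_matrix(-0.3, -0.3, gap_beta_sev=0.45)
        out = dmr.stitch(self._dmrs("hypo"), mat, c, s)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (1000, 4500)
        assert out[0].stitched_from == ["a", "b"]
        assert abs(out[0].delta) >= 0.1

    def test_direction_mismatch_not_merged(self):
        mat, c, s = _two_dmr_matrix(0.3, 0.3)
        dmrs = self._dmrs("hypo")
        dmrs[1].direction = "hyper"
        out = dmr.stitch(dmrs, mat, c, s)
        assert len(out) == 2

    def test_merged_delta_guard_blocks_weak_merge(self):
        """Intervening CpGs dilute the merged difference below 10%."""
        mat, c, s = _two_dmr_matrix(-0.12, -0.12, gap_beta_sev=0.5)
        out = dmr.stitch(self._dmrs("hypo"), mat, c, s)
        assert len(out) == 2

    def test_far_apart_not_merged(self):
        mat, c, s = _two_dmr_matrix(-0.3, -0.3, gap_beta_sev=0.4)
        dmrs = self._dmrs("hypo")
        dmrs[1] = DMR("b", "chr1", 9000, 9500, 5, 0.5, 0.2, -0.3, "hypo", -5.0,
                      wilcoxon_p=0.03, passed_wilcoxon=True)
        out = dmr.stitch(dmrs, mat, c, s, max_join_gap=5000)
        assert len(out) == 2


class TestSummarize:
    def test_direction_shares_from_printed_counts(self):
        """18,965 of 25,028 hypo regions is 76%; 6,063 hyper is 24%."""
        pct_hyper, pct_hypo = dmr.direction_shares(6063, 18965)
        assert (pct_hyper, pct_hypo) == (24, 76)

    def test_empty_list_no_division_error(self):
        out = dmr.summarize([])
        assert out["n_total"] == 0 and out["pct_hyper"] == 0

    def test_counts_and_means(self):
        dmrs = [
            DMR("a", "chr1", 0, 100, 5, 0.5, 0.7, 0.2, "hyper", 1.0),
            DMR("b", "chr1", 500, 700, 10, 0.5, 0.3, -0.2, "hypo", -1.0),
        ]
        out = dmr.summarize(dmrs)
        assert out["n_hyper"] == 1 and out["n_hypo"] == 1
        assert out["mean_n_cpg"] == 7.5 and out["mean_length"] == 150.0


class TestPipelineProperties:
    def test_group_swap_flips_directions(self, small_study):
        """Antisymmetry: swapping group labels converts hyper to hypo with
        |delta| preserved."""
        from methdeg import io
        from methdeg.evaluation import call_dmrs_scaled

        *_, design, effects, callsets = small_study[1:]
        layout = small_study[0]
        mat = io.filter_cpgs(list(callsets.values()))
        fwd = call_dmrs_scaled(mat, design.ids("control"), design.ids("severe"))
        rev = call_dmrs_scaled(mat, design.ids("severe"), design.ids("control"))
        f = {(d.chrom, d.start, d.end): (d.direction, round(d.delta, 9)) for d in fwd}
        r = {(d.chrom, d.start, d.end): (d.direction, round(d.delta, 9)) for d in rev}
        assert set(f) == set(r)
        for k in f:
            assert f[k][0] != r[k][0]
            assert f[k][1] == pytest.approx(-r[k][1])

    def test_coordinate_shift_equivariance(self, small_study):
        """Shifting all coordinates by a constant shifts DMRs identically."""
        from methdeg import io
        from methdeg.evaluation import call_dmrs_scaled

        *_, design, effects, callsets = small_study[1:]
        mat = io.filter_cpgs(list(callsets.values()))
        shift = 7_000
        shifted = mat.subset(np.ones(mat.n_cpg, bool))
        shifted.index = shifted.index.assign(pos=shifted.index["pos"] + shift)
        a = call_dmrs_scaled(mat, design.ids("control"), design.ids("severe"))
        b = call_dmrs_scaled(shifted, design.ids("control"), design.ids("severe"))
        assert [(d.chrom, d.start + shift, d.end + shift) for d in a] == [
            (d.chrom, d.start, d.end) for d in b
        ]
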