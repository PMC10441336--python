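import math

import numpy as np
import pandas as pd
import pytest

from scwga_cnv import segment
from scwga_cnv.segment import SegmentSet


def brute_force_best_arc(x, min_width):
    """Independent O(n^2) search for the maximal arc statistic."""
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    best, arg = -np.inf, None
    for i in range(n):
        if i != 0 and i < min_width:
            continue
        for j in range(i + min_width, n + 1):
            if j != n and j > n - min_width:
                continue
            k = j - i
            if n - k < min_width:
                continue
            d = S[j] - S[i]
            stat = abs(d / k - (S[n] - d) / (n - k)) / \
                math.sqrt(1 / k + 1 / (n - k))
            if stat > best:
                best, arg = stat, (i, j)
    return best, arg


def seg_set(ratios, weights):
    n = len(ratios)
    return SegmentSet(pd.DataFrame({
        "chrom": ["chr1"] * n, "start_bin": range(n), "end_bin": range(n),
        "n_bins": weights, "mean_ratio": ratios,
        "cn_est": np.nan, "cn_int": np.nan}))


class TestCbs:
    def test_constant_vector_single_segment(self):
        ss = segment.cbs_segment(np.ones(60), np.repeat("chr1", 60))
        assert len(ss) == 1
        assert ss.df.iloc[0]["n_bins"] == 60

    def test_planted_step_breakpoint_location(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(1.0, 0.1, 100),
                            rng.normal(1.5, 0.1, 50)])
        ss = segment.cbs_segment(x, np.repeat("chr1", 150), rng_seed=1)
        assert len(ss) == 2
        assert abs(ss.df.iloc[0]["end_bin"] + 1 - 100) <= 2

    def test_first_split_matches_brute_force_oracle(self):
        # on short vectors with one planted change, the accepted first split
        # must sit exactly at the brute-force maximal-statistic arc
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(30, 61))
            lo = int(rng.integers(5, n - 10))
            hi = int(rng.integers(lo + 5, min(lo + 25, n) + 1))
            x = rng.normal(1.0, 0.1, n)
            x[lo:hi] += 0.6
            b_stat, (bi, bj) = brute_force_best_arc(x, 5)
            masks = segment._arc_masks(n, 5)
            stat, (i, j) = segment._max_arc_stat(x[None, :], masks,
                                                 want_argmax=True)
            assert stat[0] == pytest.approx(b_stat, rel=1e-12)
            # an arc and its complement induce the same cuts and share the
            # statistic, so compare the induced cut sets
            cuts_impl = {c for c in (i, j) if 0 < c < n}
            cuts_oracle = {c for c in (bi, bj) if 0 < c < n}
            assert cuts_impl == cuts_oracle
            ss = segment.cbs_segment(x, np.repeat("chr1", n), rng_seed=seed,
                                     merge_delta=0.0)
            if len(ss) > 1:  # accepted: cuts include the oracle arc bounds
                cuts = set(ss.df["start_bin"]) | {n}
                assert cuts_oracle <= cuts

    def test_short_chromosome_single_segment(self):
        ss = segment.cbs_segment(np.r_[np.ones(4), np.full(4, 3.0)],
                                 np.repeat("chr1", 8), min_width=5)
        assert len(ss) == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1, 0.12, 300)
        x[120:140] += 0.5
        chrom = np.repeat(["chr1", "chr2"], 150)
        a = segment.cbs_segment(x, chrom, rng_seed=1)
        b = segment.cbs_segment(x, chrom, rng_seed=1)
        assert a.df.equals(b.df)

    def test_type_one_error_controlled(self):
        # pure noise should almost never split at alpha = 0.01
        split = 0
        for seed in range(25):
            rng = np.random.default_rng(5_000 + seed)
            x = rng.normal(1, 0.1, 200)
            split += len(segment.cbs_segment(x, np.repeat("chr1", 200),
                                             rng_seed=seed)) > 1
        assert split <= 2


class TestFitPloidy:
    def test_diploid_flat(self):
        assert segment.fit_ploidy(seg_set([1.0], [10])) == pytest.approx(2.0)

    def test_mostly_diploid_with_gain(self):
        assert segment.fit_ploidy(seg_set([1.0, 1.5], [90, 10])) == \
            pytest.approx(2.0)

    def test_triploid_exact_fit(self):
        assert segment.fit_ploidy(seg_set([1.0, 1.3333, 0.6667], [1, 1, 1])) \
            == pytest.approx(3.0)

    def test_tie_prefers_smallest(self):
        # ratio 1.0 fits every integer ploidy exactly; smallest grid value wins
        assert segment.fit_ploidy(seg_set([1.0], [5]),
                                  grid=np.array([2.0, 3.0, 4.0])) == 2.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            segment.fit_ploidy(seg_set([1.0], [5]), grid=np.array([]))

    def test_assign_copy_numbers(self):
        ss = segment.assign_copy_numbers(seg_set([1.0, 1.52], [90, 10]))
        assert ss.ploidy == pytest.approx(2.0)
        assert list(ss.df["cn_int"]) == [2, 3]


class TestThresholds:
    def test_disabled_derivation_returns_defaults(self):
        assert segment.derive_thresholds([], derive=False) == (1.29, 2.80)

    def test_three_cluster_derivation(self):
        rng = np.random.default_rng(1)
        cn = np.concatenate([rng.normal(1, 0.1, 40), rng.normal(2, 0.1, 200),
                             rng.normal(3, 0.1, 40)])
        ss = SegmentSet(pd.DataFrame({
            "chrom": "chr1", "start_bin": 0, "end_bin": 9, "n_bins": 10,
            "mean_ratio": cn / 2, "cn_est": cn, "cn_int": np.round(cn)}))
        loss, gain = segment.derive_thresholds([ss])
        assert 1.3 < loss < 1.9
        assert 2.1 < gain < 2.9

    def test_degenerate_all_diploid(self):
        cn = np.full(50, 2.0)
        ss = SegmentSet(pd.DataFrame({
            "chrom": "chr1", "start_bin": 0, "end_bin": 9, "n_bins": 10,
            "mean_ratio": cn / 2, "cn_est": cn, "cn_int": 2}))
        loss, gain = segment.derive_thresholds([ss], min_separation=0.3)
        assert loss == pytest.approx(1.7)
        assert gain == pytest.approx(2.3)

    def test_too_few_segments_falls_back(self):
        ss = SegmentSet(pd.DataFrame({
            "chrom": ["chr1"], "start_bin": [0], "end_bin": [9],
            "n_bins": [10], "mean_ratio": [1.0], "cn_est": [2.0],
            "cn_int": [2]}))
        with pytest.warns(UserWarning, match="too few"):
            assert segment.derive_thresholds([ss]) == (1.29, 2.80)

    def test_size_limits_filter_pool(self):
        # segments outside 5..127 bins must not influence the derivation
        cn = np.concatenate([np.full(30, 1.0), np.full(200, 2.0),
                             np.full(30, 3.0)])
        n_bins = np.full(len(cn), 10)
        n_bins[:30] = 200  # oversized: the whole sub-diploid mode drops out
        ss = SegmentSet(pd.DataFrame({
            "chrom": "chr1", "start_bin": 0, "end_bin": 9, "n_bins": n_bins,
            "mean_ratio": cn / 2, "cn_est": cn, "cn_int": np.round(cn)}))
        loss, gain = segment.derive_thresholds([ss], min_separation=0.3)
        assert loss == pytest.approx(1.7)  # fallback: no sub-diploid mode


class TestExtractCnvs:
    def bins(self):
        from scwga_cnv import coverage
        return coverage.build_bins([("chr1", 5_000_000)], "fixed", 500_000)

    def extract(self, cn_est, n_bins):
        ss = SegmentSet(pd.DataFrame({
            "chrom": ["chr1"], "start_bin": [0], "end_bin": [n_bins - 1],
            "n_bins": [n_bins], "mean_ratio": [cn_est / 2],
            "cn_est": [cn_est], "cn_int": [round(cn_est)]}), ploidy=2.0)
        return segment.extract_cnvs(ss, self.bins(), cell_id="c")

    def test_below_gain_threshold_not_called(self):
        assert len(self.extract(2.79, 10)) == 0

    def test_small_segment_not_called(self):
        assert len(self.extract(1.20, 4)) == 0

    def test_gain_called_with_coordinates(self):
        calls = self.extract(3.1, 6)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert row["type"] == "gain" and row["cn_int"] == 3
        assert row["start"] == 0 and row["end"] == 3_000_000

    def test_boundary_inclusive(self):
        assert len(self.extract(2.80, 10)) == 1
        assert len(self.extract(1.29, 10)) == 1

    def test_threshold_order_validated(self):
        with pytest.raises(ValueError):
            segment.extract_cnvs(seg_set([1.0], [10]), self.bins(),
                                 loss_thr=2.5, gain_thr=2.8)
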