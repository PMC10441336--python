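import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scwga_cnv import coverage


def track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


class TestBuildBins:
    def test_fixed_bins_cover_chromosome(self, four_bin_scheme):
        df = four_bin_scheme.df
        assert len(df) == 4
        assert list(df["start"]) == [0, 250_000, 500_000, 750_000]
        assert list(df["end"]) == [250_000, 500_000, 750_000, 1_000_000]

    def test_fixed_terminal_remainder(self):
        bins = coverage.build_bins([("chr1", 1_100_000)], "fixed", 250_000)
        assert list(bins.df["end"])[-1] == 1_100_000
        assert bins.widths[-1] == 100_000

    def test_uniform_mappability_matches_fixed(self):
        mp = track([("chr1", 0, 2_000_000, 1.0)])
        fixed = coverage.build_bins([("chr1", 2_000_000)], "fixed", 500_000)
        var = coverage.build_bins([("chr1", 2_000_000)], "variable", 500_000,
                                  mappability_track=mp)
        assert list(var.df["start"]) == list(fixed.df["start"])
        assert list(var.df["end"]) == list(fixed.df["end"])

    def test_variable_bins_skip_unmappable_sequence(self):
        # dead first half: the first bin must extend past it and still hold
        # a full fixed-bin's worth of mappable sequence
        mp = track([("chr1", 0, 500_000, 0.0), ("chr1", 500_000, 1_000_000, 1.0)])
        bins = coverage.build_bins([("chr1", 1_000_000)], "variable", 250_000,
                                   mappability_track=mp)
        first = bins.df.iloc[0]
        assert first["start"] == 0
        assert first["end"] >= 500_000 + 250_000

    def test_variable_bins_equalize_expected_counts(self):
        # Monte-Carlo oracle: uniform sampling of mappable positions must
        # load every (non-terminal) bin equally
        rng = np.random.default_rng(0)
        mp_rows = [("chr1", s, s + 100_000, float(v)) for s, v in
                   zip(range(0, 5_000_000, 100_000),
                       rng.choice([0.0, 0.5, 1.0], 50, p=[0.2, 0.3, 0.5]))]
        mp = track(mp_rows)
        bins = coverage.build_bins([("chr1", 5_000_000)], "variable", 500_000,
                                   mappability_track=mp)
        weights = np.concatenate([
            np.repeat(v, 100_000) for _, _, v in
            ((r[1], r[2], r[3]) for r in mp_rows)])
        positions = rng.choice(5_000_000, size=400_000,
                               p=weights / weights.sum())
        counts, _ = coverage.count_fragments(
            pd.DataFrame({"chrom": "chr1", "pos": positions}), bins)
        inner = counts[:-1]  # terminal remainder bin is short by design
        assert inner.std() / inner.mean() < 0.02

    def test_short_chromosome_single_bin_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than one bin"):
            bins = coverage.build_bins([("chrS", 90_000)], "fixed", 250_000)
        assert len(bins.df) == 1
        assert bins.df.iloc[0]["end"] == 90_000

    def test_invalid_modes(self):
        with pytest.raises(ValueError):
            coverage.build_bins([("chr1", 1_000_000)], "fixed", 0)
        with pytest.raises(ValueError):
            coverage.build_bins([("chr1", 1_000_000)], "variable", 250_000)


class TestCountFragments:
    def frags(self, positions, mqs=None):
        df = pd.DataFrame({"chrom": "chr1", "pos": positions})
        if mqs is not None:
            df["mq"] = mqs
        return df

    def test_basic_assignment(self, four_bin_scheme):
        counts, tally = coverage.count_fragments(
            self.frags([10_000, 260_000, 900_000]), four_bin_scheme)
        assert list(counts) == [1, 1, 0, 1]
        assert tally["counted"] == 3

    def test_mq_floor_drops_low_quality(self, four_bin_scheme):
        counts, tally = coverage.count_fragments(
            self.frags([10_000, 260_000, 900_000], [0, 10, 10]),
            four_bin_scheme, mq_min=10)
        assert list(counts) == [0, 1, 0, 1]
        assert tally["mq_filtered"] == 1

    def test_empty_input(self, four_bin_scheme):
        counts, _ = coverage.count_fragments(self.frags([]), four_bin_scheme)
        assert counts.sum() == 0

    def test_beyond_chromosome_end_tallied(self, four_bin_scheme):
        counts, tally = coverage.count_fragments(
            self.frags([500, 2_000_000]), four_bin_scheme)
        assert counts.sum() == 1
        assert tally["out_of_range"] == 1

    @given(st.lists(st.integers(min_value=-10_000, max_value=1_200_000),
                    max_size=60),
           st.integers(min_value=0, max_value=40))
    @settings(max_examples=30, deadline=None)
    def test_counting_conserves_fragments(self, positions, mq_min):
        bins = coverage.build_bins([("chr1", 1_000_000)], "fixed", 250_000)
        rng = np.random.default_rng(abs(hash((tuple(positions), mq_min))) % 2**31)
        mqs = rng.integers(0, 60, len(positions))
        counts, tally = coverage.count_fragments(
            self.frags(positions, mqs), bins, mq_min=mq_min)
        assert (counts.sum() + tally["mq_filtered"] + tally["out_of_range"]
                == len(positions))


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        ([100, 100, 100, 100], [1, 1, 1, 1]),
        ([2, 0, 2, 0], [2, 0, 2, 0]),
        ([10, 20, 30, 40], [0.4, 0.8, 1.2, 1.6]),
    ])
    def test_examples(self, raw, expected):
        assert coverage.normalize(np.array(raw)) == pytest.approx(expected)

    def test_autosomal_mean_is_one(self):
        rng = np.random.default_rng(1)
        raw = rng.poisson(100, 200).astype(float)
        auto = np.ones(200, bool)
        auto[150:] = False  # pretend a sex chromosome
        norm = coverage.normalize(raw, auto)
        assert norm[auto].mean() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_cell_flagged(self):
        with pytest.raises(ValueError, match="unusable"):
            coverage.normalize(np.zeros(10))


class TestGcCorrect:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.gc = np.clip(rng.normal(0.42, 0.05, 2_000), 0.3, 0.6)

    def test_flat_profile_unchanged(self):
        flat = np.ones_like(self.gc)
        corrected = coverage.gc_correct(flat, self.gc)
        assert np.abs(corrected - flat).max() < 0.02

    def test_linear_trend_divided_out(self):
        biased = 2.0 - self.gc
        biased = biased / biased.mean()
        corrected = coverage.gc_correct(biased, self.gc)
        assert np.abs(corrected - 1.0).max() < 0.05

    def test_reduces_gc_correlation(self):
        rng = np.random.default_rng(8)
        normalized = np.exp(-1.5 * (self.gc - 0.42)) * \
            np.exp(rng.normal(0, 0.1, len(self.gc)))
        normalized /= normalized.mean()
        corrected = coverage.gc_correct(normalized, self.gc)
        assert abs(np.corrcoef(corrected, self.gc)[0, 1]) < \
            abs(np.corrcoef(normalized, self.gc)[0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        normalized = np.exp(-1.0 * (self.gc - 0.42)) * \
            np.exp(rng.normal(0, 0.08, len(self.gc)))
        normalized /= normalized.mean()
        once = coverage.gc_correct(normalized, self.gc)
        twice = coverage.gc_correct(once, self.gc)
        assert np.abs(twice - once).max() < 1e-3 * np.abs(once).max() + 1e-2

    def test_few_gc_values_skips_with_warning(self):
        gc = np.repeat([0.4, 0.5], 10)
        vals = np.ones(20)
        with pytest.warns(UserWarning, match="skipped"):
            out = coverage.gc_correct(vals, gc)
        assert out == pytest.approx(vals)
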