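"""Circular binary segmentation, ploidy fitting and integer copy-number calls.

Segmentation follows the circular binary segmentation (CBS) scheme: within
each chromosome the most aberrant arc (contiguous run of bins compared
against the rest of the chromosome) is located by a maximal t-like
statistic, its significance is assessed against a permutation reference
distribution, and accepted change points are recursed on until no further
split is significant. Segmentation is *independent*: one cell and one
chromosome at a time, no joint multi-sample step.

Segment mean depth ratios are mapped to copy numbers by a grid search for
the ploidy multiplier that brings all segments closest to integers
(``fit_ploidy``), and gains/losses are then called against copy-number
thresholds that are either configured (defaults 1.29 loss / 2.80 gain) or
derived from the pooled segment CN distribution of all QC-passed cells
(``derive_thresholds``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta

from ._util import child_rng

SEGMENT_COLUMNS = ["chrom", "start_bin", "end_bin", "n_bins",
                   "mean_ratio", "cn_est", "cn_int"]
CALL_COLUMNS = ["chrom", "start", "end", "type", "cn_int", "cn_est",
                "n_bins", "cell_id", "individual_id", "method"]

#: configured gain/loss thresholds on estimated copy number
DEFAULT_LOSS_THR = 1.29
DEFAULT_GAIN_THR = 2.80


@dataclass
class SegmentSet:
    """Per-cell segmentation: one row per segment, bin indices inclusive.

    ``start_bin``/``end_bin`` index into the cell's BinScheme; ``mean_ratio``
    is the mean corrected depth ratio of the segment; ``cn_est`` and
    ``cn_int`` are filled once a ploidy has been fitted.
    """

    df: pd.DataFrame
    ploidy: float | None = None

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# the arc statistic


def _arc_masks(n: int, min_width: int) -> dict[int, np.ndarray]:
    """Valid arc start indices per arc length.

    An arc (i, j) of length k = j - i is admissible when the arc and its
    complement both hold at least ``min_width`` bins and neither flank left
    by an interior cut is shorter than ``min_width``.
    """
    masks = {}
    for k in range(min_width, n - min_width + 1):
        i = np.arange(n - k + 1)
        j = i + k
        ok = ((i == 0) | (i >= min_width)) & ((j == n) | (j <= n - min_width))
        if ok.any():
            masks[k] = ok
    return masks


def _max_arc_stat(batch: np.ndarray, masks: dict[int, np.ndarray],
                  want_argmax: bool = False):
    """Maximal |mean(arc) - mean(rest)| / sqrt(1/k + 1/(n-k)) per row.

    ``batch`` has shape (B, n). The overall SD is permutation-invariant so it
    is dropped from the statistic. Returns the per-row maxima and, when
    requested, the (i, j) achieving the maximum for the first row.
    """
    B, n = batch.shape
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(batch, axis=1)], axis=1)
    T = S[:, -1:]
    best = np.full(B, -np.inf)
    arg = (0, n)
    for k, mask in masks.items():
        d = S[:, k:] - S[:, :-k]
        stat = np.abs(d / k - (T - d) / (n - k)) / math.sqrt(1.0 / k + 1.0 / (n - k))
        stat[:, ~mask] = -np.inf
        row_max = stat.max(axis=1)
        if want_argmax and row_max[0] > best[0]:
            arg = (int(stat[0].argmax()), int(stat[0].argmax()) + k)
        best = np.maximum(best, row_max)
    return (best, arg) if want_argmax else (best, None)


def _permutation_test(x: np.ndarray, obs: float, masks: dict[int, np.ndarray],
                      alpha: float, n_perm: int, rng: np.random.Generator,
                      batch: int = 256) -> tuple[bool, float]:
    """Sequential permutation p-value for the observed maximal arc statistic.

    Permutations run in fixed-size batches with two early-stopping rules:
    stop 'not significant' once the exceedance count already forces
    p >= alpha, and stop 'significant' once the 99.9% Clopper-Pearson upper
    bound on p drops below alpha. Batch order is deterministic given the
    generator, so results are reproducible.
    """
    c_stop = math.ceil(alpha * (n_perm + 1))
    c = m = 0
    while m < n_perm:
        b = min(batch, n_perm - m)
        perms = rng.permuted(np.broadcast_to(x, (b, len(x))).copy(), axis=1)
        stats, _ = _max_arc_stat(perms, masks)
        c += int((stats >= obs - 1e-12).sum())
        m += b
        if c >= c_stop:
            return False, (1 + c) / (1 + m)
        if m >= 500:
            upper = beta.ppf(0.999, c + 1, m - c)
            if upper < alpha:
                return True, (1 + c) / (1 + m)
    p = (1 + c) / (1 + n_perm)
    return p < alpha, p


def _segment_chrom(x: np.ndarray, alpha: float, min_width: int,
                   n_perm: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns half-open (start, end) runs."""
    segments: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2 * min_width:
            segments.append((lo, hi))
            continue
        sub = x[lo:hi]
        if np.ptp(sub) < 1e-12:  # constant segment: nothing to split
            segments.append((lo, hi))
            continue
        masks = _arc_masks(n, min_width)
        obs_arr, (i, j) = _max_arc_stat(sub[None, :], masks, want_argmax=True)
        significant, _ = _permutation_test(sub, float(obs_arr[0]), masks,
                                           alpha, n_perm, rng)
        if not significant:
            segments.append((lo, hi))
            continue
        cuts = [lo] + [lo + c for c in (i, j) if 0 < c < n] + [hi]
        # push right-to-left so parts are processed left-to-right
        for a, b in reversed(list(zip(cuts[:-1], cuts[1:]))):
            stack.append((a, b))
    return sorted(segments)


def _merge_segments(segs: list[tuple[int, int]], x: np.ndarray,
                    merge_delta: float) -> list[tuple[int, int]]:
    """Merge adjacent segments whose means differ by less than merge_delta."""
    segs = list(segs)
    while len(segs) > 1:
        means = [x[a:b].mean() for a, b in segs]
        gaps = [abs(means[i + 1] - means[i]) for i in range(len(segs) - 1)]
        i = int(np.argmin(gaps))
        if gaps[i] >= merge_delta:
            break
        segs[i] = (segs[i][0], segs[i + 1][1])
        del segs[i + 1]
    return segs


def cbs_segment(values: np.ndarray, chrom_labels: np.ndarray,
                alpha: float = 0.01, min_width: int = 5,
                n_perm: int = 10_000, rng_seed: int = 1,
                merge_delta: float = 0.05) -> SegmentSet:
    """Segment a per-bin depth-ratio profile chromosome by chromosome.

    A split is accepted when its permutation p-value is below ``alpha`` and
    every resulting segment holds at least ``min_width`` bins; chromosomes
    shorter than ``2 * min_width`` bins become a single segment. Adjacent
    segments whose means differ by less than ``merge_delta`` are merged
    afterwards (a surrogate for CBS split-undoing). Deterministic given
    ``rng_seed``.
    """
    values = np.asarray(values, dtype=float)
    chrom_labels = np.asarray(chrom_labels)
    if len(values) != len(chrom_labels):
        raise ValueError("values and chrom_labels must align")
    rows = []
    for chrom in dict.fromkeys(chrom_labels):
        idx = np.flatnonzero(chrom_labels == chrom)
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        x = values[lo:hi]
        rng = child_rng(rng_seed, "cbs", str(chrom))
        segs = _segment_chrom(x, alpha, min_width, n_perm, rng)
        segs = _merge_segments(segs, x, merge_delta)
        for a, b in segs:
            rows.append((chrom, lo + a, lo + b - 1, b - a,
                         float(x[a:b].mean()), np.nan, np.nan))
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return SegmentSet(df)


# ---------------------------------------------------------------------------
# ploidy and copy number


def fit_ploidy(segments: SegmentSet, grid: np.ndarray | None = None) -> float:
    """Grid-search the ploidy multiplier mapping segment ratios to integers.

    Minimizes the n_bins-weighted sum of squared distances of
    ``mean_ratio * p`` from the nearest integer over the candidate grid
    (default 1.5–5.5 in steps of 0.05); ties go to the smallest ploidy.
    """
    if len(segments) == 0:
        raise ValueError("cannot fit ploidy on an empty segmentation")
    if grid is None:
        grid = np.arange(1.5, 5.5 + 1e-9, 0.05)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty ploidy grid")
    r = segments.df["mean_ratio"].to_numpy()[:, None]
    w = segments.df["n_bins"].to_numpy(dtype=float)[:, None]
    cn = r * grid[None, :]
    obj = (w * (cn - np.round(cn)) ** 2).sum(axis=0)
    best = obj.min()
    return float(grid[np.flatnonzero(obj <= best + 1e-12)[0]])


def assign_copy_numbers(segments: SegmentSet, ploidy: float | None = None,
                        grid: np.ndarray | None = None) -> SegmentSet:
    """Fill cn_est = mean_ratio * ploidy and its integer rounding."""
    if ploidy is None:
        ploidy = fit_ploidy(segments, grid)
    df = segments.df.copy()
    df["cn_est"] = df["mean_ratio"] * ploidy
    df["cn_int"] = np.round(df["cn_est"]).astype(int)
    return SegmentSet(df, ploidy=float(ploidy))


def derive_thresholds(segment_sets, min_bins: int = 5, max_bins: int = 127,
                      defaults: tuple[float, float] = (DEFAULT_LOSS_THR,
                                                      DEFAULT_GAIN_THR),
                      derive: bool = True, min_separation: float = 0.3,
                      min_segments: int = 20) -> tuple[float, float]:
    """Gain/loss CN thresholds from the pooled segment CN distribution.

    Pools ``cn_est`` of segments with ``min_bins <= n_bins <= max_bins``
    (the upper limit mirrors excluding segments larger than the smallest
    chromosome) across all QC-passed cells, then places each threshold in
    the quantile gap between the diploid mode and the adjacent CN-1 / CN-3
    mode: the midpoint of the 99.5th percentile of the outer mode and the
    0.5th percentile of the diploid mode (falling back to the half-distance
    between mode medians when the quantile gap is inverted). A missing outer
    mode yields 2 -/+ ``min_separation``. With ``derive=False`` or too few
    eligible segments the configured ``defaults`` are returned.
    """
    if not derive:
        return defaults
    frames = [s.df if hasattr(s, "df") else s for s in segment_sets]
    pooled = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if len(pooled):
        keep = (pooled["n_bins"] >= min_bins) & (pooled["n_bins"] <= max_bins)
        cn = pooled.loc[keep, "cn_est"].dropna().to_numpy()
    else:
        cn = np.array([])
    if len(cn) < min_segments:
        warnings.warn("too few eligible segments to derive thresholds; "
                      "using configured defaults")
        return defaults
    sub = cn[cn < 1.5]
    dip = cn[(cn >= 1.5) & (cn < 2.5)]
    supra = cn[cn >= 2.5]

    def _cut(outer, inner, q_outer, q_inner, fallback):
        if len(outer) == 0 or len(inner) == 0:
            return fallback
        qo, qi = np.quantile(outer, q_outer), np.quantile(inner, q_inner)
        if (qo - qi) * (np.median(outer) - np.median(inner)) > 0:
            # modes separate cleanly: cut at the midpoint of the quantile gap
            return 0.5 * (qo + qi)
        # overlapping modes: fall back to the half-distance between medians
        return 0.5 * (np.median(outer) + np.median(inner))

    loss = _cut(sub, dip, 0.995, 0.005, 2.0 - min_separation)
    gain = _cut(supra, dip, 0.005, 0.995, 2.0 + min_separation)
    return float(min(loss, 2.0 - 0.01)), float(max(gain, 2.0 + 0.01))


def extract_cnvs(segments: SegmentSet, bins, loss_thr: float = DEFAULT_LOSS_THR,
                 gain_thr: float = DEFAULT_GAIN_THR, min_bins: int = 5,
                 cell_id: str = "", individual_id: str = "",
                 method: str = "") -> pd.DataFrame:
    """Turn aberrant segments into CNV calls with base-pair coordinates.

    A segment becomes a call iff its CN estimate is <= ``loss_thr`` or
    >= ``gain_thr`` (both inclusive) and it spans at least ``min_bins`` bins.
    """
    if not (loss_thr < 2.0 < gain_thr):
        raise ValueError("thresholds must satisfy loss_thr < 2 < gain_thr")
    df = segments.df
    if df["cn_est"].isna().any():
        raise ValueError("assign_copy_numbers must run before extract_cnvs")
    starts = bins.df["start"].to_numpy()
    ends = bins.df["end"].to_numpy()
    rows = []
    for seg in df.itertuples(index=False):
        if seg.n_bins < min_bins:
            continue
        if seg.cn_est <= loss_thr:
            kind = "loss"
        elif seg.cn_est >= gain_thr:
            kind = "gain"
        else:
            continue
        rows.append((seg.chrom, int(starts[seg.start_bin]),
                     int(ends[seg.end_bin]), kind, int(seg.cn_int),
                     float(seg.cn_est), int(seg.n_bins),
                     cell_id, individual_id, method))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
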