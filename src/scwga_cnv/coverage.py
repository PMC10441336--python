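"""Read-depth preprocessing: genomic bins, fragment counting, normalization, GC correction.

The unit of analysis is a *bin*: a genomic interval into which aligned
fragments are counted. Bins are either fixed-width or variable-width; a
variable-width scheme allocates an equal amount of mappable sequence to each
bin so that, under uniform sampling of mappable positions, every bin has the
same expected count. Per-cell counts are normalized to a mean of one across
autosomal bins and then corrected for coverage-vs-GC trends with a locally
weighted regression.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._util import autosome_mask

BIN_COLUMNS = ["chrom", "start", "end", "gc", "mappability"]


@dataclass
class BinScheme:
    """Ordered, non-overlapping genomic bins with GC and mappability annotation.

    ``df`` has columns chrom, start, end, gc, mappability; bins are sorted
    within each chromosome, contiguous blocks per chromosome, and half-open.
    """

    df: pd.DataFrame
    bin_size_label: str = ""

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        missing = [c for c in BIN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"bin table missing columns: {missing}")
        if (df["end"] <= df["start"]).any():
            raise ValueError("bins must have end > start")
        for col in ("gc", "mappability"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        for _, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValueError("bins overlap or are unsorted within a chromosome")
        self.df = df

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    @property
    def chrom_labels(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def autosomal(self) -> np.ndarray:
        return autosome_mask(self.df["chrom"])

    @property
    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.df["chrom"].to_numpy() == chrom)
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_bed(self, path) -> None:
        """Write as BED plus gc and mappability columns."""
        self.df.to_csv(path, sep="\t", header=False, index=False,
                       float_format="%.6g")

    @classmethod
    def from_bed(cls, path, bin_size_label: str = "") -> "BinScheme":
        df = pd.read_csv(path, sep="\t", header=None, names=BIN_COLUMNS,
                         dtype={"chrom": str})
        return cls(df, bin_size_label)


@dataclass
class CellProfile:
    """Per-bin read depth of one cell at the raw / normalized / corrected stages."""

    cell_id: str
    individual_id: str
    method: str
    raw: np.ndarray
    normalized: np.ndarray | None = None
    corrected: np.ndarray | None = None
    qc_tally: dict = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        return bool(np.any(self.raw > 0))


def _track_to_arrays(track: pd.DataFrame, chrom: str, chrom_len: int):
    """Piecewise-constant track for one chromosome as breakpoints + values.

    ``track`` is a BED-like frame (chrom, start, end, value). Gaps are filled
    with value 0; intervals are clipped to [0, chrom_len).
    """
    sub = track[track["chrom"] == chrom].sort_values("start")
    edges = [0]
    values = []
    pos = 0
    for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
        start, end = max(0, int(start)), min(chrom_len, int(end))
        if end <= pos:
            continue
        if start > pos:
            edges.append(start)
            values.append(0.0)
            pos = start
        edges.append(end)
        values.append(float(value))
        pos = end
    if pos < chrom_len:
        edges.append(chrom_len)
        values.append(0.0)
    return np.asarray(edges, dtype=float), np.asarray(values, dtype=float)


def _mean_over(edges, values, start, end) -> float:
    lengths = np.clip(np.minimum(edges[1:], end) - np.maximum(edges[:-1], start),
                      0, None)
    span = end - start
    return float(np.dot(lengths, values) / span) if span > 0 else 0.0


def build_bins(chrom_lengths, mode: str = "fixed", size_bp: int = 500_000,
               mappability_track: pd.DataFrame | None = None,
               gc_track: pd.DataFrame | None = None,
               bin_size_label: str | None = None) -> BinScheme:
    """Partition a genome into fixed- or variable-width bins.

    Parameters
    ----------
    chrom_lengths : sequence of (chrom, length) or mapping chrom -> length
    mode : 'fixed' or 'variable'
        Fixed bins are ``size_bp`` wide except for a chromosome-terminal
        remainder. Variable bins each hold the same mappable mass, namely
        ``size_bp`` times the mean mappability of mappable (non-zero)
        positions, so every variable bin carries the read capacity of a fully
        mappable fixed bin.
    mappability_track, gc_track : BED-like frames (chrom, start, end, value)
        The mappability track is required in variable mode. Bin GC is the
        length-weighted mean of the GC track over the bin (0.5 when absent).
    """
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    if mode not in ("fixed", "variable"):
        raise ValueError(f"unknown binning mode: {mode!r}")
    if mode == "variable" and mappability_track is None:
        raise ValueError("variable mode requires a mappability track")
    items = list(chrom_lengths.items()) if hasattr(chrom_lengths, "items") \
        else list(chrom_lengths)

    if mode == "variable":
        # target mass per bin: size_bp scaled by the mean mappability of
        # positions that are mappable at all
        tot_mass = tot_len = 0.0
        for chrom, length in items:
            edges, values = _track_to_arrays(mappability_track, chrom, int(length))
            seg = np.diff(edges)
            tot_mass += float(np.dot(seg, values))
            tot_len += float(seg[values > 0].sum())
        if tot_mass <= 0:
            raise ValueError("mappability track has no mappable sequence")
        target_mass = size_bp * (tot_mass / tot_len)

    rows = []
    for chrom, length in items:
        length = int(length)
        if mode == "fixed":
            starts = np.arange(0, length, size_bp)
            ends = np.minimum(starts + size_bp, length)
            if length < size_bp:
                warnings.warn(f"{chrom} shorter than one bin; using a single "
                              "whole-chromosome bin")
        else:
            edges, values = _track_to_arrays(mappability_track, chrom, length)
            seg_mass = np.diff(edges) * values
            cum = np.concatenate([[0.0], np.cumsum(seg_mass)])
            total = cum[-1]
            n_full = int(total // target_mass)
            cuts = [0]
            for k in range(1, n_full + 1):
                # position where cumulative mass reaches k*target_mass
                j = int(np.searchsorted(cum, k * target_mass, side="left"))
                j = min(j, len(edges) - 1)
                deficit = k * target_mass - cum[j - 1]
                pos = edges[j - 1] + (deficit / values[j - 1] if values[j - 1] > 0
                                      else 0.0)
                cuts.append(int(round(pos)))
            if cuts[-1] < length:
                cuts.append(length)
            starts = np.asarray(cuts[:-1])
            ends = np.asarray(cuts[1:])
            keep = ends > starts
            starts, ends = starts[keep], ends[keep]
            if len(starts) == 0:
                warnings.warn(f"{chrom} shorter than one bin; using a single "
                              "whole-chromosome bin")
                starts, ends = np.array([0]), np.array([length])
        gc_arrays = None
        if gc_track is not None:
            gc_arrays = _track_to_arrays(gc_track, chrom, length)
        map_arrays = None
        if mappability_track is not None:
            map_arrays = _track_to_arrays(mappability_track, chrom, length)
        for s, e in zip(starts, ends):
            gc = _mean_over(*gc_arrays, s, e) if gc_arrays else 0.5
            mp = _mean_over(*map_arrays, s, e) if map_arrays else 1.0
            rows.append((chrom, int(s), int(e), gc, mp))

    label = bin_size_label or f"{size_bp // 1000} kb"
    return BinScheme(pd.DataFrame(rows, columns=BIN_COLUMNS), label)


def count_fragments(fragments: pd.DataFrame, bins: BinScheme,
                    mq_min: int = 0) -> tuple[np.ndarray, dict]:
    """Count fragments per bin by leftmost mapped position, with a MAPQ floor.

    ``fragments`` needs columns chrom and pos; an optional mq column is
    compared against ``mq_min`` (fragments below it are excluded). Returns
    (counts, tally) where the tally records how many fragments were dropped
    by the MAPQ filter or fell outside the bin scheme.
    """
    if mq_min < 0:
        raise ValueError("mq_min must be >= 0")
    counts = np.zeros(bins.n_bins, dtype=np.int64)
    tally = {"mq_filtered": 0, "out_of_range": 0, "counted": 0}
    if len(fragments) == 0:
        return counts, tally
    frags = fragments
    if "mq" in frags.columns and mq_min > 0:
        keep = frags["mq"].to_numpy() >= mq_min
        tally["mq_filtered"] = int((~keep).sum())
        frags = frags.loc[keep]
    for chrom, sub in frags.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        try:
            sl = bins.chrom_slice(str(chrom))
        except KeyError:
            tally["out_of_range"] += len(sub)
            continue
        starts = bins.df["start"].to_numpy()[sl]
        ends = bins.df["end"].to_numpy()[sl]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos >= 0)
        in_bin = np.zeros(len(pos), dtype=bool)
        in_bin[ok] = pos[ok] < ends[idx[ok]]
        tally["out_of_range"] += int((~in_bin).sum())
        np.add.at(counts[sl], idx[in_bin], 1)
    tally["counted"] = int(counts.sum())
    return counts, tally


def normalize(raw: np.ndarray, autosomal: np.ndarray | None = None) -> np.ndarray:
    """Scale raw counts so the mean over autosomal bins is one.

    All bins (sex chromosomes included) are divided by the autosomal mean;
    sex-chromosome values are therefore on the same diploid-relative scale.
    """
    raw = np.asarray(raw, dtype=float)
    mask = np.ones(len(raw), bool) if autosomal is None else np.asarray(autosomal)
    mean = raw[mask].mean() if mask.any() else 0.0
    if mean <= 0:
        raise ValueError("cell has no autosomal reads; unusable for normalization")
    return raw / mean


def gc_correct(normalized: np.ndarray, gc: np.ndarray,
               smoother_fraction: float = 0.05, iterations: int = 3,
               autosomal: np.ndarray | None = None) -> np.ndarray:
    """Remove the coverage-vs-GC trend by dividing out a LOWESS fit.

    The locally weighted regression of normalized depth on bin GC is fitted
    on autosomal bins and evaluated at every bin's GC; corrected depth is
    normalized / fitted, rescaled to autosomal mean one. With fewer than 10
    distinct GC values the correction is skipped (identity, with a warning).
    """
    normalized = np.asarray(normalized, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if len(gc) != len(normalized):
        raise ValueError("gc must be known for every bin")
    mask = np.ones(len(gc), bool) if autosomal is None else np.asarray(autosomal)
    if len(np.unique(gc[mask])) < 10:
        warnings.warn("fewer than 10 distinct GC values; GC correction skipped")
        return normalized.copy()
    # keep the local window at >= ~20 points so small bin sets stay smooth
    frac = min(1.0, max(smoother_fraction, 20.0 / max(int(mask.sum()), 1)))
    fitted = lowess(normalized[mask], gc[mask], frac=frac,
                    it=iterations, xvals=gc)
    fitted = np.clip(fitted, 0.05, None)
    corrected = normalized / fitted
    mean = corrected[mask].mean()
    if mean <= 0:
        raise ValueError("GC correction produced a zero-mean profile")
    return corrected / mean


def make_profile(cell_id: str, individual_id: str, method: str,
                 raw: np.ndarray, bins: BinScheme,
                 smoother_fraction: float = 0.05) -> CellProfile:
    """Raw counts -> normalized -> GC-corrected profile for one cell."""
    auto = bins.autosomal
    profile = CellProfile(cell_id, individual_id, method, np.asarray(raw))
    profile.normalized = normalize(profile.raw, auto)
    profile.corrected = gc_correct(profile.normalized, bins.df["gc"].to_numpy(),
                                   smoother_fraction, autosomal=auto)
    return profile
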