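"""Multi-cell artifact filtering and genomic annotation of CNV calls.

Recurrent calls are suspect: an event shared by half the cells of an
individual, or appearing in more than one individual, is far more likely a
germline variant or a systematic wet/dry-lab artifact than an independent
somatic event, and is removed. Sharing is defined by boundary proximity
(both endpoints within a per-chemistry tolerance) with transitive closure.
Remaining calls can be annotated as subtelomeric, as whole-chromosome
aneusomies, or as lying mostly in reference-specific novel sequence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: boundary tolerance for call sharing, per amplification method (bp)
DEFAULT_TOLERANCES = {"picoplex": 2_500_000, "pta": 5_000_000}


def _union_find(n: int):
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    return find, union


def match_shared(calls: pd.DataFrame,
                 tolerances: dict[str, int] | None = None,
                 default_tol: int = 2_500_000) -> pd.DataFrame:
    """Group calls shared across cells; adds a ``group`` column.

    Two calls are linked when they sit on the same chromosome, have the same
    type, and both |Δstart| and |Δend| are within the tolerance — the larger
    of the two cells' method tolerances when methods differ. Groups are the
    transitive closure of pairwise links, labelled by the smallest original
    index they contain, so the grouping is independent of input order.
    """
    tolerances = DEFAULT_TOLERANCES if tolerances is None else tolerances
    calls = calls.reset_index(drop=True)
    n = len(calls)
    find, union = _union_find(n)
    starts = calls["start"].to_numpy()
    ends = calls["end"].to_numpy()
    chroms = calls["chrom"].to_numpy()
    types = calls["type"].to_numpy()
    tols = np.array([tolerances.get(m, default_tol)
                     for m in calls.get("method", pd.Series([""] * n))])
    for i in range(n):
        for j in range(i + 1, n):
            if chroms[i] != chroms[j] or types[i] != types[j]:
                continue
            tol = max(tols[i], tols[j])
            if abs(starts[i] - starts[j]) <= tol and \
                    abs(ends[i] - ends[j]) <= tol:
                union(i, j)
    out = calls.copy()
    out["group"] = [find(i) for i in range(n)]
    return out


def filter_artifacts(grouped: pd.DataFrame,
                     n_cells_per_individual: dict[str, int],
                     share_fraction: float = 0.5) -> pd.DataFrame:
    """Drop call groups recurrent within or across individuals.

    A group is removed entirely when its calls span at least two
    individuals, or when its distinct carrier cells make up at least
    ``share_fraction`` of the QC-passed cells of its (single) individual.
    """
    if "group" not in grouped.columns:
        raise ValueError("run match_shared first (missing 'group' column)")
    drop_groups = set()
    for gid, sub in grouped.groupby("group"):
        individuals = set(sub["individual_id"])
        if len(individuals) >= 2:
            drop_groups.add(gid)
            continue
        (individual,) = individuals
        n_cells = n_cells_per_individual.get(individual)
        if n_cells is None:
            raise KeyError(f"no cell count for individual {individual!r}")
        if sub["cell_id"].nunique() >= share_fraction * n_cells:
            drop_groups.add(gid)
    return grouped[~grouped["group"].isin(drop_groups)].reset_index(drop=True)


def annotate_subtelomeric(calls: pd.DataFrame, chrom_lengths,
                          window_bp: int) -> pd.DataFrame:
    """Flag calls whose boundary lies within ``window_bp`` of a chromosome end."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    lengths = dict(chrom_lengths) if not hasattr(chrom_lengths, "get") \
        else chrom_lengths
    out = calls.copy()
    flags = []
    for row in out.itertuples(index=False):
        chrom_len = lengths[row.chrom]
        flags.append(row.start < window_bp or row.end > chrom_len - window_bp)
    out["subtelomeric"] = flags
    return out


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    merged = []
    for s, e in iv:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def novel_region_gains(calls: pd.DataFrame, novel_bed: pd.DataFrame,
                       min_overlap_frac: float = 0.5) -> pd.DataFrame:
    """Calls whose span lies mostly (>= min_overlap_frac) in novel sequence.

    ``novel_bed`` holds the regions unique to one reference (chrom, start,
    end); overlap is measured against the *union* of those intervals, so a
    call straddling several novel regions accumulates their overlap.
    """
    for col in ("chrom", "start", "end"):
        if col not in novel_bed.columns:
            raise ValueError(f"novel-region BED missing column {col!r}")
    if (novel_bed["end"] <= novel_bed["start"]).any():
        raise ValueError("novel-region BED has intervals with end <= start")
    by_chrom = {c: _merge_intervals(list(zip(sub["start"], sub["end"])))
                for c, sub in novel_bed.groupby("chrom")}
    keep = []
    for row in calls.itertuples():
        span = row.end - row.start
        overlap = sum(max(0, min(row.end, e) - max(row.start, s))
                      for s, e in by_chrom.get(row.chrom, []))
        keep.append(overlap >= min_overlap_frac * span)
    return calls[np.asarray(keep, bool)].reset_index(drop=True)


def aneusomy_check(calls: pd.DataFrame, chrom_lengths,
                   min_fraction: float = 0.95) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promote near-complete chromosome coverage to whole-chromosome events.

    For each cell and chromosome, when calls of one type jointly cover at
    least ``min_fraction`` of the chromosome, the partial calls are replaced
    by a single whole-chromosome gain/loss. Returns (aneusomies, calls) where
    ``calls`` contains the replacement events in place of the merged partial
    ones.
    """
    lengths = dict(chrom_lengths) if not hasattr(chrom_lengths, "get") \
        else chrom_lengths
    aneusomies = []
    drop_idx = []
    replacement_rows = []
    for (cell, chrom, kind), sub in calls.groupby(
            ["cell_id", "chrom", "type"]):
        chrom_len = lengths[chrom]
        covered = sum(e - s for s, e in
                      _merge_intervals(list(zip(sub["start"], sub["end"]))))
        if covered >= min_fraction * chrom_len:
            drop_idx.extend(sub.index)
            row = sub.iloc[0].copy()
            row["start"], row["end"] = 0, chrom_len
            row["n_bins"] = int(sub["n_bins"].sum())
            aneusomies.append(row)
            replacement_rows.append(row)
    aneus_df = pd.DataFrame(aneusomies).reset_index(drop=True)
    out = calls.drop(index=drop_idx)
    if replacement_rows:
        out = pd.concat([out, pd.DataFrame(replacement_rows)],
                        ignore_index=True)
    return aneus_df, out.reset_index(drop=True)
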