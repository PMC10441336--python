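"""Per-cell amplification-quality metrics and the QC gate for CNV calling.

Whole-genome amplification is uneven; cells whose read depth fluctuates too
much between neighbouring bins, or whose segments sit between integer copy
numbers, produce unreliable copy-number calls and are excluded. Three
metrics drive the gate:

* MAD — scaled median absolute deviation of the differences between
  neighbouring normalized bin counts. A robust per-cell evenness score that
  is insensitive to genuine copy-number steps.
* Gini / Lorenz curve — global coverage-uniformity summary: the cumulative
  fraction of reads as a function of the cumulative fraction of the genome.
* Confidence score — how close segment copy-number estimates are to
  integers, weighted by segment length. The exact formula used here is this
  package's reconstruction (see docs/methods.md); it maps a segment exactly
  halfway between integers to 0 and an exact integer to 1.

Default gate: MAD <= 0.3 and confidence >= 0.7, both boundaries inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import autosome_mask

#: consistency constant making the MAD of Gaussian data estimate its SD
#: (the R default; switchable in compute_mad)
MAD_CONSTANT = 1.4826


@dataclass
class QcReport:
    cell_id: str
    mad: float
    gini: float
    confidence: float
    passes: bool


def compute_mad(values: np.ndarray, chrom: np.ndarray | None = None,
                constant: float = MAD_CONSTANT) -> float:
    """Scaled MAD of neighbouring-bin differences.

    ``values`` are normalized (or corrected) per-bin depths, already
    restricted to the bins the score should cover (conventionally the
    autosomes). Differences are taken within chromosomes only — pass
    ``chrom`` labels to suppress the spurious jump at each chromosome
    boundary. Returns ``median(|d - median(d)|) * constant`` over the
    pooled differences.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("MAD requires at least 3 bins")
    if chrom is None:
        diffs = np.diff(values)
    else:
        chrom = np.asarray(chrom)
        same = chrom[1:] == chrom[:-1]
        diffs = np.diff(values)[same]
    if len(diffs) == 0:
        raise ValueError("no within-chromosome neighbour pairs")
    return float(np.median(np.abs(diffs - np.median(diffs))) * constant)


def lorenz_curve(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Lorenz curve of per-bin depth and its Gini coefficient.

    Bins are sorted by increasing depth; the curve gives the cumulative
    fraction of reads against the cumulative fraction of bins. Uniform depth
    yields the diagonal and Gini 0; concentrating all reads in one of n bins
    approaches Gini (n-1)/n.
    """
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValueError("depth values must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero profile has no Lorenz curve")
    srt = np.sort(values)
    x = np.arange(len(values) + 1) / len(values)
    y = np.concatenate([[0.0], np.cumsum(srt) / total])
    auc = float(np.trapezoid(y, x))
    return x, y, 1.0 - 2.0 * auc


def confidence_score(segments) -> float:
    """Length-weighted closeness of autosomal segment CN estimates to integers.

    ``segments`` is a SegmentSet (or its frame) with per-segment ``cn_est``
    and ``n_bins``. Each segment scores max(0, 1 - 2*|cn_est - round(cn_est)|);
    the cell score is the n_bins-weighted mean over autosomal segments.
    """
    df = segments.df if hasattr(segments, "df") else segments
    if len(df) == 0:
        raise ValueError("empty segmentation")
    auto = autosome_mask(df["chrom"]) if "chrom" in df.columns \
        else np.ones(len(df), bool)
    sub = df.loc[auto]
    if len(sub) == 0:
        raise ValueError("no autosomal segments")
    cn = sub["cn_est"].to_numpy(dtype=float)
    w = sub["n_bins"].to_numpy(dtype=float)
    score = np.maximum(0.0, 1.0 - 2.0 * np.abs(cn - np.round(cn)))
    return float(np.average(score, weights=w))


def qc_gate(report: QcReport, mad_max: float = 0.3,
            conf_min: float = 0.7) -> bool:
    """Cell passes iff MAD <= mad_max and confidence >= conf_min (inclusive)."""
    return bool(report.mad <= mad_max and report.confidence >= conf_min)


def qc_cell(cell_id: str, corrected: np.ndarray, bins, segments=None,
            mad_max: float = 0.3, conf_min: float = 0.7) -> QcReport:
    """Assemble a QcReport from a corrected profile (autosomes only for MAD/Gini)."""
    auto = bins.autosomal
    mad = compute_mad(corrected[auto], bins.chrom_labels[auto])
    _, _, gini = lorenz_curve(corrected[auto])
    conf = confidence_score(segments) if segments is not None else 1.0
    report = QcReport(cell_id, mad, gini, conf, False)
    report.passes = qc_gate(report, mad_max, conf_min)
    return report


def qc_table(reports: list[QcReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
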