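"""Cohort-level summaries and group-comparison statistics.

The per-cohort summary mirrors the conventional success-rate table of a
single-cell CNV study: per individual and chemistry, the fraction of cells
passing QC, the fraction of QC-passed cells carrying at least one retained
CNV, and gain/loss call counts, plus cohort-wide roll-ups. Group
comparisons use Fisher's exact test (2x2 proportions) and the
Mann-Whitney rank-sum test (CNV sizes), both two-sided.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers.

    Uses the probability-based two-sided rule (as R's fisher.test): sum the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed that of the observed table, with a
    (1 + 1e-7) tolerance factor. A zero margin yields p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or (t < 0).any():
            raise ValueError("table entries must be non-negative integers")
        t = np.round(t).astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1 by convention")
        return 1.0
    k = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = hypergeom.pmf(k, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def rank_sum(a, b) -> float:
    """Two-sided Mann-Whitney p-value for two samples of sizes (e.g. CNV Mb).

    Exact null distribution when the samples are tie-free and small
    (n1 * n2 <= 400); otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0 or len(a) + len(b) < 2:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(a) * len(b) <= 400:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.pvalue)


def u_statistic(a, b) -> float:
    """Mann-Whitney U of sample a versus b (ties counted half)."""
    a = np.asarray(a, dtype=float)[:, None]
    b = np.asarray(b, dtype=float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def rollup_counts(n_passed: int, n_cnv_cells: int, n_calls: int,
                  n_gains: int) -> dict[str, float]:
    """Cohort roll-up percentages recomputed from integer counts.

    Returns the fraction of QC-passed cells with at least one CNV, the gain
    fraction among calls, and the mean number of calls per CNV-bearing cell,
    as percentages / plain ratios on the scale a summary table prints.
    """
    return {
        "pct_cells_with_cnv": 100.0 * n_cnv_cells / n_passed if n_passed else 0.0,
        "pct_gains": 100.0 * n_gains / n_calls if n_calls else 0.0,
        "mean_cnvs_per_cnv_cell": n_calls / n_cnv_cells if n_cnv_cells else 0.0,
        "total_cnvs": n_calls,
    }


def summarize_cohort(qc: pd.DataFrame,
                     calls: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Success-rate table per individual x method, plus cohort roll-ups.

    ``qc`` needs columns cell_id, individual_id, method, passes; ``calls``
    are the retained (filtered) CNV calls with a cell_id column. Percentages
    are recomputed from the integer counts in the table, never carried as
    stored floats.
    """
    cnv_cells = set(calls["cell_id"]) if len(calls) else set()
    rows = []
    for (ind, method), sub in qc.groupby(["individual_id", "method"]):
        passed = sub[sub["passes"]]
        passed_ids = set(passed["cell_id"])
        with_cnv = passed_ids & cnv_cells
        sub_calls = calls[calls["cell_id"].isin(passed_ids)] if len(calls) \
            else calls
        n_gain = int((sub_calls["type"] == "gain").sum()) if len(sub_calls) else 0
        n_loss = int((sub_calls["type"] == "loss").sum()) if len(sub_calls) else 0
        rows.append({
            "individual_id": ind, "method": method,
            "n_cells": len(sub), "n_passed": len(passed),
            "pct_passed": 100.0 * len(passed) / len(sub) if len(sub) else 0.0,
            "n_cnv_cells": len(with_cnv),
            "pct_cnv_cells": (100.0 * len(with_cnv) / len(passed)
                              if len(passed) else 0.0),
            "total_cnvs": n_gain + n_loss, "gains": n_gain, "losses": n_loss,
        })
    table = pd.DataFrame(rows)
    n_passed = int(table["n_passed"].sum()) if len(table) else 0
    n_cnv = int(table["n_cnv_cells"].sum()) if len(table) else 0
    n_calls = int(table["total_cnvs"].sum()) if len(table) else 0
    n_gains = int(table["gains"].sum()) if len(table) else 0
    rollup = rollup_counts(n_passed, n_cnv, n_calls, n_gains)
    rollup["n_passed"] = n_passed
    return table, rollup
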