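"""PCA denoising of read-depth matrices.

High-noise amplification chemistries (droplet MDA in particular) show
depth fluctuations that recur across cells — locus-specific amplification
bias rather than genuine copy-number change. Principal components of the
cross-cell depth matrix capture this shared variation; regressing each
cell's profile on the leading components and keeping the residuals removes
it, while somatic CNVs private to one cell barely influence the components
and survive.

Components are estimated leave-one-out: the components a cell is regressed
on are computed from the *other* cells only, so a private CNV cannot leak
into its own correction basis.
"""

from __future__ import annotations

import warnings

import numpy as np

#: variance-fraction grid conventionally scanned when tuning the denoiser
VARIANCE_GRID = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
#: bin-size grid (bp) at which denoised re-calling is typically attempted
BIN_SIZE_GRID = (500_000, 1_000_000, 2_500_000, 5_000_000)


def _n_components(singular_values: np.ndarray, variance_fraction: float) -> int:
    var = singular_values ** 2
    total = var.sum()
    if total <= 0:
        return 0
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)


def pca_denoise(matrix: np.ndarray, variance_fraction: float = 0.4) -> np.ndarray:
    """Remove cross-cell shared depth variation; returns residuals recentred at 1.

    Parameters
    ----------
    matrix : (n_bins, n_cells) array of corrected depth ratios.
    variance_fraction : float in (0, 1)
        The minimal set of leading principal components jointly explaining at
        least this fraction of cross-cell variance is removed.

    For each cell, the mean profile and principal components of the remaining
    cells are computed; the cell's centred profile is regressed on those
    components (ordinary least squares with intercept) and the residual,
    recentred to mean 1, is returned.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("denoising needs a bins x cells matrix with >= 3 cells")
    if not (0.0 < variance_fraction < 1.0):
        raise ValueError("variance_fraction must lie strictly in (0, 1)")
    n_bins, n_cells = X.shape
    out = np.empty_like(X)
    for j in range(n_cells):
        others = np.delete(X, j, axis=1)
        mean_profile = others.mean(axis=1)
        centred_others = others - mean_profile[:, None]
        U, s, _ = np.linalg.svd(centred_others, full_matrices=False)
        m = _n_components(s, variance_fraction)
        max_m = centred_others.shape[1] - 1
        if m > max_m:
            warnings.warn("requested variance fraction needs more components "
                          "than cells provide; capping")
            m = max_m
        # the shared structure enters as regression covariates (mean profile
        # plus leading components), so variation a cell does not share —
        # its own noise, its private CNVs — is left untouched
        design = np.column_stack([np.ones(n_bins),
                                  mean_profile - mean_profile.mean(),
                                  U[:, :m]])
        coef, *_ = np.linalg.lstsq(design, X[:, j], rcond=None)
        resid = X[:, j] - design @ coef
        out[:, j] = resid - resid.mean() + 1.0
    return out


def denoise_grid(matrix: np.ndarray,
                 fractions=VARIANCE_GRID) -> dict[float, np.ndarray]:
    """Denoised matrices for each variance fraction in the grid."""
    return {float(f): pca_denoise(matrix, float(f)) for f in fractions}
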