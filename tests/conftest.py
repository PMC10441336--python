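import numpy as np
import pandas as pd
import pytest

from scwga_cnv import coverage, simulate

GENOME5 = [(f"chr{i}", 50_000_000) for i in range(1, 6)]


@pytest.fixture(scope="session")
def four_bin_scheme():
    """One 1 Mb chromosome cut into four 250 kb bins."""
    return coverage.build_bins([("chr1", 1_000_000)], "fixed", 250_000)


@pytest.fixture(scope="session")
def picoplex_cohort():
    """20 default-profile PicoPLEX cells, no CNVs, 500 kb bins."""
    spec = simulate.CohortSpec(cells=[("A", "picoplex", 20)], genome=GENOME5,
                               bin_size=500_000, rng_seed=11,
                               shared_artifact_seed=11)
    return simulate.simulate_cohort(spec)


@pytest.fixture(scope="session")
def dmda_cohort():
    """15 default-profile dMDA cells, no CNVs, 500 kb bins (the bin size at
    which the per-chemistry MAD reference values are defined)."""
    spec = simulate.CohortSpec(cells=[("A", "dmda", 15)],
                               genome=GENOME5[:4], bin_size=500_000,
                               rng_seed=3, shared_artifact_seed=3)
    return simulate.simulate_cohort(spec)


def corrected_matrix(counts: pd.DataFrame, bins, individual="A",
                     method="picoplex") -> np.ndarray:
    """Stack per-cell corrected profiles into a bins x cells array."""
    return np.column_stack([
        coverage.make_profile(c, individual, method, counts[c].to_numpy(),
                              bins).corrected
        for c in counts.columns])
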