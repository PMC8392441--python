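import numpy as np
import pandas as pd
import pytest

from qsig import simdata


@pytest.fixture(scope="session")
def small_counts():
    """500-gene, 4-cell-line DiD count matrix with 5% planted DE at lfc 3."""
    counts, truth = simdata.simulate_counts(
        n_genes=500, de_fraction=0.05, lfc_magnitude=3.0, dispersion=0.1,
        seed=11)
    return counts, truth


@pytest.fixture(scope="session")
def toy_cohort():
    """Late-effect survival cohort with one loaded and one null gene."""
    cohort, truth = simdata.simulate_cohort(
        n_patients=400, beta_early=0.0, beta_late=0.8, censor_rate=0.25,
        seed=5, genes=["gLATE", "gNULL"], prognostic_genes=["gLATE"],
        gene_loading=0.7)
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_ranked():
    """10-gene ranked list with distinct statistics."""
    stats = np.array([5.0, 3.2, 2.1, 1.4, 0.7, -0.3, -1.1, -2.0, -3.5, -4.8])
    return pd.Series(stats, index=[f"g{i}" for i in range(10)], name="stat")
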