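import numpy as np
import pandas as pd
import pytest

from bsewas.ewas import compute_celltype_pc1
from bsewas.simulate import SimulationConfig, simulate_cohort
from bsewas.types import CELL_TYPES


def attach_pc1(cov: pd.DataFrame) -> pd.DataFrame:
    cov = cov.copy()
    cov["pc1"], _ = compute_celltype_pc1(cov[list(CELL_TYPES)].to_numpy())
    return cov


@pytest.fixture(scope="session")
def small_cohort():
    """40 samples, 200 sites, 2 planted DMRs, 1 planted meQTL cluster."""
    cfg = SimulationConfig(
        n_samples=40, n_clusters_per_chrom=10, n_dmrs=2, n_meqtl=1,
        n_background_snps=10, seed=11,
    )
    mat, geno, cov, truth = simulate_cohort(cfg)
    return mat, geno, attach_pc1(cov), truth


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects, pure binomial: for calibration checks."""
    cfg = SimulationConfig(
        n_samples=60, n_clusters_per_chrom=25, n_dmrs=0, n_meqtl=0,
        n_background_snps=0, seed=7,
    )
    mat, geno, cov, truth = simulate_cohort(cfg)
    return mat, attach_pc1(cov), truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
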