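import numpy as np
import pandas as pd
import pytest

from surfacer import CallParams, CohortConfig, TriageParams, generate_cohort
from surfacer.tables import ProteinQuantTable


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_pdx=3, n_proteins=200, n_true_targets=8,
                        n_decoys_per_archetype=2, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture
def call_params() -> CallParams:
    return CallParams(seed=5)


@pytest.fixture
def triage_params() -> TriageParams:
    return TriageParams()


def make_quant_table(pdx_id="PDX1", n_proteins=30, n_biot=4, n_nb=2,
                     missing_frac=0.1, seed=0) -> ProteinQuantTable:
    """A small random quantification table for unit tests."""
    rng = np.random.default_rng(seed)
    runs = [f"biot.{i+1}" for i in range(n_biot)] + \
           [f"nb.{i+1}" for i in range(n_nb)]
    ids = pd.Index([f"P{i:03d}" for i in range(n_proteins)],
                   name="protein_id")
    x = rng.normal(25, 2, (n_proteins, len(runs)))
    if missing_frac > 0:
        mask = rng.random(x.shape) < missing_frac
        # keep at least 2 observed per run so imputation stays defined
        for j in range(len(runs)):
            while mask[:, j].sum() > n_proteins - 2:
                mask[rng.integers(n_proteins), j] = False
        x[mask] = np.nan
    pep = rng.poisson(3, x.shape)
    pep[np.isnan(x)] = 0
    table = ProteinQuantTable(
        pdx_id,
        pd.DataFrame(x, index=ids, columns=runs),
        pd.DataFrame(pep, index=ids, columns=runs))
    return table.validate()
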