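import numpy as np
import pandas as pd
import pytest

from ffpeqc import simulate as sim


@pytest.fixture(scope="session")
def small_params() -> sim.SimulationParams:
    return sim.SimulationParams(
        n_genes=800, n_samples=24, n_batches=3, n_replicate_groups=3, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """Small but fully structured synthetic cohort (batches, controls,
    replicates) shared across tests."""
    return sim.simulate_cohort(small_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def replicate_pair(quality: float, seed: int, n_genes: int = 2000):
    """Two replicate libraries of one specimen at the given quality."""
    params = sim.SimulationParams(n_genes=n_genes, seed=seed)
    catalog = sim.generate_gene_catalog(n_genes, seed)
    truth = pd.DataFrame(
        {
            "quality": [quality, quality],
            "batch_id": ["b1", "b2"],
            "replicate_group": ["g", "g"],
            "is_technical_control": [False, False],
            "true_status": ["PASS", "PASS"],
        },
        index=pd.Index(["A", "B"], name="sample_id"),
    )
    counts = sim.simulate_counts(catalog, truth, params)
    return catalog, counts
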