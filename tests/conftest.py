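import numpy as np
import pandas as pd
import pytest

from odm.dataset import ExpressionDataset, sample_name
from odm.simulate import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=120,
        de_fraction=0.2,
        assoc_genes_per_effect=2,
        n_regulators=8,
        n_compounds=25,
        n_gene_sets=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    ds, truth = simulate_expression(small_config)
    return ds, truth


@pytest.fixture(scope="session")
def small_fits(small_bundle):
    from odm.timecourse import fit_dataset

    ds, _ = small_bundle
    return fit_dataset(ds)


def make_single_drug_dataset(Y, drug="morphine", time_points=(0, 1, 2, 4, 8), reps=3):
    """Wrap a genes x (times*reps) matrix as an ExpressionDataset."""
    cols = [sample_name(drug, t, r + 1) for t in time_points for r in range(reps)]
    values = pd.DataFrame(
        Y, index=[f"G{i:06d}" for i in range(Y.shape[0])], columns=cols
    )
    samples = pd.DataFrame(
        {
            "drug": drug,
            "time_hours": np.repeat(time_points, reps).astype(float),
            "replicate": list(range(1, reps + 1)) * len(time_points),
        },
        index=cols,
    )
    return ExpressionDataset(values, samples)
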