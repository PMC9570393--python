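import numpy as np
import pandas as pd
import pytest

from dilimark import ExpressionMatrix, SimConfig, simulate_expression


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with five planted markers, reused read-only."""
    config = SimConfig(
        n_case=40,
        n_control=12,
        n_genes=300,
        n_de=5,
        logfc_values=[2.0, 1.5, 1.4, 1.2, 1.0],
        noise_sd=0.5,
        n_batches=3,
        n_fraction_links=2,
        seed=7,
    )
    matrix, truth = simulate_expression(config)
    return config, matrix, truth


def make_matrix(values, groups=None, batches=None):
    """Hand-build an ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    groups = groups or ["DILI"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2)
    batches = batches or ["b0"] * n_samples
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_meta=pd.DataFrame(
            {"group": groups, "batch": batches}, index=pd.Index(samples, name="sample")
        ),
    )
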