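import numpy as np
import pandas as pd
import pytest

from drugfunnel.deg import ExpressionMatrix
from drugfunnel.synthetic import SimConfig, load_reference_fixture


@pytest.fixture(scope="session")
def fixture_data():
    return load_reference_fixture()


@pytest.fixture(scope="session")
def small_cfg():
    """A fast, fully-planted configuration used across module tests."""
    return SimConfig(
        seed=11,
        n_genes=300,
        n_true_risk=100,
        n_sets_per_channel=30,
        n_enriched_per_channel=6,
        set_size_range=(10, 60),
        background_multiplier=10,
        sample_sizes=((10, 10), (8, 12)),
        effect_size=4.0,
        noise_sd=0.5,
        druggable_fraction=0.25,
        n_compounds=40,
        n_profiled_genes=400,
        correlated_compounds=8,
        max_transpositions=120,
        n_touchstone=80,
    )


def make_matrix(values: np.ndarray, n_normal: int, genes=None) -> ExpressionMatrix:
    """Wrap a plain array into an ExpressionMatrix (first columns = normal)."""
    n_genes, n_samples = values.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    groups = pd.Series(
        ["normal"] * n_normal + ["tumor"] * (n_samples - n_normal), index=samples
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), groups=groups
    )
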