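import numpy as np
import pandas as pd
import pytest

from brsgkit.simulate import SyntheticExpressionSpec, generate_expression


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    return pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=pd.Index(["gA", "gB"], name="gene_id"),
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def tiny_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {"region": ["HPC", "HPC", "HPT"],
         "group": ["control", "aggressive", "control"]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """A small seeded synthetic experiment shared across tests."""
    spec = SyntheticExpressionSpec(n_genes=400, n_single_region=5,
                                   n_shared_pair=5, n_group_effect=5,
                                   seed=42)
    return generate_expression(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
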