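import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from seedcoex.io import ExpressionMatrix
from seedcoex.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study shared by read-only tests."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture()
def small_matrix():
    """A tiny hand-made matrix: a seed, a correlated probe pair, background."""
    rng = np.random.default_rng(42)
    n = 50
    f = rng.standard_normal(n)
    rows = {
        "p_seed": f,
        "p_dup1": 0.8 * f + 0.6 * rng.standard_normal(n),
        "p_dup2": 0.8 * f + 0.6 * rng.standard_normal(n),
        "p_neg": -0.7 * f + np.sqrt(1 - 0.49) * rng.standard_normal(n),
        "p_null1": rng.standard_normal(n),
        "p_null2": rng.standard_normal(n),
    }
    values = pd.DataFrame(rows).T
    values.columns = [f"S{i:02d}" for i in range(n)]
    symbols = pd.Series({"p_seed": "SEED", "p_dup1": "DUPG", "p_dup2": "DUPG",
                         "p_neg": "NEGG", "p_null1": "NUL1", "p_null2": "NUL2"},
                        name="gene_symbol").loc[values.index]
    return ExpressionMatrix(values=values, gene_symbols=symbols)
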