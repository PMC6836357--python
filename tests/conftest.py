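import numpy as np
import pandas as pd
import pytest

from gwas2drug.preprocess import ExpressionMatrix
from gwas2drug.simulate import SimConfig, generate_all


@pytest.fixture(scope="session")
def default_sim():
    """One generated fixture set under the default study conditions."""
    return generate_all(SimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_matrix():
    """Five genes x six samples with one exact linear copy of GENE_A."""
    rng = np.random.default_rng(7)
    base = rng.normal(size=6)
    values = pd.DataFrame(
        {
            "GENE_A": base,
            "GENE_B": 2.0 * base + 1.0,  # r = 1 with GENE_A
            "GENE_C": rng.normal(size=6),
            "GENE_D": -base,  # r = -1
            "GENE_E": rng.normal(size=6),
        }
    ).T
    values.columns = [f"s{i}" for i in range(6)]
    return ExpressionMatrix(values=values, tissue_category="skin", scaled=True)
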