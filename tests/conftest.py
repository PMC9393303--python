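import numpy as np
import pandas as pd
import pytest

from ferroscore.io import ExpressionMatrix
from ferroscore.simulate import synthetic_ips_table


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_matrix(rng):
    """10 genes x 4 samples of positive continuous expression."""
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(4)]
    vals = pd.DataFrame(rng.lognormal(1.0, 0.8, (10, 4)), index=genes, columns=samples)
    return ExpressionMatrix(vals, layer="normalized")


@pytest.fixture
def ips_table():
    return synthetic_ips_table(seed=0)


@pytest.fixture
def ips_matrix(ips_table, rng):
    """Expression over the synthetic IPS genes plus two bystanders."""
    genes = ips_table["gene"].tolist() + ["BYSTANDER1", "BYSTANDER2"]
    samples = [f"s{i}" for i in range(20)]
    vals = pd.DataFrame(rng.lognormal(2.0, 1.0, (len(genes), 20)),
                        index=genes, columns=samples)
    return ExpressionMatrix(vals, layer="normalized")
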