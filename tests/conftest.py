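import numpy as np
import pandas as pd
import pytest

from stemstat.enrich import DEGTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_deg_table():
    """Six genes spanning the padj and log2fc filter boundaries."""
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(6)],
            "log2fc": [1.0, 0.4, -2.0, 0.6, -0.1, 0.51],
            "pvalue": [0.001, 0.01, 0.012, 0.05, 0.4, 0.008],
            "padj": [0.01, 0.049, 0.05, 0.2, 0.9, 0.03],
        }
    )
    return DEGTable(df, universe_size=6)
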