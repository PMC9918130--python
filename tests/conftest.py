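import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import plsrank as pr

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix():
    """3-group, 2-per-group toy FPKM matrix with one separating gene."""
    values = pd.DataFrame(
        {
            "C_1": [10.0, 5.0, 2.0],
            "C_2": [11.0, 5.5, 2.1],
            "A20_1": [30.0, 5.2, 2.0],
            "A20_2": [29.0, 4.9, 1.9],
            "AD_1": [20.0, 5.1, 2.2],
            "AD_2": [21.0, 5.3, 2.0],
        },
        index=pd.Index(["Sep", "Flat1", "Flat2"], name="gene_id"),
    )
    design = pd.Series(
        ["C", "C", "A20", "A20", "AD", "AD"],
        index=values.columns,
        name="group",
    )
    return pr.ExpressionMatrix(values, design)


@pytest.fixture
def default_experiment():
    """One mid-sized synthetic experiment shared across read-only tests."""
    cfg = pr.SyntheticConfig(n_genes=600, seed=11)
    return pr.generate_experiment(cfg)


@pytest.fixture
def curated():
    return pr.load_curated_annotation()
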