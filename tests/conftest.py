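import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from permdeg import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_2v2():
    """3-gene, 2-vs-2 matrix with hand-picked values for brute-force oracles."""
    values = pd.DataFrame(
        {
            "KD_1": [5.0, 8.0, 2.0],
            "KD_2": [6.0, 8.5, 2.5],
            "WT_1": [3.0, 8.2, 6.0],
            "WT_2": [3.5, 8.1, 6.5],
        },
        index=["g1", "g2", "g3"],
    )
    design = {"KD_1": "KD", "KD_2": "KD", "WT_1": "WT", "WT_2": "WT"}
    return ExpressionMatrix(values, design)


@pytest.fixture
def random_matrix():
    """8-gene, 2-group matrix of well-behaved random intensities."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(7, 2, size=(8, 4)),
        index=[f"g{i}" for i in range(8)],
        columns=["A_1", "A_2", "B_1", "B_2"],
    )
    design = {"A_1": "grpA", "A_2": "grpA", "B_1": "grpB", "B_2": "grpB"}
    return ExpressionMatrix(values, design)
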