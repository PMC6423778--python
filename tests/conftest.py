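import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stemsig import microarray, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_run():
    """Default planted simulation with its detection result (shared)."""
    cfg = synthetic.SimConfig.with_planted(seed=11)
    matrix, truth = synthetic.generate_bead_summary(cfg)
    det = microarray.detection_pvalues(matrix)
    return cfg, matrix, truth, det


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 samples with 5 controls per sample."""
    signals = pd.DataFrame(
        [[30.0, 50.0], [10.0, 7.0], [22.0, 15.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    controls = pd.DataFrame(
        np.array([[1, 5, 7, 9, 12], [1, 5, 7, 9, 12]], dtype=float).T,
        index=[f"nc{i}" for i in range(5)],
        columns=["s1", "s2"],
    )
    with pytest.warns(UserWarning, match="negative controls"):
        return microarray.BeadSummaryMatrix(
            signals, controls, {"s1": "fMSC", "s2": "iMSC"}
        )
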