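from __future__ import annotations

import numpy as np
import pytest

from awnet import PipelineConfig, SyntheticConfig, run_pipeline
from awnet.ggm import GGMNetwork


def make_net(weights, labels=None) -> GGMNetwork:
    """Build a GGMNetwork directly from a weight matrix (unit-diagonal
    precision implied), for tests that only exercise the weights."""
    W = np.asarray(weights, dtype=float)
    p = W.shape[0]
    labels = labels or [f"N{i + 1:02d}" for i in range(p)]
    precision = np.eye(p) - W
    return GGMNetwork(
        weights=W,
        precision=precision,
        lambda_path=np.array([0.1]),
        ebic_values=np.array([0.0]),
        lambda_selected=0.1,
        gamma=0.5,
        n=100,
        node_labels=list(labels),
    )


@pytest.fixture(scope="session")
def recovery_bundle():
    """One full pipeline run on the default synthetic scenario (n=280, p=27,
    q=10, 4 planted communities), shared across tests that inspect it."""
    cfg = PipelineConfig(synthetic=SyntheticConfig(), seed=1)
    return run_pipeline(cfg, write=False)
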