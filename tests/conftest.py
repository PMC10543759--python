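import numpy as np
import pytest

from mdalink import (GateConfig, SimilarityMatrix, SyntheticSpec,
                     build_graph, generate_associations)
from mdalink.dnn import DnnConfig
from mdalink.pipeline import PipelineConfig


def random_similarity(n: int, seed: int, side: str = "disease",
                      kind: str = "fused") -> SimilarityMatrix:
    rng = np.random.default_rng(seed)
    S = rng.random((n, n))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix([f"n{i}" for i in range(n)], S, side, kind)


@pytest.fixture
def small_graph():
    """5-node attributed graph used by the loop-oracle checks."""
    rng = np.random.default_rng(42)
    sim = random_similarity(5, seed=7)
    X = rng.random((5, 4))
    return build_graph(sim, X, k_neighbors=2)


@pytest.fixture(scope="session")
def synth_assoc():
    """The default synthetic study conditions: 40 x 120, rank 4, 4% dense."""
    assoc, propensity = generate_associations(SyntheticSpec())
    return assoc, propensity


@pytest.fixture(scope="session")
def fast_pipeline_config():
    """Reduced-epoch pipeline settings used for CV-level checks."""
    return PipelineConfig(gate=GateConfig(epochs=100),
                          dnn=DnnConfig(epochs=100), seed=1)
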