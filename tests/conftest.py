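import numpy as np
import pytest

from biofilmkg import pipeline, synth
from biofilmkg.node2vec import WalkConfig
from biofilmkg.train import TrainConfig

# Light walk settings used wherever structural embeddings are needed but the
# embedding quality itself is not under test (keeps the suite inside budget).
LIGHT_WALKS = WalkConfig(walks_per_node=5, walk_length=40, epochs=2, seed=42)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-config synthetic dataset (seed 42)."""
    return synth.generate_dataset(synth.SynthConfig())


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic dataset for cheap structural tests."""
    cfg = synth.SynthConfig(n_virus=40, n_disease_virus=8, n_bacteria=20,
                            n_samples=24, n_latent_factors=3, seed=7)
    return synth.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """Full default-scale pipeline inputs, shared by end-to-end tests."""
    return pipeline.build_bundle(synth.SynthConfig(), LIGHT_WALKS,
                                 holdout_fraction=0.2)


@pytest.fixture(scope="session")
def endtoend_runs(default_bundle):
    """Trained relation-aware + GAT models over seeds {0, 1, 2}."""
    runs = {}
    for kind in ("relgat", "gat"):
        runs[kind] = [
            pipeline.run_experiment(default_bundle, kind, TrainConfig(seed=s))
            for s in (0, 1, 2)
        ]
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
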