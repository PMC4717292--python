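import warnings

import pytest

from mycolink import PipelineParams, WorldConfig, generate_world, run_pipeline


@pytest.fixture(scope="session")
def world():
    """Default-condition synthetic world, shared across the suite."""
    return generate_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def result(world):
    """Full pipeline run on the shared world."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(world, PipelineParams(seed=11))


@pytest.fixture(scope="session")
def tiny_world():
    """Three noiseless clusters of ten genes: every stage recovers truth exactly."""
    cfg = WorldConfig(
        seed=5,
        n_host_genes=60,
        n_symbiont_genes=200,
        n_clusters_planted=3,
        cluster_size=10,
        noise_sd=0.0,
        compendium_noise_sd=0.0,
        silent_fraction=0.2,
        background_motif_frequency=0.0,
        reads_per_sample=0,
    )
    return generate_world(cfg)
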