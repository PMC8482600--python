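import numpy as np
import pytest

from spacerscope.config_io import PipelineConfig
from spacerscope.pipeline import run_pipeline
from spacerscope.synthetic_data import GeneratorParams, generate_universe


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_universe():
    """A cheap universe for I/O and bookkeeping tests."""
    return generate_universe(
        GeneratorParams(n_clusters=6, spacers_per_cluster=8, n_decoy_spacers=6,
                        n_array_embedded_hits=4, rng_seed=7)
    )


@pytest.fixture(scope="session")
def default_universe():
    """The default study-conditions universe (20 clusters x 30 spacers)."""
    return generate_universe(GeneratorParams(rng_seed=11))


def external_orientations(universe):
    """Database-style orientation annotations from the planted truth."""
    return {
        sid: universe.truth.clusters[t["cluster"]]["orientation"]
        for sid, t in universe.truth.spacers.items()
        if t["cluster"] != "decoy"
    }


@pytest.fixture(scope="session")
def default_result(default_universe):
    """Full pipeline run on the default universe (shared across tests)."""
    return run_pipeline(
        default_universe.records,
        default_universe.subjects,
        orf_annotations=default_universe.orfs,
        external_orientations=external_orientations(default_universe),
    )
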