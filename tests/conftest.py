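import numpy as np
import pytest

from uvbclines.synthetic import (
    reference_simulation_config,
    simulate_sample_sets,
    simulate_uvb_raster,
)


@pytest.fixture(scope="session")
def reference_run():
    """One seeded simulation of the built-in 60-cohort reference design."""
    config, roster = reference_simulation_config(seed=1)
    sets, freq, annotations = simulate_sample_sets(config, roster)
    return {"config": config, "sets": sets, "freq": freq, "annotations": annotations}


@pytest.fixture(scope="session")
def reference_raster(reference_run):
    return simulate_uvb_raster(reference_run["config"], reference_run["sets"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
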