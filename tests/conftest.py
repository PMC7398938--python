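import numpy as np
import pandas as pd
import pytest

from invasdm import (PredictorStack, RunConfig, VirtualSpeciesConfig,
                     run_pipeline, simulate_virtual_species)


@pytest.fixture(scope="session")
def species_config():
    """Reference virtual species: 64x64 grid, 3 informative + 2 collinear
    covariates, 500 presences (the benchmarking fixture)."""
    return VirtualSpeciesConfig(n_presences=500, seed=1)


@pytest.fixture(scope="session")
def virtual_species(species_config):
    return simulate_virtual_species(species_config)


@pytest.fixture(scope="session")
def species_stack(virtual_species):
    sim = virtual_species
    return PredictorStack(sim["names"] + ["landcover"],
                          sim["covariates"] + [sim["landcover"]],
                          sim["kinds"] + ["categorical"])


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, species_config):
    """One full end-to-end run shared by integration tests."""
    rundir = tmp_path_factory.mktemp("run")
    config = RunConfig(species=species_config, seed=1)
    manifest = run_pipeline(config, rundir)
    return {"config": config, "rundir": rundir, "manifest": manifest}


@pytest.fixture()
def toy_table():
    """Linearly separable 2-D toy feature table."""
    rng = np.random.default_rng(42)
    n = 100
    x1 = np.concatenate([rng.normal(-2, 0.5, n), rng.normal(2, 0.5, n)])
    x2 = rng.normal(size=2 * n)
    return pd.DataFrame({
        "id": [f"r{i}" for i in range(2 * n)],
        "label": np.repeat([0, 1], n),
        "partition": "train",
        "x1": x1,
        "x2": x2,
    })
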