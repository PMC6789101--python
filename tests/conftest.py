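import numpy as np
import pytest

from ecoeff import RunConfig
from ecoeff.ensemble import load_ensemble
from ecoeff.synthetic import (
    ModelSpec,
    default_model_specs,
    generate_archive,
    generate_ensemble,
    make_grid,
)

YEARS = np.arange(1901, 2011)


@pytest.fixture(scope="session")
def config():
    return RunConfig(seed=7)


@pytest.fixture(scope="session")
def small_grid():
    return make_grid(6, 8, 0.6, seed=3)


@pytest.fixture(scope="session")
def archive_dir(config, tmp_path_factory):
    root = tmp_path_factory.mktemp("archive")
    return generate_archive(config, root)


@pytest.fixture(scope="session")
def ensembles(archive_dir, config):
    return load_ensemble(archive_dir, config)


@pytest.fixture(scope="session")
def null_ensemble(small_grid):
    """All effect sizes zero, no noise: every scenario identical and constant."""
    spec = ModelSpec(name="NULL", has_nitrogen=True, noise_sd=0.0, rho=0.0, seed=11)
    return generate_ensemble(spec, grid=small_grid, years=YEARS)


@pytest.fixture(scope="session")
def co2_only_ensemble(small_grid):
    """Single injected CO2 effect on GPP (+20 % per span), noiseless."""
    spec = ModelSpec(
        name="CO2ONLY", has_nitrogen=True, noise_sd=0.0, rho=0.0, seed=13,
        effects={"co2": {"gpp": 0.20}},
    )
    return generate_ensemble(spec, grid=small_grid, years=YEARS)


@pytest.fixture(scope="session")
def noiseless_specs(config):
    specs = default_model_specs(config)
    for s in specs:
        s.noise_sd = 0.0
    return specs


@pytest.fixture(scope="session")
def noiseless_archive(noiseless_specs, config, tmp_path_factory):
    root = tmp_path_factory.mktemp("noiseless")
    return generate_archive(config, root, specs=noiseless_specs)
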