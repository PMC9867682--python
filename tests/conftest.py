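import pytest
from hypothesis import settings

from pterisk.datasets import remance_foods

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")
from pterisk.io import load_default_parameters
from pterisk.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def foods():
    return remance_foods()


@pytest.fixture(scope="session")
def sim():
    """A medium synthetic survey shared by recovery-style tests."""
    return generate(GeneratorConfig(seed=7, n_samples=500, n_bcr=500))


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small synthetic survey written to disk for I/O-level tests."""
    ds = generate(GeneratorConfig(seed=11, n_samples=40, n_bcr=12))
    out = tmp_path_factory.mktemp("sim_small")
    paths = ds.write(out)
    return ds, paths
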