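import pytest

from shiftprofiler import ShepherdConfig, run_pipeline
from shiftprofiler.fixtures import FixtureSpec, generate_experiment_set


@pytest.fixture(scope="session")
def default_config():
    return ShepherdConfig()


@pytest.fixture(scope="session")
def small_fixture():
    """A 2-experiment, 800-PSM synthetic dataset with known truth."""
    spec = FixtureSpec(
        n_experiments=2,
        n_psms_per_experiment=400,
        n_peptides_per_experiment=80,
        rng_seed=7,
    )
    es, manifest = generate_experiment_set(spec)
    return spec, es, manifest


@pytest.fixture(scope="session")
def small_result(small_fixture):
    _, es, _ = small_fixture
    return run_pipeline(es)


@pytest.fixture(scope="session")
def full_fixture():
    """The default stated world: 3 experiments x 2000 PSMs, 8 shifts."""
    spec = FixtureSpec()
    es, manifest = generate_experiment_set(spec)
    return spec, es, manifest


@pytest.fixture(scope="session")
def full_result(full_fixture):
    _, es, _ = full_fixture
    return run_pipeline(es)
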