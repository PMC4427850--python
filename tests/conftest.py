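import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from mipscan import (
    BuiltinSearchBackend,
    FixtureSpec,
    PipelineConfig,
    generate_fixture,
    run_pipeline,
)


@pytest.fixture(scope="session")
def default_fixture():
    """The canonical synthetic benchmark (seed 42, default spec)."""
    return generate_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_predictions(default_fixture, default_config):
    """Pipeline output on the canonical fixture with default thresholds."""
    fx = default_fixture
    return run_pipeline(
        fx.proteome,
        fx.tfs,
        fx.unwanted,
        cfg=default_config,
        search_backend=BuiltinSearchBackend(),
        domain_library=fx.library,
    )
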