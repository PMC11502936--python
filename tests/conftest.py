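import pytest
from hypothesis import HealthCheck, settings

from conecap.synthetic_data import DerryclareFixture, derryclare_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture() -> DerryclareFixture:
    """The packaged Derryclare survey encoding (deterministic)."""
    return derryclare_fixture()


@pytest.fixture(scope="session")
def pipeline_result(fixture):
    """Full pipeline run on the packaged fixture with published densities."""
    from conecap.cli import run_pipeline

    return run_pipeline(
        fixture.transects,
        fixture.cones,
        fixture.stands,
        fixture.config,
        fixture.species_params,
        densities=fixture.densities,
    )
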