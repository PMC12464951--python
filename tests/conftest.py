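import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def population():
    from floralscape import fig_population

    return fig_population()


@pytest.fixture(scope="session")
def guild():
    from floralscape import fig_guild

    return fig_guild()


@pytest.fixture(scope="session")
def mixed_env():
    from floralscape import fig_environment

    return fig_environment(seed=1)


@pytest.fixture(scope="session")
def mixed_result(population, mixed_env):
    from floralscape import simulate_environment

    return simulate_environment(population, mixed_env)
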