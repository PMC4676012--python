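"""Shared fixtures: one generated dataset and its pipeline outcomes per session."""

import pytest

from txrefine import fixtures, pipeline

try:  # make hypothesis fully deterministic when it is available
    from hypothesis import settings

    settings.register_profile("deterministic", derandomize=True, max_examples=60)
    settings.load_profile("deterministic")
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


@pytest.fixture(scope="session")
def fx():
    return fixtures.generate_fixture(fixtures.FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def improvement(fx):
    return pipeline.improve_fixture(fx)


@pytest.fixture(scope="session")
def screen(fx):
    return pipeline.screen_fixture(fx)


@pytest.fixture(scope="session")
def tiers(fx):
    return pipeline.tier_fixture(fx)
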