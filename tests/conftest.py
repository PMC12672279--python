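import logging

import pytest
from hypothesis import settings

import droughtscreen as ds

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

logging.getLogger("droughtscreen").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def published_descriptives():
    return ds.datasets.load_published_descriptives()


@pytest.fixture(scope="session")
def published_indices_t1():
    return ds.datasets.load_published_indices("T1")


@pytest.fixture(scope="session")
def published_indices_t2():
    return ds.datasets.load_published_indices("T2")


@pytest.fixture(scope="session")
def published_scorecard():
    return ds.datasets.load_published_scorecard()


@pytest.fixture(scope="session")
def default_cfg():
    return ds.default_config()


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """One default synthetic cohort shared by read-only tests."""
    return ds.generate_cohort(default_cfg, seed=11)
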