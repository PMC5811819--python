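"""Shared fixtures: simulated survey tables and fitted models.

Fits are expensive relative to the rest of the suite, so the canonical
height fit is session-scoped and shared by every test that only reads it.
"""

import warnings

import numpy as np
import pytest

import sitar


@pytest.fixture(scope="session")
def height_spec():
    return sitar.default_spec("height", "male", seed=1)


@pytest.fixture(scope="session")
def height_table(height_spec):
    return sitar.simulate_surveys(height_spec)


@pytest.fixture(scope="session")
def height_fit(height_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sitar.fit_sitar(height_table, df=6)


@pytest.fixture(scope="session")
def weight_spec():
    return sitar.default_spec("weight", "male", seed=2)


@pytest.fixture(scope="session")
def weight_table(weight_spec):
    return sitar.simulate_surveys(weight_spec)


@pytest.fixture(scope="session")
def weight_fit(weight_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return sitar.fit_sitar(weight_table, df=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
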