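"""Shared fixtures: the packaged base-case model and its results."""

import numpy as np
import pytest

from hcc_cea.cli_io import load_config


@pytest.fixture(scope="session")
def base_config():
    return load_config()


@pytest.fixture(scope="session")
def base_model(base_config):
    return base_config.model


@pytest.fixture(scope="session")
def base_result(base_model):
    return base_model.run()


@pytest.fixture(scope="session")
def flat_life_table():
    """Zero background mortality, for closed-form limit checks."""
    from hcc_cea.synthetic_data import LifeTable

    return LifeTable(np.arange(60, 101), np.zeros(41))
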