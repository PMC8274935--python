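import numpy as np
import pytest

from nablock import fixtures, presets
from nablock.gating import DrugParams


@pytest.fixture(scope="session")
def truth():
    return fixtures.default_truth()


@pytest.fixture(scope="session")
def fitted():
    return presets.fitted_default()


@pytest.fixture(scope="session")
def drug20():
    return presets.lidocaine(20.0)


@pytest.fixture(scope="session")
def drug_free():
    return DrugParams()


@pytest.fixture(scope="session")
def noiseless_datasets():
    return fixtures.gen_clamp_fixture(fixtures.FixtureSpec())


@pytest.fixture(scope="session")
def default_restitution():
    return fixtures.gen_restitution("default")


@pytest.fixture(scope="session")
def steep_restitution():
    return fixtures.gen_restitution("steep")


def central_diff4(f, x, h):
    """Fourth-order central finite difference."""
    return (-f(x + 2 * h) + 8 * f(x + h) - 8 * f(x - h) + f(x - 2 * h)) / (12 * h)


@pytest.fixture(scope="session")
def fd4():
    return central_diff4
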