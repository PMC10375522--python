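import numpy as np
import pytest

from trixs import DWParams, SoluteGeometry, get_solvent
from trixs.scenario import standard_forward_model


@pytest.fixture(scope="session")
def q_fine():
    """Experimental q-range at the default spacing."""
    return np.round(np.arange(0.5, 4.5 + 1e-9, 0.02), 10)


@pytest.fixture(scope="session")
def q_coarse():
    """Coarser q-grid for optimizer-heavy tests."""
    return np.round(np.arange(0.5, 4.5 + 1e-9, 0.05), 10)


@pytest.fixture(scope="session")
def acn():
    return get_solvent("acetonitrile")


@pytest.fixture(scope="session")
def gs_acn(acn):
    return acn.gs_geometry


@pytest.fixture
def dw():
    return DWParams()


@pytest.fixture(scope="session")
def fm_coarse(q_coarse):
    """Forward model on the coarse grid, shared by refinement tests."""
    return standard_forward_model("acetonitrile", q_coarse)


def random_geometry(rng):
    """A random valid triiodide geometry inside the refinement hull."""
    return SoluteGeometry(
        rng.uniform(2.7, 3.5), rng.uniform(2.8, 6.0), rng.uniform(0.6, 3.0)
    )
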