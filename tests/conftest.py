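import numpy as np
import pytest

from obpcnet.quadrature import QuadratureGrid
from obpcnet.rate_model import CouplingTuple, spec_pair, table2_spec


@pytest.fixture(scope="session")
def grid():
    return QuadratureGrid()


@pytest.fixture(scope="session")
def fine_grid():
    """Halved mesh, for quadrature-refinement checks."""
    return QuadratureGrid(mesh=0.005)


@pytest.fixture(scope="session")
def wide_grid():
    """Wide domain, for oracle checks against unclipped Gaussian identities."""
    return QuadratureGrid(lo=-8.0, hi=8.0, mesh=0.01)


@pytest.fixture(scope="session")
def spont_spec():
    return table2_spec("spontaneous")


@pytest.fixture(scope="session")
def evoked_spec():
    return table2_spec("evoked")


@pytest.fixture(scope="session")
def base_pair():
    return spec_pair()


@pytest.fixture(scope="session")
def weak_tuple():
    return CouplingTuple(0.1, 0.1, 0.1, 0.1)


@pytest.fixture(scope="session")
def reduced_sweep():
    """Step-0.25 sweep of the coupling grid (shared across acceptance tests)."""
    from obpcnet.sweep import SweepGrid, run_grid
    return run_grid(SweepGrid.with_step(0.25))
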