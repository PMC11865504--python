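import numpy as np
import pytest

from actodrop.cell_sim import CellParams, run_cell
from actodrop.chem_cycle import KineticParams
from actodrop.config import bulk_reference
from actodrop.size_control import DropletFieldParams, run_to_steady


@pytest.fixture(scope="session")
def kinetics() -> KineticParams:
    return KineticParams()


@pytest.fixture(scope="session")
def bulk_ref():
    """Gel-layer bulk reference condition: (field params, c_total, volume)."""
    return bulk_reference()


@pytest.fixture(scope="session")
def bulk_steady(bulk_ref):
    """A bulk emulsion evolved to steady state (shared across tests)."""
    fld, c_total, volume = bulk_ref
    final, converged = run_to_steady(fld, c_total, volume, t_end=3000.0, seed=1)
    assert converged
    return final


@pytest.fixture(scope="session")
def cell_run_default():
    """One fuelled synthetic-cell run at the reference condition."""
    return run_cell(CellParams(seed=1), t_end=900.0, out_dt=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
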