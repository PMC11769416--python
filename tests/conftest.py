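import numpy as np
import pytest

from sirnapbpk.pbpk_core import DoseEvent
from sirnapbpk.physiology import load_physiology
from sirnapbpk.synthetic_data import get_compound, simulate_entry


@pytest.fixture(scope="session")
def mouse_table():
    return load_physiology("mouse")


@pytest.fixture(scope="session")
def aln_at3():
    return get_compound("ALN-AT3")


@pytest.fixture(scope="session")
def sc_1mgkg():
    return [DoseEvent(time=0.0, route="SC", dose=1.0)]


@pytest.fixture(scope="session")
def aln_sim_1000h(aln_at3, sc_1mgkg):
    """Reference 1000 h simulation of 1 mg/kg SC ALN-AT3, reused across tests."""
    t_grid = np.linspace(0.0, 1000.0, 400)
    return simulate_entry(aln_at3, sc_1mgkg, t_grid)
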