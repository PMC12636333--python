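import numpy as np
import pytest

from memppi import EnergyModel, InclusionSpec, build_lattice
from memppi.inclusions import add_inclusion, rasterize_disk
from memppi.lattice import LIPID


@pytest.fixture
def model():
    return EnergyModel()


@pytest.fixture
def probe_spec():
    return InclusionSpec(name="probe", radius=0, count=1, role="",
                         partition_by_state={"inactive": 1, "active": 1})


def brute_force_energy(state, model):
    """Independent double-loop bond enumeration (test oracle).

    Walks every +x/+y bond once and classifies endpoints by occupancy,
    without using the packed kernel code paths.
    """
    L = state.L
    E = 0.0
    for x in range(L):
        for y in range(L):
            for nx, ny in (((x + 1) % L, y), (x, (y + 1) % L)):
                o1, o2 = state.owner[x, y], state.owner[nx, ny]
                b1, b2 = state.bnd[x, y], state.bnd[nx, ny]
                if o1 == LIPID and o2 == LIPID:
                    c = model.J
                elif o1 == LIPID and o2 != LIPID and b2:
                    c = model.J_int
                elif o2 == LIPID and o1 != LIPID and b1:
                    c = model.J_int
                else:
                    c = 0.0
                E -= c * float(state.spin[x, y]) * float(state.spin[nx, ny])
    return E


@pytest.fixture
def random_state_with_inclusion(model):
    """6x6 random-spin lattice holding one r=1 inclusion."""
    state = build_lattice(6, 0.0, seed=5)
    spec = InclusionSpec(name="disk", radius=1, count=1, role="",
                         partition_by_state={"inactive": -1, "active": -1})
    add_inclusion(state, spec, (2, 3))
    return state
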