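"""Bridge between the Python object layer and the fused numba kernel."""

from __future__ import annotations

import numpy as np

from . import _kernels
from .inclusions import _radii_array, state_tables
from .lattice import EnergyModel, LatticeState, metropolis_table


def pack_species(state: LatticeState) -> dict:
    from .inclusions import STATE_NAMES
    n = len(state.species)
    b_by_state = np.zeros((max(n, 1), 2), dtype=np.int8)
    is_target = np.zeros(max(n, 1), dtype=np.uint8)
    for i, s in enumerate(state.species):
        for j, sn in enumerate(STATE_NAMES):
            b_by_state[i, j] = s.boundary_value(sn)
        is_target[i] = 1 if s.role == "target" else 0
    return {"spec_b_by_state": b_by_state, "spec_is_target": is_target}


_EMPTY_RULES = {
    "rule_actor": np.empty(0, dtype=np.int64),
    "rule_target": np.empty(0, dtype=np.int64),
    "rule_before": np.empty(0, dtype=np.int64),
    "rule_after": np.empty(0, dtype=np.int64),
    "rule_rate": np.empty(0, dtype=np.float64),
}


def advance_state(state: LatticeState, model: EnergyModel, network=None,
                  C: int = 1, nsweeps: int = 1, E0: float = 0.0,
                  event_capacity: int | None = None) -> dict:
    """Run nsweeps fused scheduler steps (Kawasaki + disk moves + reactions)
    in place.  Returns per-sweep activity and running-energy series, the
    event log, and the accumulated energy change.

    E0 seeds the running energy; pass total_energy(state, model) to get an
    absolute energy series, or leave 0 to read the series as cumulative dE.
    """
    if state.temperature <= 0:
        raise ValueError("temperature must be positive")
    if C < 0:
        raise ValueError("disk attempts per sweep must be >= 0")
    t = state_tables(state)
    sp = pack_species(state)
    rules = network.to_arrays(state.species) if network is not None else _EMPTY_RULES
    nsweeps = int(nsweeps)
    act = np.empty(nsweeps, dtype=np.float64)
    energy = np.empty(nsweeps, dtype=np.float64)
    cap = event_capacity
    if cap is None:
        cap = max(16, nsweeps * max(state.n_inclusions, 1))
    ev_sweep = np.empty(cap, dtype=np.int64)
    ev_inc = np.empty(cap, dtype=np.int64)
    ev_rule = np.empty(cap, dtype=np.int64)
    seed = int(state.rng.integers(2**31))
    table, off = metropolis_table(model, state.temperature)
    E_run, n_ev = _kernels.advance(
        state.spin, state.owner, state.bnd,
        state.inc_x, state.inc_y, _radii_array(state),
        state.inc_species, state.inc_state, state.inc_b,
        sp["spec_b_by_state"], sp["spec_is_target"],
        rules["rule_actor"], rules["rule_target"], rules["rule_before"],
        rules["rule_after"], rules["rule_rate"],
        t["fp_dx"], t["fp_dy"], t["fp_isb"], t["fp_start"],
        t["ld_dx"], t["ld_dy"], t["tr_dx"], t["tr_dy"], t["ed_start"],
        model.J, model.J_int, state.temperature,
        int(C), nsweeps, state.n_lipid, float(E0), seed,
        act, energy, ev_sweep, ev_inc, ev_rule, table, off)
    return {
        "activity": act,
        "energy": energy,
        "events": np.column_stack([ev_sweep[:n_ev], ev_inc[:n_ev],
                                   ev_rule[:n_ev]]),
        "dE": float(E_run - E0),
        "E_final": float(E_run),
    }
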