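"""Single-run simulation driver.

Builds the initial configuration (inclusions placed first, then lipid
spins assigned to hit the target magnetization over the remaining lipid
sites), then advances the fused scheduler — Kawasaki sweep, C translation
attempts per inclusion, contact detection, reactions — recording the
activity and energy series, periodic snapshots and the reaction event log.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._context import advance_state
from .config import RunConfig
from .inclusions import STATE_NAMES, place_inclusions
from .lattice import EnergyModel, LatticeState, measure_magnetization, total_energy
from .observables import Snapshot, Trajectory


def build_initial_state(config: RunConfig, seed: int | None = None) -> LatticeState:
    """Seeded initial configuration: placed inclusions + shuffled lipid spins."""
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_place, s_spin, s_dyn = ss.spawn(3)
    state = LatticeState(config.lattice_size, tau=config.tau,
                         rng=np.random.default_rng(s_place))
    if config.species:
        place_inclusions(state, config.species)
    state.assign_lipid_spins(config.magnetization,
                             rng=np.random.default_rng(s_spin))
    state.rng = np.random.default_rng(s_dyn)
    return state


def _take_snapshot(state: LatticeState, sweep: int) -> Snapshot:
    return Snapshot(
        sweep=sweep,
        spin=state.spin.copy(),
        inc_x=state.inc_x.copy(),
        inc_y=state.inc_y.copy(),
        inc_species=state.inc_species.copy(),
        inc_state=state.inc_state.copy(),
        inc_b=state.inc_b.copy(),
    )


def run_simulation(config: RunConfig, seed: int | None = None) -> Trajectory:
    """Run one seeded simulation and return its Trajectory.

    The trajectory records activity and running energy each sweep, a
    snapshot every ``snapshot_interval`` sweeps (plus the initial one),
    and every reaction event.
    """
    state = build_initial_state(config, seed)
    model = EnergyModel(J=config.J, J_int=config.J_int)
    network = config.network() if config.rules else None
    if config.pre_equilibrate_sweeps > 0:
        # configurational preparation with reactions off: with static
        # component states the spatial ensemble is Boltzmann, so alternating
        # fast nonlocal lipid exchange with normal scheduler steps samples
        # the same stationary law the reaction phase starts from
        from .lattice import equilibrate_exchange
        block = 250
        done = 0
        while done < config.pre_equilibrate_sweeps:
            n = min(block, config.pre_equilibrate_sweeps - done)
            equilibrate_exchange(state, model, nsweeps=n)
            advance_state(state, model, network=None,
                          C=config.disk_attempts, nsweeps=n)
            done += n
    achieved_m = measure_magnetization(state)
    initial_state = state.inc_state.copy()
    initial_species = state.inc_species.copy()
    E = total_energy(state, model)
    snapshots = [_take_snapshot(state, 0)]
    n_chunks, rem = divmod(config.sweeps, config.snapshot_interval)
    chunk_sizes = [config.snapshot_interval] * n_chunks + ([rem] if rem else [])
    act_parts, en_parts, ev_parts = [], [], []
    done = 0
    for chunk in chunk_sizes:
        res = advance_state(state, model, network=network,
                            C=config.disk_attempts, nsweeps=chunk, E0=E)
        E = res["E_final"]
        act_parts.append(res["activity"])
        en_parts.append(res["energy"])
        ev = res["events"]
        if len(ev):
            ev = ev.copy()
            ev[:, 0] += done + 1  # 1-based sweep indices, matching traj.sweeps
            ev_parts.append(ev)
        done += chunk
        snapshots.append(_take_snapshot(state, done))
    events = (np.concatenate(ev_parts) if ev_parts
              else np.empty((0, 3), dtype=np.int64))
    rule_after = {i: r.target_state_after for i, r in enumerate(config.rules)}
    events_df = pd.DataFrame(events, columns=["sweep", "inclusion", "rule"])
    events_df["new_state"] = [
        1 if rule_after[r] == "active" else 0 for r in events_df["rule"]
    ] if len(events_df) else []
    return Trajectory(
        sweeps=np.arange(1, config.sweeps + 1),
        activity=np.concatenate(act_parts) if act_parts else np.empty(0),
        energy=np.concatenate(en_parts) if en_parts else np.empty(0),
        snapshots=snapshots,
        events=events_df,
        species=list(state.species),
        initial_inc_state=initial_state,
        initial_inc_species=initial_species,
        achieved_m=achieved_m,
        tau=config.tau,
        seed=config.seed if seed is None else seed,
        config_hash=config.hash(),
        metadata={"sweeps": config.sweeps, "m_target": config.magnetization,
                  "L": config.lattice_size, "C": config.disk_attempts},
    )
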