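"""Output writers and readers.

Tables go to delimited text with ``#``-prefixed header metadata (config
hash, seed, achieved magnetization); snapshots and event logs to a
self-describing NPZ array archive.  Writing the same trajectory twice
produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observables import Snapshot, Trajectory


def _header_lines(traj: Trajectory) -> str:
    return (f"# config_hash: {traj.config_hash}\n"
            f"# seed: {traj.seed}\n"
            f"# tau: {traj.tau}\n"
            f"# achieved_m: {traj.achieved_m:.6f}\n")


def write_outputs(traj: Trajectory, outdir, tables: dict | None = None) -> dict:
    """Write a trajectory (and optional extra tables) under outdir.

    Produces activity.csv, events.csv, snapshots.npz, meta.json plus one
    CSV per entry of ``tables``.  Returns the written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    act = pd.DataFrame({"sweep": traj.sweeps, "f_A": traj.activity,
                        "energy": traj.energy})
    paths["activity"] = out / "activity.csv"
    with open(paths["activity"], "w", newline="") as fh:
        fh.write(_header_lines(traj))
        act.to_csv(fh, index=False)

    paths["events"] = out / "events.csv"
    with open(paths["events"], "w", newline="") as fh:
        fh.write(_header_lines(traj))
        traj.events.to_csv(fh, index=False)

    arrays = {
        "sweeps": np.array([s.sweep for s in traj.snapshots], dtype=np.int64),
        "initial_inc_state": traj.initial_inc_state,
        "initial_inc_species": traj.initial_inc_species,
    }
    for i, s in enumerate(traj.snapshots):
        arrays[f"spin_{i}"] = s.spin
        arrays[f"inc_x_{i}"] = s.inc_x
        arrays[f"inc_y_{i}"] = s.inc_y
        arrays[f"inc_species_{i}"] = s.inc_species
        arrays[f"inc_state_{i}"] = s.inc_state
        arrays[f"inc_b_{i}"] = s.inc_b
    paths["snapshots"] = out / "snapshots.npz"
    np.savez(paths["snapshots"], **arrays)

    meta = {
        "config_hash": traj.config_hash,
        "seed": int(traj.seed),
        "tau": float(traj.tau),
        "achieved_m": float(traj.achieved_m),
        "species": [{"name": s.name, "radius": s.radius, "role": s.role,
                     "partition_by_state": s.partition_by_state,
                     "count": s.count, "initial_state": s.initial_state}
                    for s in traj.species],
        "metadata": traj.metadata,
    }
    paths["meta"] = out / "meta.json"
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)

    for name, df in (tables or {}).items():
        p = out / f"{name}.csv"
        with open(p, "w", newline="") as fh:
            fh.write(_header_lines(traj))
            df.to_csv(fh, index=False)
        paths[name] = p
    return paths


def read_outputs(outdir) -> Trajectory:
    """Read back a trajectory written by :func:`write_outputs`."""
    from .inclusions import InclusionSpec
    out = Path(outdir)
    with open(out / "meta.json") as fh:
        meta = json.load(fh)
    act = pd.read_csv(out / "activity.csv", comment="#")
    events = pd.read_csv(out / "events.csv", comment="#")
    if events.empty:
        events = pd.DataFrame(columns=["sweep", "inclusion", "rule", "new_state"])
    z = np.load(out / "snapshots.npz")
    snaps = []
    for i, sw in enumerate(z["sweeps"]):
        snaps.append(Snapshot(
            sweep=int(sw), spin=z[f"spin_{i}"],
            inc_x=z[f"inc_x_{i}"], inc_y=z[f"inc_y_{i}"],
            inc_species=z[f"inc_species_{i}"], inc_state=z[f"inc_state_{i}"],
            inc_b=z[f"inc_b_{i}"]))
    species = [InclusionSpec(name=s["name"], radius=s["radius"],
                             partition_by_state={k: int(v) for k, v
                                                 in s["partition_by_state"].items()},
                             count=s["count"], role=s["role"],
                             initial_state=s["initial_state"])
               for s in meta["species"]]
    return Trajectory(
        sweeps=act["sweep"].to_numpy(),
        activity=act["f_A"].to_numpy(),
        energy=act["energy"].to_numpy(),
        snapshots=snaps,
        events=events,
        species=species,
        initial_inc_state=z["initial_inc_state"],
        initial_inc_species=z["initial_inc_species"],
        achieved_m=meta["achieved_m"],
        tau=meta["tau"],
        seed=meta["seed"],
        config_hash=meta["config_hash"],
        metadata=meta["metadata"],
    )
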