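"""Measurements on simulation states and trajectories.

Covers the steady-state activity fraction, radially averaged
cross-correlation functions between inclusion species, detection of
dark-domain clusters and the out-of-equilibrium "pockets" — dark domains
filled with activated targets and activators (recruiters) but devoid of
inactivators (excluders) — and the operational rule that flags a
replicate as pocketed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage

from .inclusions import STATE_NAMES, rasterize_disk
from .lattice import LIPID, LatticeState


@dataclass
class Snapshot:
    """A stored configuration: spins plus the inclusion table."""

    sweep: int
    spin: np.ndarray              # int8 (L, L); boundary/interior values included
    inc_x: np.ndarray
    inc_y: np.ndarray
    inc_species: np.ndarray
    inc_state: np.ndarray
    inc_b: np.ndarray


@dataclass
class Trajectory:
    """Time series and snapshots of one simulation run."""

    sweeps: np.ndarray            # sweep indices of the activity series
    activity: np.ndarray          # fraction of active targets per sweep
    energy: np.ndarray            # running total energy per sweep
    snapshots: list               # list[Snapshot], strictly increasing sweeps
    events: pd.DataFrame          # columns: sweep, inclusion, rule
    species: list                 # list[InclusionSpec]
    initial_inc_state: np.ndarray
    initial_inc_species: np.ndarray
    achieved_m: float
    tau: float
    seed: int
    config_hash: str = ""
    metadata: dict = field(default_factory=dict)

    def steady_state_activity(self, burn_in_fraction: float = 0.5) -> float:
        n = len(self.activity)
        start = int(n * burn_in_fraction)
        return float(np.nanmean(self.activity[start:]))


def snapshot_state(traj: Trajectory, snap: Snapshot,
                   tau: float | None = None) -> LatticeState:
    """Rebuild a LatticeState (occupancy included) from a stored snapshot."""
    from .inclusions import add_inclusion
    L = snap.spin.shape[0]
    state = LatticeState(L, tau=tau if tau is not None else traj.tau)
    state.spin = snap.spin.copy()
    state.species = list(traj.species)
    for k in range(len(snap.inc_x)):
        spec = traj.species[snap.inc_species[k]]
        # footprint rewrite below; spins at the footprint already stored
        offsets, isb = rasterize_disk(spec.radius)
        xs = (snap.inc_x[k] + offsets[:, 0]) % L
        ys = (snap.inc_y[k] + offsets[:, 1]) % L
        state.owner[xs, ys] = k
        state.bnd[xs, ys] = isb
    state.inc_x = snap.inc_x.astype(np.int64).copy()
    state.inc_y = snap.inc_y.astype(np.int64).copy()
    state.inc_species = snap.inc_species.astype(np.int64).copy()
    state.inc_state = snap.inc_state.astype(np.int64).copy()
    state.inc_b = snap.inc_b.astype(np.int8).copy()
    return state


# ---------------------------------------------------------------------------
# activity

def activity_fraction(state: LatticeState) -> float:
    """(active targets) / (all targets); rejects states with no targets."""
    roles = np.array([state.species[s].role for s in state.inc_species])
    targets = roles == "target"
    n = int(targets.sum())
    if n == 0:
        raise ValueError("activity fraction undefined: no target inclusions")
    return float((state.inc_state[targets] == 1).sum() / n)


def replay_activity(traj: Trajectory) -> np.ndarray:
    """Reconstruct the per-sweep activity series from the event log.

    Cross-check: must reproduce ``traj.activity`` exactly.
    """
    roles = np.array([traj.species[s].role for s in traj.initial_inc_species])
    target_ids = np.nonzero(roles == "target")[0]
    n_t = len(target_ids)
    if n_t == 0:
        return np.full(len(traj.sweeps), np.nan)
    states = traj.initial_inc_state.copy()
    out = np.empty(len(traj.sweeps), dtype=np.float64)
    ev = traj.events.sort_values("sweep", kind="stable")
    ev_iter = list(ev.itertuples(index=False))
    k = 0
    target_set = set(int(t) for t in target_ids)
    for i, sw in enumerate(traj.sweeps):
        while k < len(ev_iter) and ev_iter[k].sweep <= sw:
            e = ev_iter[k]
            states[e.inclusion] = e.new_state
            k += 1
        out[i] = sum(states[t] == 1 for t in target_set) / n_t
    return out


# ---------------------------------------------------------------------------
# radial cross-correlation

@lru_cache(maxsize=8)
def _lattice_distance_census(L: int, bin_width: float, rmax: float):
    """Histogram of minimum-image distances over all L^2 displacement
    vectors; the ideal-gas expectation for pair separations."""
    d = np.arange(L)
    d = np.minimum(d, L - d)
    dist = np.hypot(d[:, None], d[None, :]).ravel()
    edges = np.arange(0.0, rmax + bin_width, bin_width)
    census, _ = np.histogram(dist, bins=edges)
    return edges, census


def radial_cross_correlation(traj: Trajectory, species_a: str, species_b: str,
                             bin_width: float = 1.0,
                             rmax: float | None = None) -> pd.DataFrame:
    """Radially averaged pair correlation g(r) between two species.

    Histogram of minimum-image centre-to-centre distances, averaged over
    snapshots and normalized by the uniform-random expectation on the
    periodic lattice, so g = 1 for an ideal gas.
    """
    if not traj.snapshots:
        raise ValueError("trajectory has no snapshots")
    names = [s.name for s in traj.species]
    try:
        ia = names.index(species_a)
        ib = names.index(species_b)
    except ValueError as e:
        raise ValueError(f"unknown species in {species_a!r}/{species_b!r}") from e
    L = traj.snapshots[0].spin.shape[0]
    if rmax is None:
        rmax = L / 2.0
    edges, census = _lattice_distance_census(L, float(bin_width), float(rmax))
    counts = np.zeros(len(edges) - 1, dtype=np.float64)
    n_pairs_tot = 0.0
    for snap in traj.snapshots:
        sel_a = snap.inc_species == ia
        sel_b = snap.inc_species == ib
        na, nb = int(sel_a.sum()), int(sel_b.sum())
        if na == 0 or nb == 0:
            raise ValueError("a snapshot has no inclusions of a requested species")
        ax, ay = snap.inc_x[sel_a], snap.inc_y[sel_a]
        bx, by = snap.inc_x[sel_b], snap.inc_y[sel_b]
        dx = np.abs(ax[:, None] - bx[None, :])
        dy = np.abs(ay[:, None] - by[None, :])
        dx = np.minimum(dx, L - dx)
        dy = np.minimum(dy, L - dy)
        dist = np.hypot(dx, dy).ravel()
        if ia == ib:
            dist = dist[~np.eye(na, dtype=bool).ravel()]
            n_pairs = na * (na - 1)
        else:
            n_pairs = na * nb
        h, _ = np.histogram(dist, bins=edges)
        counts += h
        n_pairs_tot += n_pairs
    expected = census / (L * L) * n_pairs_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, np.nan)
    return pd.DataFrame({
        "r_lo": edges[:-1], "r_hi": edges[1:],
        "r_mid": 0.5 * (edges[:-1] + edges[1:]),
        "count": counts, "expected": expected, "g": g,
    })


# ---------------------------------------------------------------------------
# dark-domain clustering and pockets

@dataclass
class PocketRecord:
    """One qualifying dark cluster: site set plus occupant census."""

    sweep: int
    sites: np.ndarray             # (n, 2) lattice coordinates of the cluster
    census: dict                  # (species name, state name) -> count
    occupants: list               # inclusion ids whose footprint meets the cluster

    @property
    def size(self) -> int:
        return int(len(self.sites))


def _label_periodic(mask: np.ndarray) -> np.ndarray:
    """4-connected labelling with periodic wrap (union-find over edges)."""
    labels, n = ndimage.label(mask)  # default structure = 4-connectivity
    if n == 0:
        return labels
    parent = np.arange(n + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    top, bot = labels[0, :], labels[-1, :]
    for a, b in zip(top, bot):
        if a and b:
            union(a, b)
    left, right = labels[:, 0], labels[:, -1]
    for a, b in zip(left, right):
        if a and b:
            union(a, b)
    remap = np.array([find(i) for i in range(n + 1)])
    return remap[labels]


def dark_mask(state: LatticeState) -> np.ndarray:
    """Ordered-phase sites: +1 lipids plus the whole footprint of any
    inclusion whose current boundary value is +1 (order-preferring), so
    protein-rich domains still count as dark."""
    mask = (state.owner == LIPID) & (state.spin == 1)
    if state.n_inclusions:
        dark_inc = np.zeros(state.n_inclusions + 1, dtype=bool)
        dark_inc[:-1] = state.inc_b == 1
        inc_sites = state.owner >= 0
        mask = mask | (inc_sites & dark_inc[state.owner])
    return mask


def detect_dark_clusters(state: LatticeState, min_size: int = 10,
                         sweep: int = 0) -> list:
    """All 4-connected dark clusters of at least min_size sites, with the
    occupant census of every inclusion whose footprint meets the cluster."""
    labels = _label_periodic(dark_mask(state))
    if labels.max() == 0:
        return []
    # inclusion -> set of labels under its footprint
    inc_labels = []
    L = state.L
    for i in range(state.n_inclusions):
        offsets, _ = rasterize_disk(state.species[state.inc_species[i]].radius)
        xs = (state.inc_x[i] + offsets[:, 0]) % L
        ys = (state.inc_y[i] + offsets[:, 1]) % L
        inc_labels.append(set(int(v) for v in np.unique(labels[xs, ys])) - {0})
    records = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sites = np.argwhere(labels == lab)
        if len(sites) < min_size:
            continue
        census: dict = {}
        occupants = []
        for i in range(state.n_inclusions):
            if lab in inc_labels[i]:
                occupants.append(i)
                key = (state.species[state.inc_species[i]].name,
                       STATE_NAMES[state.inc_state[i]])
                census[key] = census.get(key, 0) + 1
        records.append(PocketRecord(sweep=sweep, sites=sites,
                                    census=census, occupants=occupants))
    return records


def is_pocket(record: PocketRecord, species: list) -> bool:
    """Composition criterion: >=1 active target, >=1 activator, 0 inactivators."""
    role_of = {s.name: s.role for s in species}
    n_active_targets = sum(c for (name, st), c in record.census.items()
                           if role_of.get(name) == "target" and st == "active")
    n_activators = sum(c for (name, _), c in record.census.items()
                       if role_of.get(name) == "activator")
    n_inactivators = sum(c for (name, _), c in record.census.items()
                         if role_of.get(name) == "inactivator")
    return n_active_targets >= 1 and n_activators >= 1 and n_inactivators == 0


def detect_pockets(state: LatticeState, min_size: int = 10,
                   sweep: int = 0) -> list:
    """Dark clusters of >= min_size sites whose occupant census shows at
    least one active target and one activator but no inactivator."""
    return [r for r in detect_dark_clusters(state, min_size, sweep)
            if is_pocket(r, state.species)]


def pocket_persistence(traj: Trajectory, min_size: int = 10) -> int:
    """Longest run of consecutive snapshots containing at least one pocket."""
    best = cur = 0
    for snap in traj.snapshots:
        state = snapshot_state(traj, snap)
        if detect_pockets(state, min_size=min_size, sweep=snap.sweep):
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


def flag_pocketed(mean_activities, persistences, iqr_mult: float = 0.5,
                  min_persist: int = 3) -> np.ndarray:
    """Operational pocketing flag across replicates of one condition.

    A replicate is flagged when its mean activity exceeds the
    across-replicate median by iqr_mult interquartile ranges AND a pocket
    persists for at least min_persist consecutive snapshots.  Persistence
    is the physical evidence; the activity clause discards transient
    clusters.  Defaults are calibrated on the pilot runs of the
    partition-switching protocol (see the methods note).
    """
    act = np.asarray(mean_activities, dtype=float)
    per = np.asarray(persistences, dtype=float)
    med = np.median(act)
    q1, q3 = np.percentile(act, [25, 75])
    iqr = q3 - q1
    return (act > med + iqr_mult * max(iqr, 1e-12)) & (per >= min_persist)
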