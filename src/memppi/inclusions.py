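"""Disk-shaped membrane inclusions: rasterization, placement, diffusion.

An inclusion is a rasterized disk (all offsets with dx^2 + dy^2 <= r^2)
whose boundary sites — footprint sites with at least one 4-neighbour
outside the footprint — carry a uniform spin value b set by the species'
partitioning preference for the inclusion's current activity state.
Interior sites carry no coupling.  Inclusions interact with each other
only through hard-core exclusion; all attraction is solvent-mediated.

Translation moves displace the lipid spins on the leading edge to the
trailing edge by a deterministic sorted-offset mapping, which makes the
proposal symmetric so plain Metropolis acceptance obeys detailed balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import _kernels
from .lattice import LIPID, EnergyModel, LatticeState, measure_magnetization

STATE_NAMES = ("inactive", "active")
STATE_INDEX = {"inactive": 0, "active": 1}


@dataclass
class InclusionSpec:
    """Species template for a PPI component.

    partition_by_state maps activity state -> boundary spin value:
    +1 prefers the ordered (dark) phase, -1 the disordered (bright) phase.
    Non-target species are conventionally created in the 'active'
    (reaction-competent) state.
    """

    name: str
    radius: int
    partition_by_state: dict = field(default_factory=lambda: {"inactive": 1, "active": 1})
    count: int = 1
    role: str = ""
    initial_state: str | None = None  # default: 'inactive' for targets, else 'active'

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        for s in STATE_NAMES:
            if s not in self.partition_by_state:
                raise ValueError(f"partition_by_state missing state '{s}'")
            if self.partition_by_state[s] not in (-1, 1):
                raise ValueError("boundary values must be +1 or -1")
        if self.initial_state is None:
            self.initial_state = "inactive" if self.role == "target" else "active"
        if self.initial_state not in STATE_NAMES:
            raise ValueError(f"unknown state '{self.initial_state}'")

    def boundary_value(self, state: str) -> int:
        return int(self.partition_by_state[state])


@dataclass
class Inclusion:
    """A placed instance (read-only view onto the lattice registry arrays)."""

    id: int
    species: InclusionSpec
    center: tuple
    activity_state: str
    boundary_value: int


def inclusion_views(state: LatticeState) -> list:
    return [
        Inclusion(
            id=i,
            species=state.species[state.inc_species[i]],
            center=(int(state.inc_x[i]), int(state.inc_y[i])),
            activity_state=STATE_NAMES[state.inc_state[i]],
            boundary_value=int(state.inc_b[i]),
        )
        for i in range(state.n_inclusions)
    ]


# ---------------------------------------------------------------------------
# rasterization and edge geometry

@lru_cache(maxsize=None)
def rasterize_disk(radius: int):
    """Closed-disk footprint offsets and boundary mask for integer radius.

    Returns (offsets, is_boundary): offsets is an (n, 2) int64 array of
    (dx, dy) with dx^2 + dy^2 <= r^2, sorted lexicographically; boundary
    sites are those with a 4-neighbour outside the footprint.
    r=0 is a single site (its own boundary); r=1 the 5-site plus shape.
    """
    r = int(radius)
    if r < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    pts = [(dx, dy)
           for dx in range(-r, r + 1)
           for dy in range(-r, r + 1)
           if dx * dx + dy * dy <= r * r]
    pts.sort()
    pset = set(pts)
    isb = np.array(
        [any((dx + ex, dy + ey) not in pset
             for ex, ey in ((1, 0), (-1, 0), (0, 1), (0, -1)))
         for dx, dy in pts],
        dtype=np.uint8)
    offsets = np.array(pts, dtype=np.int64).reshape(len(pts), 2)
    offsets.setflags(write=False)
    isb.setflags(write=False)
    return offsets, isb


_DIRS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@lru_cache(maxsize=None)
def edge_maps(radius: int):
    """Leading/trailing edge offsets (relative to the pre-move centre) for
    each of the four directions, sorted lexicographically.

    lead[d] are the newly covered sites of a move along d, trail[d] the
    newly vacated ones; counts match, and the k-th lead spin relocates to
    the k-th trail site.
    """
    offsets, _ = rasterize_disk(radius)
    fp = {(int(dx), int(dy)) for dx, dy in offsets}
    leads, trails = [], []
    for ddx, ddy in _DIRS:
        lead = sorted((ox + ddx, oy + ddy) for ox, oy in fp
                      if (ox + ddx, oy + ddy) not in fp)
        trail = sorted((ox, oy) for ox, oy in fp
                       if (ox - ddx, oy - ddy) not in fp)
        assert len(lead) == len(trail)
        leads.append(np.array(lead, dtype=np.int64).reshape(len(lead), 2))
        trails.append(np.array(trail, dtype=np.int64).reshape(len(trail), 2))
    return leads, trails


@lru_cache(maxsize=None)
def geometry_tables(rmax: int):
    """Flat, kernel-ready footprint/edge tables for radii 0..rmax.

    Returns a dict of arrays indexed as fp_start[r]..fp_start[r+1] for
    footprints and ed_start[r*4+d] for direction-d edges.
    """
    fp_dx, fp_dy, fp_isb = [], [], []
    fp_start = [0]
    ld_dx, ld_dy, tr_dx, tr_dy = [], [], [], []
    ed_start = [0]
    for r in range(rmax + 1):
        offsets, isb = rasterize_disk(r)
        fp_dx.extend(offsets[:, 0])
        fp_dy.extend(offsets[:, 1])
        fp_isb.extend(isb)
        fp_start.append(len(fp_dx))
        leads, trails = edge_maps(r)
        for d in range(4):
            ld_dx.extend(leads[d][:, 0])
            ld_dy.extend(leads[d][:, 1])
            tr_dx.extend(trails[d][:, 0])
            tr_dy.extend(trails[d][:, 1])
            ed_start.append(len(ld_dx))
    return {
        "fp_dx": np.array(fp_dx, dtype=np.int64),
        "fp_dy": np.array(fp_dy, dtype=np.int64),
        "fp_isb": np.array(fp_isb, dtype=np.uint8),
        "fp_start": np.array(fp_start, dtype=np.int64),
        "ld_dx": np.array(ld_dx, dtype=np.int64),
        "ld_dy": np.array(ld_dy, dtype=np.int64),
        "tr_dx": np.array(tr_dx, dtype=np.int64),
        "tr_dy": np.array(tr_dy, dtype=np.int64),
        "ed_start": np.array(ed_start, dtype=np.int64),
    }


def state_tables(state: LatticeState) -> dict:
    rmax = int(max((s.radius for s in state.species), default=0))
    return geometry_tables(rmax)


# ---------------------------------------------------------------------------
# placement

class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place an inclusion."""


def add_inclusion(state: LatticeState, spec: InclusionSpec,
                  center: tuple, activity_state: str | None = None) -> int:
    """Place one inclusion at an explicit centre; returns its id.

    Raises PackingError if the footprint overlaps an existing inclusion.
    """
    if 2 * spec.radius + 3 > state.L:
        raise ValueError(
            f"radius {spec.radius} too large for lattice side {state.L}")
    astate = activity_state if activity_state is not None else spec.initial_state
    sidx = _species_index(state, spec)
    offsets, isb = rasterize_disk(spec.radius)
    L = state.L
    cx, cy = int(center[0]) % L, int(center[1]) % L
    xs = (cx + offsets[:, 0]) % L
    ys = (cy + offsets[:, 1]) % L
    if np.any(state.owner[xs, ys] != LIPID):
        raise PackingError(
            f"footprint of '{spec.name}' at {(cx, cy)} overlaps an inclusion")
    iid = state.n_inclusions
    b = spec.boundary_value(astate)
    state.owner[xs, ys] = iid
    state.bnd[xs, ys] = isb
    state.spin[xs, ys] = np.where(isb.astype(bool), b, 0).astype(np.int8)
    state.inc_x = np.append(state.inc_x, cx)
    state.inc_y = np.append(state.inc_y, cy)
    state.inc_species = np.append(state.inc_species, sidx)
    state.inc_state = np.append(state.inc_state, STATE_INDEX[astate])
    state.inc_b = np.append(state.inc_b, np.int8(b))
    return iid


def _species_index(state: LatticeState, spec: InclusionSpec) -> int:
    for i, s in enumerate(state.species):
        if s is spec or s == spec:
            return i
    state.species.append(spec)
    return len(state.species) - 1


def place_inclusions(state: LatticeState, specs: list,
                     seed: int | None = None,
                     max_attempts: int = 10_000) -> LatticeState:
    """Place spec.count copies of each species at uniformly random
    non-overlapping positions (rejection sampling, reproducible by seed).

    Displaced lipid spins are removed from the lattice; the achieved
    magnetization should be re-measured afterwards.
    """
    area = sum(len(rasterize_disk(s.radius)[0]) * s.count for s in specs)
    if area >= state.L * state.L:
        raise PackingError("total inclusion footprint exceeds lattice area")
    rng = np.random.default_rng(seed) if seed is not None else state.rng
    for spec in specs:
        for _ in range(spec.count):
            for _attempt in range(max_attempts):
                cx = int(rng.integers(state.L))
                cy = int(rng.integers(state.L))
                try:
                    add_inclusion(state, spec, (cx, cy))
                    break
                except PackingError:
                    continue
            else:
                raise PackingError(
                    f"could not place '{spec.name}' after {max_attempts} attempts")
    return state


# ---------------------------------------------------------------------------
# dynamics

def inclusion_move_attempt(state: LatticeState, inclusion_id: int,
                           model: EnergyModel,
                           direction: int | None = None) -> tuple:
    """One Metropolis translation attempt for one inclusion.

    Proposes a one-site move in a uniformly random (or given) lattice
    direction (0:+x, 1:-x, 2:+y, 3:-y); rejects outright on hard-core
    overlap.  Returns (accepted, dE).
    """
    if state.temperature <= 0:
        raise ValueError("temperature must be positive")
    if not 0 <= inclusion_id < state.n_inclusions:
        raise IndexError(f"no inclusion with id {inclusion_id}")
    d = int(state.rng.integers(4)) if direction is None else int(direction)
    u = float(state.rng.random())
    t = state_tables(state)
    inc_r = _radii_array(state)
    acc, dE = _kernels.try_disk_move(
        state.spin, state.owner, state.bnd,
        state.inc_x, state.inc_y, inc_r, state.inc_b,
        inclusion_id, d, u,
        t["fp_dx"], t["fp_dy"], t["fp_isb"], t["fp_start"],
        t["ld_dx"], t["ld_dy"], t["tr_dx"], t["tr_dy"], t["ed_start"],
        model.J, model.J_int, state.temperature)
    return bool(acc), float(dE)


def _radii_array(state: LatticeState) -> np.ndarray:
    return np.array([state.species[s].radius for s in state.inc_species],
                    dtype=np.int64)


def detect_overlaps(state: LatticeState) -> list:
    """Exhaustive pairwise footprint-overlap check (testing aid).

    Returns a list of offending (id, id) pairs; empty means all disjoint.
    """
    L = state.L
    seen = {}
    bad = []
    for i in range(state.n_inclusions):
        offsets, _ = rasterize_disk(state.species[state.inc_species[i]].radius)
        for dx, dy in offsets:
            site = ((state.inc_x[i] + dx) % L, (state.inc_y[i] + dy) % L)
            if site in seen and seen[site] != i:
                bad.append((seen[site], i))
            seen[site] = i
    return sorted(set(bad))


def scheduler_step(state: LatticeState, model: EnergyModel, C: int = 1,
                   nsweeps: int = 1) -> float:
    """One (or more) full scheduler steps without reactions: a Kawasaki
    sweep interleaved with C translation attempts per inclusion in
    randomised order.  Returns accumulated dE.
    """
    from ._context import advance_state  # local import avoids a cycle
    result = advance_state(state, model, network=None, C=C, nsweeps=nsweeps)
    return result["dE"]
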