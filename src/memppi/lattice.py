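"""The two-dimensional Ising solvent: lattice state, energy, Kawasaki dynamics.

The membrane is an L x L square lattice with periodic boundaries.  Lipids
are Ising spins s = +/-1; s = +1 is the ordered (dark, liquid-ordered)
phase and s = -1 the disordered (bright, liquid-disordered) phase.  Lipid
diffusion is modelled by Kawasaki spin exchange, which conserves the order
parameter locally (model-B dynamics).  Composition is controlled by the
magnetization m = <s> over lipid sites, and temperature by the rescaled
temperature tau = T / Tc of the bare lattice, with Tc the Onsager critical
temperature 2J / ln(1 + sqrt(2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels

#: Onsager critical temperature of the bare square-lattice Ising model, J = 1.
TC_ONSAGER = 2.0 / math.log(1.0 + math.sqrt(2.0))

#: owner-grid value marking a lipid site
LIPID = -1


@dataclass
class EnergyModel:
    """Coupling constants of the lattice Hamiltonian.

    J is the nearest-neighbour lipid-lipid coupling and sets the energy
    unit; J > 0 is ferromagnetic, so like lipids attract and the membrane
    demixes below Tc.  J_int couples an inclusion's boundary spins to
    adjacent lipids; by default it equals J.
    """

    J: float = 1.0
    J_int: float = 1.0

    def __post_init__(self) -> None:
        if self.J <= 0:
            raise ValueError("J must be positive (ferromagnetic coupling)")


class LatticeState:
    """Full configurational state: spin grid, occupancy, inclusion registry.

    Attributes
    ----------
    spin : int8 array (L, L)
        Ising spin at lipid sites, boundary value at inclusion-boundary
        sites, 0 at inclusion-interior sites.
    owner : int32 array (L, L)
        ``LIPID`` (-1) for lipid sites, else the id of the owning inclusion.
    bnd : uint8 array (L, L)
        1 on inclusion-boundary sites.
    """

    def __init__(self, L: int, tau: float = 1.0, rng=None,
                 magnetization_target: float = 0.0):
        if L < 4:
            raise ValueError(f"lattice side must be >= 4, got {L}")
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.L = int(L)
        self.tau = float(tau)
        self.temperature = float(tau) * TC_ONSAGER
        self.magnetization_target = float(magnetization_target)
        self.rng = rng if rng is not None else np.random.default_rng()
        self.spin = np.zeros((L, L), dtype=np.int8)
        self.owner = np.full((L, L), LIPID, dtype=np.int32)
        self.bnd = np.zeros((L, L), dtype=np.uint8)
        # inclusion registry (parallel arrays; see memppi.inclusions)
        self.species: list = []            # list[InclusionSpec]
        self.inc_x = np.empty(0, dtype=np.int64)
        self.inc_y = np.empty(0, dtype=np.int64)
        self.inc_species = np.empty(0, dtype=np.int64)   # index into species
        self.inc_state = np.empty(0, dtype=np.int64)     # 0 inactive, 1 active
        self.inc_b = np.empty(0, dtype=np.int8)

    # -- occupancy helpers -------------------------------------------------

    @property
    def n_inclusions(self) -> int:
        return int(self.inc_x.shape[0])

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.owner == LIPID

    @property
    def n_lipid(self) -> int:
        return int(np.count_nonzero(self.owner == LIPID))

    def lipid_spin_sum(self) -> int:
        """Conserved quantity of Kawasaki dynamics: sum of lipid-site spins."""
        return int(self.spin[self.lipid_mask].sum(dtype=np.int64))

    def assign_lipid_spins(self, m: float, rng=None) -> float:
        """(Re)assign lipid spins as a uniform random permutation hitting m.

        The up-spin count is round(n_lipid * (1 + m) / 2).  Returns the
        achieved magnetization.
        """
        if not -1.0 <= m <= 1.0:
            raise ValueError(f"magnetization must lie in [-1, 1], got {m}")
        rng = rng if rng is not None else self.rng
        mask = self.lipid_mask
        n = int(mask.sum())
        if n == 0:
            raise ValueError("lattice has no lipid sites")
        n_up = int(round(n * (1.0 + m) / 2.0))
        vals = np.full(n, -1, dtype=np.int8)
        vals[:n_up] = 1
        rng.shuffle(vals)
        self.spin[mask] = vals
        self.magnetization_target = float(m)
        return measure_magnetization(self)

    def copy(self) -> "LatticeState":
        other = LatticeState.__new__(LatticeState)
        other.L = self.L
        other.tau = self.tau
        other.temperature = self.temperature
        other.magnetization_target = self.magnetization_target
        other.rng = np.random.default_rng(self.rng.integers(2**31))
        other.spin = self.spin.copy()
        other.owner = self.owner.copy()
        other.bnd = self.bnd.copy()
        other.species = list(self.species)
        other.inc_x = self.inc_x.copy()
        other.inc_y = self.inc_y.copy()
        other.inc_species = self.inc_species.copy()
        other.inc_state = self.inc_state.copy()
        other.inc_b = self.inc_b.copy()
        return other


def build_lattice(L: int, m: float, seed: int | None = None,
                  tau: float = 1.0) -> LatticeState:
    """Create a bare lattice (no inclusions) at target magnetization m.

    The number of up spins is round(L^2 (1+m)/2); placement is a uniform
    random permutation under the given seed.
    """
    state = LatticeState(L, tau=tau, rng=np.random.default_rng(seed),
                         magnetization_target=m)
    state.assign_lipid_spins(m)
    return state


def metropolis_table(model: EnergyModel, T: float):
    """Precomputed acceptance factors for the discrete swap energy changes.

    With integer couplings every Kawasaki dE is an integer bounded by
    12*max(J, J_int); the table maps dE + offset -> exp(-dE/T).  Returns
    (empty array, 0) for non-integer couplings, signalling the kernels to
    fall back to computing the exponential.
    """
    J, Jint = float(model.J), float(model.J_int)
    if not (J.is_integer() and Jint.is_integer()):
        return np.empty(0, dtype=np.float64), 0
    off = int(12 * max(abs(J), abs(Jint)))
    dE = np.arange(-off, off + 1, dtype=np.float64)
    return np.exp(-dE / T), off


def total_energy(state: LatticeState, model: EnergyModel) -> float:
    """Hamiltonian: -J sum_<ij> s_i s_j over lipid-lipid bonds
    plus -J_int sum over (boundary site, adjacent lipid) bonds.

    Each bond is counted once; periodic wrap included.
    """
    return float(_kernels.total_energy_kernel(
        state.spin, state.owner, state.bnd, model.J, model.J_int))


def kawasaki_sweep(state: LatticeState, model: EnergyModel,
                   nsweeps: int = 1) -> float:
    """Perform nsweeps Kawasaki sweeps in place; return accumulated dE.

    One sweep makes n_lipid exchange attempts: a uniformly random lipid
    site and a uniformly random 4-neighbour; a non-lipid neighbour is a
    null move; otherwise the spins are exchanged with Metropolis
    probability min(1, exp(-dE/T)).  The lipid-spin sum is conserved.
    """
    if state.temperature <= 0:
        raise ValueError("temperature must be positive")
    seed = int(state.rng.integers(2**31))
    table, off = metropolis_table(model, state.temperature)
    return float(_kernels.kawasaki_kernel(
        state.spin, state.owner, state.bnd, model.J, model.J_int,
        state.temperature, int(nsweeps), state.n_lipid, seed, table, off))


def equilibrate_exchange(state: LatticeState, model: EnergyModel,
                         nsweeps: int = 1) -> float:
    """Nonlocal spin-exchange sweeps: an equilibration aid, not the model's
    dynamics.  Swapping two uniformly random lipid sites per attempt has
    the same Boltzmann stationary law on the fixed-magnetization class as
    Kawasaki dynamics but without the diffusive critical slowing-down, so
    it reaches equilibrium at criticality in feasible time.  Returns dE.
    """
    if state.temperature <= 0:
        raise ValueError("temperature must be positive")
    seed = int(state.rng.integers(2**31))
    table, off = metropolis_table(model, state.temperature)
    return float(_kernels.global_exchange_kernel(
        state.spin, state.owner, state.bnd, model.J, model.J_int,
        state.temperature, int(nsweeps), state.n_lipid, seed, table, off))


def measure_magnetization(state: LatticeState) -> float:
    """Mean spin over lipid sites only (inclusion sites excluded)."""
    mask = state.lipid_mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("magnetization undefined: no lipid sites")
    return float(state.spin[mask].sum(dtype=np.int64) / n)


def onsager_internal_energy_critical() -> float:
    """Exact per-spin internal energy of the infinite lattice at Tc (-sqrt 2)."""
    return -math.sqrt(2.0)
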