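"""Canonical experiment protocols.

These fix the study conditions used throughout the package's own
validation runs: lattice side 48, four activators, four inactivators and
eight targets (matched across radii), contact reaction rate 0.1 per
contact per sweep, one translation attempt per disk per sweep, half the
sweeps discarded as burn-in.  Sizes are chosen so a full grid runs on a
single CPU in minutes while the near-critical trends remain resolvable;
all knobs stay overridable.
"""

from __future__ import annotations

from .config import ExperimentConfig, RunConfig
from .fixtures import (standard_rules, static_network_species,
                       switching_network_species)

DEFAULT_L = 48
DEFAULT_SWEEPS = 20_000
DEFAULT_RATE = 0.1
#: tau grid spanning the critical region; finer near tau = 1
DEFAULT_TAU_GRID = (0.85, 0.9, 0.95, 1.0, 1.05, 1.1, 1.2, 1.3)


def static_cascade_config(radius: int = 2, tau: float = 1.0, m: float = 0.0,
                          L: int = DEFAULT_L, sweeps: int = DEFAULT_SWEEPS,
                          rate: float = DEFAULT_RATE, seed: int = 0,
                          pre_equilibrate: int = 2000,
                          n_activators: int = 6, n_inactivators: int = 6,
                          n_targets: int = 12) -> RunConfig:
    """Fixed-partitioning cascade: activator prefers the disordered phase,
    inactivator and target the ordered phase.  The solvent and component
    positions are pre-equilibrated with reactions off (their joint
    ensemble is Boltzmann for this network), so the reaction phase starts
    from a typical domain configuration."""
    return RunConfig(
        lattice_size=L, tau=tau, magnetization=m,
        species=static_network_species(radius=radius,
                                       n_activators=n_activators,
                                       n_inactivators=n_inactivators,
                                       n_targets=n_targets),
        rules=standard_rules(rate),
        sweeps=sweeps, pre_equilibrate_sweeps=pre_equilibrate,
        snapshot_interval=max(sweeps // 10, 1), seed=seed)


def switching_cascade_config(radius: int = 2, tau: float = 1.0, m: float = 0.0,
                             L: int = DEFAULT_L, sweeps: int = 20_000,
                             rate: float = DEFAULT_RATE, seed: int = 0,
                             pre_equilibrate: int = 2000,
                             n_activators: int = 6, n_inactivators: int = 6,
                             n_targets: int = 12) -> RunConfig:
    """Partition-switching cascade (recruiter/excluder motif): the target
    switches from disorder- to order-preferring on activation.  Longer
    default schedule because pocket formation is slow; pre-equilibration
    samples the all-inactive equilibrium the reactions then perturb."""
    return RunConfig(
        lattice_size=L, tau=tau, magnetization=m,
        species=switching_network_species(radius=radius,
                                          n_activators=n_activators,
                                          n_inactivators=n_inactivators,
                                          n_targets=n_targets),
        rules=standard_rules(rate),
        sweeps=sweeps, pre_equilibrate_sweeps=pre_equilibrate,
        snapshot_interval=max(sweeps // 20, 1), seed=seed)


#: tau grid of the radius/growth-width protocol: fine near the bare
#: critical point, extended upward because inclusions shift the composite
#: system's critical point above tau = 1
RADIUS_TAU_GRID = (0.85, 0.95, 1.05, 1.15, 1.3, 1.5)


def radius_tau_sweep(radii=(0, 1, 2, 3), taus=RADIUS_TAU_GRID, replicates=10,
                     master_seed=5200, L=DEFAULT_L, sweeps=10_000,
                     **kw) -> ExperimentConfig:
    """Activity vs rescaled temperature for matched inclusion counts
    (4 activators / 4 inactivators / 8 targets) across radii — the
    radius/growth-width protocol.  Counts are kept low so even r=3 disks
    cover only ~20% of the lattice and the critical-point shift stays
    moderate."""
    base = static_cascade_config(radius=max(radii), L=L, sweeps=sweeps,
                                 n_activators=4, n_inactivators=4,
                                 n_targets=8, **kw)
    return ExperimentConfig(base=base, taus=list(taus), radii=list(radii),
                            replicates=replicates, master_seed=master_seed)


def m_contrast(radii=(0, 3), ms=(-0.4, 0.0, 0.4), tau=1.1, replicates=8,
               master_seed=6200, L=64, sweeps=16_000,
               **kw) -> ExperimentConfig:
    """Activity vs magnetization at fixed tau for small vs large disks
    (the composition-sensitivity protocol).

    Conditions differ from the radius protocol for physical reasons found
    in calibration: the composition effect needs an inactivator-rich
    cascade (4 activators / 8 inactivators / 8 targets — otherwise the few
    excluders segregate away from targets in the scarce dark droplets at
    negative m, a discrete-number artifact that reverses the trend), a
    larger lattice, tau slightly above the bare critical point, and long
    pre-equilibration with doubled disk mobility so component positions
    reach their equilibrium sorting."""
    import dataclasses
    base = static_cascade_config(radius=max(radii), tau=tau, L=L,
                                 sweeps=sweeps, pre_equilibrate=6000,
                                 n_activators=4, n_inactivators=8,
                                 n_targets=8, **kw)
    base = dataclasses.replace(base, disk_attempts=2)
    return ExperimentConfig(base=base, ms=list(ms), radii=list(radii),
                            replicates=replicates, master_seed=master_seed)


def pocketing_config(tau: float, m: float, sweeps: int = 40_000,
                     seed: int = 0) -> RunConfig:
    """One pocketing run of the partition-switching network.

    Pockets need room to nucleate away from the spanning dark phase and
    time to grow, so this protocol uses a larger lattice (L=64, 8/8/16
    components of r=2 at ~10% area), doubled disk mobility (C=2, so the
    slow protein-diffusion kinetics fit into the sweep budget) and long
    schedules."""
    cfg = switching_cascade_config(radius=2, tau=tau, m=m, L=64,
                                   sweeps=sweeps, n_activators=8,
                                   n_inactivators=8, n_targets=16, seed=seed)
    import dataclasses
    return dataclasses.replace(cfg, disk_attempts=2)
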