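"""Run configuration: schema, validation, YAML loading, hashing.

A run is fully specified by the lattice geometry (size, rescaled
temperature tau, magnetization m), the energy model (J, J_int), the
inclusion species with their partitioning legs, the reaction rules, the
sweep schedule and a seed.  Unknown keys are rejected by name so typos
cannot silently change a simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .inclusions import InclusionSpec
from .reactions import ReactionNetwork, ReactionRule


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    lattice_size: int = 64
    tau: float = 1.0
    magnetization: float = 0.0
    J: float = 1.0
    J_int: float = 1.0
    species: list = field(default_factory=list)   # list[InclusionSpec]
    rules: list = field(default_factory=list)     # list[ReactionRule]
    sweeps: int = 10_000
    #: configurational pre-equilibration with reactions disabled (sweeps of
    #: nonlocal lipid exchange alternated with normal scheduler steps)
    pre_equilibrate_sweeps: int = 0
    burn_in_fraction: float = 0.5
    snapshot_interval: int = 1000
    disk_attempts: int = 1
    seed: int = 0
    output: str | None = None

    def __post_init__(self) -> None:
        if self.lattice_size < 4:
            raise ConfigError("lattice_size must be >= 4")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if not -1.0 <= self.magnetization <= 1.0:
            raise ConfigError("magnetization must lie in [-1, 1]")
        if self.sweeps <= 0:
            raise ConfigError("sweeps must be positive")
        if self.pre_equilibrate_sweeps < 0:
            raise ConfigError("pre_equilibrate_sweeps must be >= 0")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ConfigError("burn_in_fraction must lie in [0, 1)")
        if self.snapshot_interval <= 0:
            raise ConfigError("snapshot_interval must be positive")
        if self.disk_attempts < 0:
            raise ConfigError("disk_attempts must be >= 0")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate species names")
        for r in self.rules:
            for ref in (r.actor_species, r.target_species):
                if ref not in names:
                    raise ConfigError(
                        f"rule references undeclared species '{ref}'")
        for s in self.species:
            if 2 * s.radius + 3 > self.lattice_size:
                raise ConfigError(
                    f"species '{s.name}' radius {s.radius} too large for "
                    f"lattice_size {self.lattice_size}")

    def network(self) -> ReactionNetwork:
        return ReactionNetwork(species=list(self.species),
                               rules=list(self.rules))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        """Stable digest over the semantic content (output path excluded)."""
        d = self.to_dict()
        d.pop("output", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_RUN_KEYS = {
    "lattice_size", "tau", "magnetization", "J", "J_int", "species", "rules",
    "sweeps", "pre_equilibrate_sweeps", "burn_in_fraction",
    "snapshot_interval", "disk_attempts", "seed", "output",
}
_SPECIES_KEYS = {"name", "radius", "count", "role", "partition", "initial_state"}
_RULE_KEYS = {"actor", "target", "before", "after", "rate"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    raw = dict(raw)
    raw.pop("experiment", None)  # experiment grids are parsed separately
    _check_keys(raw, _RUN_KEYS, "run config")
    species = []
    for i, sd in enumerate(raw.pop("species", []) or []):
        _check_keys(sd, _SPECIES_KEYS, f"species[{i}]")
        if "name" not in sd:
            raise ConfigError(f"species[{i}] is missing 'name'")
        part = sd.get("partition", {"inactive": 1, "active": 1})
        if isinstance(part, int):
            part = {"inactive": part, "active": part}
        species.append(InclusionSpec(
            name=sd["name"],
            radius=int(sd.get("radius", 0)),
            count=int(sd.get("count", 1)),
            role=sd.get("role", ""),
            partition_by_state={k: int(v) for k, v in part.items()},
            initial_state=sd.get("initial_state"),
        ))
    rules = []
    for i, rd in enumerate(raw.pop("rules", []) or []):
        _check_keys(rd, _RULE_KEYS, f"rules[{i}]")
        for key in ("actor", "target"):
            if key not in rd:
                raise ConfigError(f"rules[{i}] is missing '{key}'")
        rules.append(ReactionRule(
            actor_species=rd["actor"],
            target_species=rd["target"],
            target_state_before=rd.get("before", "inactive"),
            target_state_after=rd.get("after", "active"),
            rate_per_contact_sweep=float(rd.get("rate", 0.1)),
        ))
    try:
        return RunConfig(species=species, rules=rules, **raw)
    except TypeError as e:
        raise ConfigError(str(e)) from e


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw or {})


@dataclass
class ExperimentConfig:
    """A grid experiment over (tau, m, radius) with seeded replicates."""

    base: RunConfig
    taus: list = field(default_factory=list)
    ms: list = field(default_factory=list)
    radii: list = field(default_factory=list)   # uniform radius override
    replicates: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not self.taus:
            self.taus = [self.base.tau]
        if not self.ms:
            self.ms = [self.base.magnetization]
        if not self.radii:
            self.radii = [None]


def experiment_from_dict(raw: dict) -> ExperimentConfig:
    base = config_from_dict(raw)
    exp = dict(raw.get("experiment") or {})
    _check_keys(exp, {"taus", "ms", "radii", "replicates", "master_seed"},
                "experiment")
    return ExperimentConfig(
        base=base,
        taus=list(exp.get("taus", [])),
        ms=list(exp.get("ms", [])),
        radii=list(exp.get("radii", [])),
        replicates=int(exp.get("replicates", 1)),
        master_seed=int(exp.get("master_seed", base.seed)),
    )


def load_experiment(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return experiment_from_dict(raw or {})
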