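# Grid experiment: activity vs rescaled temperature for the static cascade.
lattice_size: 48
tau: 1.0
magnetization: 0.0
sweeps: 8000
pre_equilibrate_sweeps: 2000
snapshot_interval: 2000
seed: 1
species:
  - {name: activator, radius: 1, count: 6, role: activator,
     partition: {inactive: -1, active: -1}}
  - {name: inactivator, radius: 1, count: 6, role: inactivator,
     partition: {inactive: 1, active: 1}}
  - {name: target, radius: 1, count: 12, role: target,
     partition: {inactive: 1, active: 1}}
rules:
  - {actor: activator, target: target, before: inactive, after: active, rate: 0.1}
  - {actor: inactivator, target: target, before: active, after: inactive, rate: 0.1}
experiment:
  taus: [0.85, 0.95, 1.05, 1.15, 1.3]
  replicates: 3
  master_seed: 7
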