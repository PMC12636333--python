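# Partition-switching cascade (recruiter/excluder motif): both enzymes
# prefer the ordered phase; the target prefers disorder while inactive
# and switches to order on activation.
lattice_size: 48
tau: 0.9
magnetization: -0.4
sweeps: 20000
pre_equilibrate_sweeps: 2000
snapshot_interval: 1000
disk_attempts: 1
seed: 1
species:
  - {name: activator, radius: 2, count: 6, role: activator,
     partition: {inactive: 1, active: 1}}
  - {name: inactivator, radius: 2, count: 6, role: inactivator,
     partition: {inactive: 1, active: 1}}
  - {name: target, radius: 2, count: 12, role: target,
     partition: {inactive: -1, active: 1}}
rules:
  - {actor: activator, target: target, before: inactive, after: active, rate: 0.1}
  - {actor: inactivator, target: target, before: active, after: inactive, rate: 0.1}
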