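# Guppy study conditions: model-3 state means/persistences as reported for
# the guppy fit, driver chain using the guppy model-2 means.  Unreported
# standard deviations and minor transition entries follow the package
# defaults documented in docs/methods.md.
n_trials: 30
n_individuals: 12
n_points: 600
step: 1.0
means: [2.96, 0.20]
sds: [2.0, 0.15]
social_sd: 1.0
mean_floor: 0.05
transition:
  - [0.95, 0.03, 0.02]
  - [0.04, 0.95, 0.01]
  - [0.44, 0.00, 0.56]
driver_transition:
  - [0.95, 0.05]
  - [0.05, 0.95]
driver_means: [3.05, 0.22]
driver_sds: [2.0, 0.15]
gap_rate: 0.0
seed: 1
arena_size: 60.0
heading_mode: independent
turn_sd: 0.4
walk_speed: 3.0
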