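# Stickleback study conditions: model-3 state means as reported for the
# stickleback fit (faster / slower movement states); remaining parameters
# follow the package defaults documented in docs/methods.md.
n_trials: 30
n_individuals: 8
n_points: 600
step: 1.0
means: [14.45, 5.59]
sds: [4.0, 2.0]
social_sd: 2.0
mean_floor: 0.05
transition:
  - [0.90, 0.02, 0.08]
  - [0.05, 0.90, 0.05]
  - [0.25, 0.05, 0.70]
driver_transition:
  - [0.90, 0.10]
  - [0.10, 0.90]
driver_means: [14.45, 5.59]
driver_sds: [4.0, 2.0]
gap_rate: 0.0
seed: 2
arena_size: 60.0
heading_mode: shared
turn_sd: 0.3
walk_speed: 12.0
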