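"""Viterbi decoding and characterisation of social behaviour.

Fits the social model, decodes the most probable behavioural-state path
of every individual, and summarises: state occupancy, state-conditional
mean speeds, how many individuals are social at the same time, and the
speeds of social fish split by whether their nearest neighbours are also
social.
"""

from dataclasses import replace

import numpy as np

from shoalhmm import (
    SimConfig,
    fit_model,
    occupancy,
    simulate_driver_focal,
    social_count_per_timepoint,
    speeds_by_social_nn,
    state_conditional_speeds,
    viterbi_decode,
)

cfg = SimConfig(
    n_trials=2, n_individuals=5, n_points=500,
    means=(3.0, 0.3), sds=(1.0, 0.2), social_sd=0.3,
    transition=[[0.7, 0.1, 0.2], [0.1, 0.7, 0.2], [0.25, 0.05, 0.7]],
    driver_means=(4.0, 1.0), driver_sds=(1.5, 0.5),
    seed=42)
sim = simulate_driver_focal(cfg)
fit = fit_model(sim.series, "model3", n_starts=4, rng_seed=0)

# decode drivers too, with the focal as their nearest neighbour, so the
# shoal's neighbour graph is complete and social-neighbour counts make sense
all_series = list(sim.series)
for focal, driver in zip(sim.series, sim.drivers):
    all_series.append(replace(
        driver, nn_speeds=focal.speeds.copy(),
        nn_ids=np.array([focal.individual_id] * len(focal), dtype=object)))
decodings = [viterbi_decode(s, fit.spec) for s in all_series]

occ = occupancy(decodings[:len(sim.series)])
print("occupancy (state 1 moving / 2 stationary / 3 social):",
      np.round(occ.fraction_by_state, 3))
truth = np.concatenate(sim.states)
decoded = np.concatenate([d.states for d in decodings[:len(sim.series)]])
print(f"decoding accuracy vs ground truth: {np.mean(truth == decoded):.3f}")

cond = state_conditional_speeds(decodings[:len(sim.series)], sim.series)
for state, speeds in cond.items():
    print(f"state {state}: n={len(speeds):5d}  mean speed={speeds.mean():.2f} cm/s")

summary = social_count_per_timepoint(decodings, all_series)
print("number of social fish per time point:",
      dict(enumerate(summary.histogram.tolist())))
for k, speeds in speeds_by_social_nn(summary).items():
    print(f"{k} social nearest neighbour(s): n={len(speeds):5d}  "
          f"mean speed={speeds.mean():.2f} cm/s")
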