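"""Shared fixtures and independent oracles for the test suite."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammainc

from shoalhmm import (
    GammaSpec,
    SimConfig,
    SpeedSeries,
    TrajectoryDataset,
)

V_CLAMP = 1e-3
MEAN_FLOOR = 0.05


def make_dataset(rows, frame_rate=10.0, group_size=2, trial_id="t0"):
    """Build a TrajectoryDataset from (frame, id, x, y, tracked) tuples."""
    df = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "tracked"])
    return TrajectoryDataset(trial_id=trial_id, frame_rate=frame_rate,
                             group_size=group_size, records=df)


def make_series(speeds, nn_speeds=None, step=1.0, segments=None,
                individual_id="a", trial_id="t0", t0=0.0):
    speeds = np.asarray(speeds, dtype=float)
    n = len(speeds)
    if segments is None:
        segments = [(0, n)]
    times = np.empty(n)
    cursor = t0
    for a, b in segments:
        times[a:b] = cursor + np.arange(b - a) * step
        cursor = times[b - 1] + 2 * step  # gap between segments
    nn = None if nn_speeds is None else np.asarray(nn_speeds, dtype=float)
    nn_ids = None if nn is None else np.array(["b"] * n, dtype=object)
    return SpeedSeries(individual_id=individual_id, trial_id=trial_id,
                       times=times, speeds=speeds, step=step,
                       segments=segments, nn_speeds=nn, nn_ids=nn_ids)


# ---------------------------------------------------------------------------
# independent likelihood oracle: exhaustive path enumeration with scipy


def oracle_emission_logprob(v, mean, sd, v_clamp=V_CLAMP):
    """Censored gamma emission log-probability, computed via scipy only."""
    shape = mean ** 2 / sd ** 2
    scale = sd ** 2 / mean
    if v <= v_clamp:
        return float(np.log(max(gammainc(shape, v_clamp / scale), 1e-300)))
    return float(stats.gamma.logpdf(v, a=shape, scale=scale))


def oracle_state_emission(v, nn, spec, state, v_clamp=V_CLAMP):
    em = spec.emissions[state]
    if isinstance(em, GammaSpec):
        return oracle_emission_logprob(v, em.mean, em.sd, v_clamp)
    mean = max(nn, em.mean_floor)
    return oracle_emission_logprob(v, mean, em.sd, v_clamp)


def oracle_stationary(trans):
    vals, vecs = np.linalg.eig(np.asarray(trans, dtype=float).T)
    i = int(np.argmin(np.abs(vals - 1)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


def brute_force_loglik(series, spec):
    """Sum over all state paths of one-segment-at-a-time enumeration."""
    pi = oracle_stationary(spec.transition) if spec.transition is not None else np.ones(1)
    t = spec.transition if spec.transition is not None else np.ones((1, 1))
    n_states = len(spec.emissions)
    nn = series.nn_speeds if series.nn_speeds is not None else np.zeros(len(series))
    total = 0.0
    for a, b in series.segments:
        seg_total = -np.inf
        for path in product(range(n_states), repeat=b - a):
            lp = np.log(pi[path[0]]) + oracle_state_emission(
                series.speeds[a], nn[a], spec, path[0])
            for j in range(1, b - a):
                lp += (np.log(t[path[j - 1], path[j]])
                       + oracle_state_emission(series.speeds[a + j], nn[a + j],
                                               spec, path[j]))
            seg_total = np.logaddexp(seg_total, lp)
        total += seg_total
    return total


def brute_force_viterbi(series, spec):
    """Argmax state path per segment by exhaustive enumeration (1-based)."""
    pi = oracle_stationary(spec.transition) if spec.transition is not None else np.ones(1)
    t = spec.transition if spec.transition is not None else np.ones((1, 1))
    n_states = len(spec.emissions)
    nn = series.nn_speeds if series.nn_speeds is not None else np.zeros(len(series))
    out = np.empty(len(series), dtype=int)
    for a, b in series.segments:
        best_lp, best_path = -np.inf, None
        for path in product(range(n_states), repeat=b - a):
            lp = np.log(pi[path[0]]) + oracle_state_emission(
                series.speeds[a], nn[a], spec, path[0])
            for j in range(1, b - a):
                lp += (np.log(t[path[j - 1], path[j]])
                       + oracle_state_emission(series.speeds[a + j], nn[a + j],
                                               spec, path[j]))
            if lp > best_lp:
                best_lp, best_path = lp, path
        out[a:b] = np.asarray(best_path) + 1
    return out


# ---------------------------------------------------------------------------
# shared fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def small_sim_config():
    """Small, strongly coupled study conditions for fast end-to-end tests."""
    return SimConfig(
        n_trials=2, n_individuals=5, n_points=500,
        means=(3.0, 0.3), sds=(1.0, 0.2), social_sd=0.3,
        transition=[[0.7, 0.1, 0.2], [0.1, 0.7, 0.2], [0.25, 0.05, 0.7]],
        driver_means=(4.0, 1.0), driver_sds=(1.5, 0.5),
        driver_transition=[[0.9, 0.1], [0.1, 0.9]],
        seed=11)


@pytest.fixture(scope="session")
def null_sim_config():
    """Conditions with no social coupling (no entry into state 3)."""
    return SimConfig(
        n_trials=1, n_individuals=4, n_points=500,
        means=(3.0, 0.3), sds=(1.0, 0.2), social_sd=0.3,
        transition=[[0.9, 0.1, 0.0], [0.1, 0.9, 0.0], [0.25, 0.05, 0.7]],
        driver_means=(4.0, 1.0), driver_sds=(1.5, 0.5),
        driver_transition=[[0.9, 0.1], [0.1, 0.9]],
        seed=12)
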