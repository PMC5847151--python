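"""Summaries of Viterbi-decoded behaviour.

Given decoded state sequences aligned to speed series, this module
computes (i) pooled state occupancy, (ii) state-conditional speed samples
and empirical CDFs, (iii) the per-timepoint distribution of the number of
individuals in the social state within a shoal, and (iv) speed samples of
social individuals conditioned on how many of their nearest neighbours
are also social.

The phrase "nearest neighbours that are also social" admits two graph
readings for a focal fish: its own nearest neighbour (out-edge) and the
individuals whose nearest neighbour is the focal fish (in-edges).  The
default counts social individuals over the union of both; either single
reading can be selected via ``neighbour_def``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hmm_core import StateDecoding
from .trajectory_io import SpeedSeries

__all__ = [
    "OccupancySummary",
    "SocialCountSummary",
    "occupancy",
    "state_conditional_speeds",
    "social_count_per_timepoint",
    "speeds_by_social_nn",
    "ecdf",
]


@dataclass
class OccupancySummary:
    """Pooled fraction of time points per state (sums to 1)."""

    fraction_by_state: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fraction_by_state, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1) > 1e-12:
            raise ParameterError("fractions must be non-negative and sum to 1")
        self.fraction_by_state = f


@dataclass
class SocialCountSummary:
    """Distribution of the number of social individuals per time point.

    ``histogram[k]`` counts complete decoded time points with exactly
    ``k`` individuals in the social state (k = 0..N);
    ``conditional_speeds[k]`` holds speeds of social focal individuals
    with ``k`` social nearest neighbours.
    """

    histogram: np.ndarray
    conditional_speeds: dict[int, np.ndarray]
    n_timepoints: int
    group_size: int
    social_state: int


def occupancy(decodings: list[StateDecoding]) -> OccupancySummary:
    """Pooled fraction of decoded points in each state."""
    if not decodings:
        raise ParameterError("no decodings supplied")
    n_states = {d.n_states for d in decodings}
    if len(n_states) != 1:
        raise ParameterError("decodings come from different models")
    n_states = n_states.pop()
    counts = np.zeros(n_states)
    for d in decodings:
        counts += np.bincount(d.states - 1, minlength=n_states)
    total = counts.sum()
    if total == 0:
        raise ParameterError("decodings contain no points")
    return OccupancySummary(fraction_by_state=counts / total, n_points=int(total))


def ecdf(sample: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF support points and values (monotone, ends at 1)."""
    x = np.sort(np.asarray(sample, dtype=float))
    return x, np.arange(1, len(x) + 1) / len(x)


def state_conditional_speeds(decodings: list[StateDecoding],
                             series_set: list[SpeedSeries]) -> dict[int, np.ndarray]:
    """Speeds partitioned by decoded state (keys are 1-based states)."""
    if len(decodings) != len(series_set):
        raise ParameterError("decodings and series counts differ")
    n_states = decodings[0].n_states
    buckets: dict[int, list] = {s: [] for s in range(1, n_states + 1)}
    for d, s in zip(decodings, series_set):
        if len(d.states) != len(s):
            raise ParameterError("decoding and series lengths differ")
        for state in range(1, n_states + 1):
            buckets[state].append(s.speeds[d.states == state])
    return {state: np.concatenate(v) if v else np.empty(0)
            for state, v in buckets.items()}


def _complete_timepoint_table(decodings, series_set):
    """Long table (trial, time, id, state, speed, nn_id) restricted to
    time points at which every individual of the trial is decoded."""
    if len(decodings) != len(series_set):
        raise ParameterError("decodings and series counts differ")
    rows = []
    for d, s in zip(decodings, series_set):
        if len(d.states) != len(s):
            raise ParameterError("decoding and series lengths differ")
        nn = s.nn_ids if s.nn_ids is not None else np.array([""] * len(s), dtype=object)
        rows.append(pd.DataFrame({
            "trial": s.trial_id, "time": s.times, "id": s.individual_id,
            "state": d.states, "speed": s.speeds, "nn_id": nn}))
    df = pd.concat(rows, ignore_index=True)
    sizes = df.groupby("trial")["id"].nunique()
    counts = df.groupby(["trial", "time"])["id"].nunique()
    full = counts[counts == sizes.reindex(counts.index.get_level_values(0)).to_numpy()]
    df = df.set_index(["trial", "time"]).loc[full.index].reset_index()
    return df, sizes


def social_count_per_timepoint(decodings: list[StateDecoding],
                               series_set: list[SpeedSeries],
                               social_state: int | None = None,
                               neighbour_def: str = "both") -> SocialCountSummary:
    """Per-timepoint social counts and neighbour-conditioned speed samples.

    Only time points at which all individuals of a trial are decoded enter.
    ``neighbour_def`` selects the neighbour set of a focal fish: ``"out"``
    (its own nearest neighbour), ``"in"`` (individuals whose nearest
    neighbour is the focal fish) or ``"both"`` (union, the default).
    """
    if neighbour_def not in ("out", "in", "both"):
        raise ParameterError("neighbour_def must be 'out', 'in' or 'both'")
    if social_state is None:
        social_state = decodings[0].n_states
    df, sizes = _complete_timepoint_table(decodings, series_set)
    group_size = int(sizes.max()) if len(sizes) else 0
    hist = np.zeros(group_size + 1, dtype=np.int64)
    cond: dict[int, list] = {}
    n_timepoints = 0
    for (_, _), sub in df.groupby(["trial", "time"], sort=True):
        n_timepoints += 1
        social = dict(zip(sub["id"], sub["state"] == social_state))
        speed = dict(zip(sub["id"], sub["speed"]))
        nn = dict(zip(sub["id"], sub["nn_id"]))
        k_social = sum(social.values())
        hist[k_social] += 1
        for focal, is_soc in social.items():
            if not is_soc:
                continue
            neigh: set[str] = set()
            if neighbour_def in ("out", "both") and nn.get(focal):
                neigh.add(nn[focal])
            if neighbour_def in ("in", "both"):
                neigh.update(i for i, j in nn.items() if j == focal)
            k = sum(social.get(i, False) for i in neigh)
            cond.setdefault(k, []).append(speed[focal])
    return SocialCountSummary(
        histogram=hist,
        conditional_speeds={k: np.asarray(v) for k, v in sorted(cond.items())},
        n_timepoints=n_timepoints, group_size=group_size,
        social_state=social_state)


def speeds_by_social_nn(summary: SocialCountSummary) -> dict[int, np.ndarray]:
    """Speed samples keyed by the number of social nearest neighbours.

    Empty keys are omitted; sample sizes are the array lengths.
    """
    return {k: v for k, v in summary.conditional_speeds.items() if len(v)}
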