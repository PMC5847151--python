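"""Synthetic speed series and trajectories with the models' statistical structure.

The fitted social model cannot be simulated directly (the social emission
conditions on the neighbour's *concurrent* speed, which would itself have
to be simulated), so the generator uses a driver-focal construction: each
focal individual is paired with an independently simulated *driver* whose
2-state gamma-HMM speed series plays the role of the nearest-neighbour
covariate.  The focal follows a 3-state Markov chain; in states 1-2 its
speeds are gamma draws with constant means, and in the social state 3 they
are gamma draws whose mean is the driver's concurrent speed (floored).
This reproduces exactly the dependence structure the model-3 likelihood
assumes, with known ground-truth states, and reduces to a model-2
generator when the transition probabilities into state 3 are zero.

A separate generator produces 2D correlated random walks in a square arena
(with an optional shared-heading mode) to exercise the trajectory pipeline
and the order parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParameterError
from .hmm_core import MEAN_FLOOR, stationary_distribution
from .trajectory_io import SpeedSeries, TrajectoryDataset, subset_series

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_driver_focal",
    "simulate_group_positions",
    "inject_gaps",
    "load_config",
    "preset",
    "PRESETS",
]

PRESETS = ("guppy", "stickleback")


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Speeds are cm/s, times seconds.  ``transition`` is the focal's 3x3
    state chain (state 3 social); ``driver_transition`` the driver's 2x2
    chain over the same two non-social emission distributions unless
    ``driver_means``/``driver_sds`` override them.
    """

    n_trials: int = 1
    n_individuals: int = 2
    n_points: int = 600
    step: float = 1.0
    means: tuple[float, float] = (3.0, 0.3)
    sds: tuple[float, float] = (2.0, 0.2)
    social_sd: float = 1.0
    mean_floor: float = MEAN_FLOOR
    transition: list = field(default_factory=lambda: [
        [0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.3, 0.05, 0.65]])
    driver_transition: list = field(default_factory=lambda: [[0.9, 0.1], [0.1, 0.9]])
    driver_means: tuple[float, float] | None = None
    driver_sds: tuple[float, float] | None = None
    gap_rate: float = 0.0
    seed: int = 0
    # position-simulation settings
    arena_size: float = 60.0
    heading_mode: str = "independent"  # or "shared"
    turn_sd: float = 0.4
    walk_speed: float = 3.0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        d = np.asarray(self.driver_transition, dtype=float)
        if t.shape != (3, 3) or d.shape != (2, 2):
            raise ConfigurationError("transition must be 3x3 and driver_transition 2x2")
        for m in (t, d):
            if (m < 0).any() or np.abs(m.sum(axis=1) - 1).max() > 1e-9:
                raise ConfigurationError("transition rows must sum to 1 and be non-negative")
        if not all(x > 0 for x in (*self.means, *self.sds, self.social_sd,
                                   self.mean_floor, self.step)):
            raise ConfigurationError("means, sds, social_sd, mean_floor, step must be positive")
        if not (0 <= self.gap_rate < 1):
            raise ConfigurationError("gap_rate must lie in [0, 1)")
        if self.heading_mode not in ("independent", "shared"):
            raise ConfigurationError("heading_mode must be 'independent' or 'shared'")
        if min(self.n_trials, self.n_individuals, self.n_points) < 1:
            raise ConfigurationError("n_trials, n_individuals, n_points must be >= 1")
        self.transition = t.tolist()
        self.driver_transition = d.tolist()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("means", "sds", "driver_means", "driver_sds"):
            if d.get(key) is not None:
                d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> SimConfig:
    """Read a SimConfig from a YAML key-value file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("means", "sds", "driver_means", "driver_sds"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return SimConfig(**d)


def preset(name: str) -> SimConfig:
    """Load one of the shipped study-condition presets ('guppy', 'stickleback')."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; available: {PRESETS}")
    ref = resources.files("shoalhmm") / "presets" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)


@dataclass
class SimResult:
    """Generator output: focal series, aligned true states, driver series."""

    series: list[SpeedSeries]
    states: list[np.ndarray]          # aligned 1-based true states per focal
    drivers: list[SpeedSeries]
    config: SimConfig


def _gamma_draw(rng, mean, sd):
    return rng.gamma(shape=mean * mean / (sd * sd), scale=sd * sd / mean)


def _markov_path(rng, trans: np.ndarray, n: int) -> np.ndarray:
    pi = stationary_distribution(trans)
    cum = np.cumsum(trans, axis=1)
    out = np.empty(n, dtype=np.int64)
    out[0] = np.searchsorted(np.cumsum(pi), rng.random(), side="right")
    u = rng.random(n)
    for t in range(1, n):
        out[t] = np.searchsorted(cum[out[t - 1]], u[t], side="right")
    return out


def simulate_driver_focal(config: SimConfig,
                          rng: np.random.Generator | int | None = None) -> SimResult:
    """Simulate focal speed series with a driver nearest-neighbour covariate.

    For every trial and focal individual an independent driver path is
    drawn from the 2-state chain; the focal's 3-state chain then emits
    gamma speeds whose state-3 mean is the driver's concurrent speed
    (clamped to ``mean_floor``).  The driver's speeds are recorded as the
    focal's ``nn_speeds`` and the true state sequences are returned.
    Optional Bernoulli gaps are applied consistently to series and states.
    """
    if rng is None:
        rng = config.seed
    rng = np.random.default_rng(rng)
    t3 = np.asarray(config.transition)
    t2 = np.asarray(config.driver_transition)
    dmeans = config.driver_means or config.means
    dsds = config.driver_sds or config.sds
    times = np.arange(config.n_points) * config.step
    series, states_out, drivers = [], [], []
    for trial in range(config.n_trials):
        trial_id = f"sim{trial:03d}"
        for ind in range(config.n_individuals):
            dstates = _markov_path(rng, t2, config.n_points)
            dspeed = np.empty(config.n_points)
            for s in (0, 1):
                mask = dstates == s
                dspeed[mask] = _gamma_draw(
                    rng, np.full(mask.sum(), dmeans[s]), dsds[s])
            fstates = _markov_path(rng, t3, config.n_points)
            fspeed = np.empty(config.n_points)
            for s in (0, 1):
                mask = fstates == s
                fspeed[mask] = _gamma_draw(
                    rng, np.full(mask.sum(), config.means[s]), config.sds[s])
            mask = fstates == 2
            soc_mean = np.maximum(dspeed[mask], config.mean_floor)
            fspeed[mask] = _gamma_draw(rng, soc_mean, config.social_sd)
            fid, did = f"f{ind:02d}", f"d{ind:02d}"
            focal = SpeedSeries(
                individual_id=fid, trial_id=trial_id, times=times.copy(),
                speeds=fspeed, step=config.step,
                segments=[(0, config.n_points)],
                nn_speeds=dspeed,
                nn_ids=np.array([did] * config.n_points, dtype=object))
            truth = fstates + 1
            if config.gap_rate > 0:
                keep = rng.random(config.n_points) >= config.gap_rate
                focal = subset_series(focal, keep)
                if focal is None:
                    continue
                truth = truth[keep]
            series.append(focal)
            states_out.append(truth)
            drivers.append(SpeedSeries(
                individual_id=did, trial_id=trial_id, times=times.copy(),
                speeds=dspeed, step=config.step,
                segments=[(0, config.n_points)]))
    return SimResult(series=series, states=states_out, drivers=drivers, config=config)


def simulate_group_positions(config: SimConfig,
                             rng: np.random.Generator | int | None = None,
                             ) -> TrajectoryDataset:
    """2D correlated random walks in a square arena with reflecting walls.

    In ``independent`` mode each individual's heading performs its own
    wrapped random walk; in ``shared`` mode all individuals track one
    common heading process (plus small individual noise), which produces
    highly polarised motion.
    """
    if config.n_individuals < 2:
        raise ConfigurationError("need at least 2 individuals")
    if rng is None:
        rng = config.seed
    rng = np.random.default_rng(rng)
    n, n_frames = config.n_individuals, config.n_points
    size = config.arena_size
    dt = config.step
    pos = rng.uniform(0.2 * size, 0.8 * size, size=(n, 2))
    theta = rng.uniform(-np.pi, np.pi, size=n)
    shared = rng.uniform(-np.pi, np.pi)
    rows = []
    ids = [f"i{k:02d}" for k in range(n)]
    for f in range(n_frames):
        for k in range(n):
            rows.append((f, ids[k], pos[k, 0], pos[k, 1], True))
        if config.heading_mode == "shared":
            shared += rng.normal(0, config.turn_sd)
            theta = shared + rng.normal(0, 0.05, size=n)
        else:
            theta = theta + rng.normal(0, config.turn_sd, size=n)
        step_len = config.walk_speed * dt
        nxt = pos + step_len * np.column_stack([np.cos(theta), np.sin(theta)])
        # reflecting walls: fold positions back and flip the heading component
        for d in range(2):
            low = nxt[:, d] < 0
            high = nxt[:, d] > size
            nxt[low, d] = -nxt[low, d]
            nxt[high, d] = 2 * size - nxt[high, d]
            flip = low | high
            if flip.any():
                if d == 0:
                    theta[flip] = np.pi - theta[flip]
                else:
                    theta[flip] = -theta[flip]
        pos = nxt
    df = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "tracked"])
    return TrajectoryDataset(trial_id="simpos", frame_rate=1.0 / dt,
                             group_size=n, records=df)


def inject_gaps(series_set: list[SpeedSeries], gap_rate: float,
                rng: np.random.Generator | int | None = None) -> list[SpeedSeries]:
    """Delete each point independently with probability ``gap_rate``.

    Segments are rebuilt around the deletions; series losing every point
    are dropped from the returned list.
    """
    if not (0 <= gap_rate < 1):
        raise ParameterError("gap_rate must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    out = []
    for s in series_set:
        if gap_rate == 0:
            out.append(s)
            continue
        keep = rng.random(len(s)) >= gap_rate
        sub = subset_series(s, keep)
        if sub is not None:
            out.append(sub)
    return out
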