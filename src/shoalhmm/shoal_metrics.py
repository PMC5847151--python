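"""Shoal-level order parameters and aggregate speed-distribution analyses.

Two classical order parameters summarise group organisation at each frame:
polarisation ``O_p = |Σ u_i| / N`` (alignment of the unit headings ``u_i``)
and rotation ``O_r = |Σ u_i × r_i| / N`` (mean normalised angular momentum
about the group centroid, with ``r_i`` the unit vector from the centre of
mass to individual ``i``; the cross product is the scalar z-component of
in-plane vectors).  Both lie in [0, 1].

The module also builds the bivariate histogram of individual speed versus
concurrent nearest-neighbour speed on a fixed 60x60 grid, together with a
permutation control distribution in which the temporal concurrence of the
two speeds is destroyed by random re-pairing — excess density on the main
diagonal relative to the control is the aggregate signature of speed
matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedResultError
from .trajectory_io import TrajectoryDataset

__all__ = [
    "ShoalFrame",
    "BivariateSpeedHist",
    "polarisation",
    "rotation",
    "shoal_frames",
    "order_parameter_series",
    "bivariate_speed_hist",
    "control_hist",
    "log_display",
]


@dataclass
class ShoalFrame:
    """Unit headings and unit centre-of-mass radials of one frame."""

    headings: np.ndarray  # (N, 2), rows unit norm
    radials: np.ndarray   # (N, 2), rows unit norm (NaN where undefined)

    def __post_init__(self) -> None:
        self.headings = np.asarray(self.headings, dtype=float)
        self.radials = np.asarray(self.radials, dtype=float)
        if self.headings.shape != self.radials.shape or self.headings.shape[1] != 2:
            raise ParameterError("headings and radials must both be (N, 2)")
        if self.headings.shape[0] < 2:
            raise ParameterError("need N >= 2")
        norms = np.linalg.norm(self.headings, axis=1)
        if not np.all(np.isfinite(norms)) or np.any(np.abs(norms - 1) > 1e-9):
            raise UndefinedResultError("headings must be finite unit vectors")
        rn = np.linalg.norm(self.radials, axis=1)
        ok = np.isnan(rn) | (np.abs(rn - 1) <= 1e-9)
        if not ok.all():
            raise ParameterError("radials must be unit vectors or NaN")

    @property
    def n(self) -> int:
        return self.headings.shape[0]


def polarisation(frame: ShoalFrame) -> float:
    """O_p = |mean heading|; 1 when all aligned, 0 under cancellation."""
    return float(np.linalg.norm(frame.headings.sum(axis=0)) / frame.n)


def rotation(frame: ShoalFrame) -> float:
    """O_r = |Σ u_i × r_i| / N with the scalar z cross product."""
    if np.isnan(frame.radials).any():
        raise UndefinedResultError("individual at centre of mass: radial undefined")
    cross = (frame.headings[:, 0] * frame.radials[:, 1]
             - frame.headings[:, 1] * frame.radials[:, 0])
    # u x r has z-component u_x r_y - u_y r_x; the sign convention only
    # flips the summand sign, the absolute total is convention-free
    return float(abs(cross.sum()) / frame.n)


def shoal_frames(ds: TrajectoryDataset) -> tuple[list[float], list[ShoalFrame], int]:
    """Per-frame ShoalFrames from a complete-frame position dataset.

    Headings come from the displacement to the next frame (same convention
    as the speed pipeline).  Frames in which any individual has zero
    displacement (undefined heading) are skipped; the skip count is
    returned alongside the frame times.
    """
    df = ds.records[ds.records["tracked"]]
    ids = ds.individual_ids()
    wide_x = df.pivot(index="frame", columns="id", values="x").reindex(columns=ids)
    wide_y = df.pivot(index="frame", columns="id", values="y").reindex(columns=ids)
    frames = wide_x.index.to_numpy()
    X, Y = wide_x.to_numpy(), wide_y.to_numpy()
    times, out, skipped = [], [], 0
    for i in range(len(frames) - 1):
        if frames[i + 1] != frames[i] + 1:
            continue
        row = np.column_stack([X[i], Y[i]])
        nxt = np.column_stack([X[i + 1], Y[i + 1]])
        if np.isnan(row).any() or np.isnan(nxt).any():
            continue
        disp = nxt - row
        norms = np.linalg.norm(disp, axis=1)
        if (norms == 0).any():
            skipped += 1
            continue
        u = disp / norms[:, None]
        com = row.mean(axis=0)
        rad = row - com
        rnorm = np.linalg.norm(rad, axis=1)
        r = np.where(rnorm[:, None] > 0, rad / np.where(rnorm == 0, 1, rnorm)[:, None],
                     np.nan)
        times.append(frames[i] / ds.frame_rate)
        out.append(ShoalFrame(headings=u, radials=r))
    return times, out, skipped


def order_parameter_series(ds: TrajectoryDataset) -> tuple[pd.DataFrame, int]:
    """Time series of (O_p, O_r) for one trial; returns (table, skipped frames)."""
    times, frames, skipped = shoal_frames(ds)
    rows = []
    for t, fr in zip(times, frames):
        try:
            orot = rotation(fr)
        except UndefinedResultError:
            skipped += 1
            continue
        rows.append((ds.trial_id, t, polarisation(fr), orot))
    return pd.DataFrame(rows, columns=["trial", "time_s", "O_p", "O_r"]), skipped


@dataclass
class BivariateSpeedHist:
    """Counts of (speed, nn_speed) pairs on an equal-width square grid."""

    grid: np.ndarray          # (bins, bins); [i, j] = speed bin i, nn bin j
    v_max: float
    n_total: int

    @property
    def bins(self) -> int:
        return self.grid.shape[0]

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.v_max, self.bins + 1)


def bivariate_speed_hist(speeds, nn_speeds, bins: int = 60,
                         v_max: float | None = None) -> BivariateSpeedHist:
    """Bivariate histogram of speed vs concurrent nearest-neighbour speed.

    ``v_max`` defaults to the maximum observed value over both inputs so
    the grid covers the full spread; values above ``v_max`` are clipped
    into the top bin.
    """
    speeds = np.asarray(speeds, dtype=float)
    nn_speeds = np.asarray(nn_speeds, dtype=float)
    if speeds.shape != nn_speeds.shape:
        raise ParameterError("speeds and nn_speeds must have equal length")
    if len(speeds) == 0:
        vm = v_max if v_max is not None else 1.0
        return BivariateSpeedHist(np.zeros((bins, bins)), float(vm), 0)
    if v_max is None:
        v_max = float(max(speeds.max(), nn_speeds.max()))
        if v_max <= 0:
            v_max = 1.0
    if v_max <= 0:
        raise ParameterError("v_max must be positive")
    a = np.minimum(speeds, v_max)
    b = np.minimum(nn_speeds, v_max)
    grid, _, _ = np.histogram2d(a, b, bins=bins, range=[[0, v_max], [0, v_max]])
    return BivariateSpeedHist(grid, float(v_max), int(len(speeds)))


def control_hist(speeds, nn_speeds, n_perm: int = 100,
                 rng_seed: int | np.random.Generator | None = None,
                 bins: int = 60, v_max: float | None = None,
                 ) -> tuple[BivariateSpeedHist, np.ndarray]:
    """Permutation control distribution and observed-minus-control grid.

    Randomly re-pairs ``nn_speeds`` against ``speeds`` ``n_perm`` times,
    averages the resulting grids, and returns the averaged control together
    with the difference grid (observed − control).  Positive differences on
    the main diagonal indicate speed matching beyond chance.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(rng_seed)
    obs = bivariate_speed_hist(speeds, nn_speeds, bins=bins, v_max=v_max)
    nn = np.asarray(nn_speeds, dtype=float)
    acc = np.zeros_like(obs.grid)
    for _ in range(n_perm):
        perm = rng.permutation(len(nn))
        acc += bivariate_speed_hist(speeds, nn[perm], bins=bins, v_max=obs.v_max).grid
    avg = acc / n_perm
    control = BivariateSpeedHist(avg, obs.v_max, obs.n_total)
    return control, obs.grid - avg


def log_display(grid: np.ndarray) -> np.ndarray:
    """Natural-log display transform with zero counts shown as zero."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    pos = grid > 0
    out[pos] = np.log(grid[pos])
    return out
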