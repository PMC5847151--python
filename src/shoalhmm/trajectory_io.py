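"""Trajectory tables and their reduction to gap-segmented speed series.

The raw observable is a per-trial table of 2D positions (cm) of ``N``
individuals filmed at a fixed frame rate, with a per-record ``tracked``
flag.  This module turns such tables into the quantity the movement models
consume: a coarse-grained speed series per individual, carrying the
concurrent speed of the nearest neighbour and an explicit segmentation into
maximal runs of regularly spaced samples (tracking gaps end a segment).

Conventions fixed here and relied on everywhere else:

* frames are 0-based integers; the time of frame ``f`` is ``f / frame_rate``;
* the speed over ``[t, t + dt]`` is assigned to time ``t``;
* smoothing uses a centred moving window and drops the half-window edge
  frames of each run, so every smoothed point is a full-window mean;
* coarse-graining keeps one sample every ``step`` seconds, anchored at the
  first frame of each run;
* nearest-neighbour ties are broken by lexicographically smallest id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    MalformedInputError,
    ParameterError,
    UndefinedResultError,
)

__all__ = [
    "TrajectoryDataset",
    "SpeedSeries",
    "load_trajectories",
    "write_trajectories",
    "filter_full_frames",
    "smooth_positions",
    "compute_speeds",
    "coarse_grain",
    "attach_nearest_neighbour",
    "lag_autocorrelation",
    "preprocess",
    "write_speed_series",
    "read_speed_series",
    "subset_series",
]

_COLUMNS = ["frame", "id", "x", "y", "tracked"]


@dataclass
class TrajectoryDataset:
    """Positions of all individuals of one trial over frames.

    ``records`` is a DataFrame with columns ``frame`` (int), ``id`` (str),
    ``x``/``y`` (cm, finite whenever ``tracked``) and ``tracked`` (bool).
    At most one record may exist per ``(frame, id)``.
    """

    trial_id: str
    frame_rate: float
    group_size: int
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        if self.group_size < 2:
            raise ConfigurationError("group_size must be at least 2")
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise MalformedInputError(f"missing columns: {missing}")
        df = df[_COLUMNS].copy()
        df["frame"] = df["frame"].astype(np.int64)
        if (df["frame"] < 0).any():
            raise MalformedInputError("negative frame index")
        df["id"] = df["id"].astype(str)
        df["tracked"] = df["tracked"].astype(bool)
        for c in ("x", "y"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
        if df.duplicated(subset=["frame", "id"]).any():
            raise MalformedInputError("duplicate (frame, id) record")
        bad = df["tracked"] & ~(np.isfinite(df["x"]) & np.isfinite(df["y"]))
        if bad.any():
            raise MalformedInputError("non-finite coordinate on tracked record")
        df = df.sort_values(["frame", "id"], kind="mergesort").reset_index(drop=True)
        self.records = df

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    def frames(self) -> np.ndarray:
        return np.unique(self.records["frame"].to_numpy())

    def individual_ids(self) -> list[str]:
        return sorted(self.records["id"].unique())


@dataclass
class SpeedSeries:
    """One individual's coarse-grained speed series.

    ``segments`` is a list of half-open ``(start, end)`` index ranges that
    are disjoint, ordered, and jointly cover all indices; within a segment,
    consecutive times differ by exactly ``step``.  ``nn_speeds``/``nn_ids``
    hold the concurrent nearest-neighbour speed and identity and may be
    ``None`` before neighbour attachment.
    """

    individual_id: str
    trial_id: str
    times: np.ndarray
    speeds: np.ndarray
    step: float
    segments: list[tuple[int, int]]
    nn_speeds: np.ndarray | None = None
    nn_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        n = len(self.times)
        if len(self.speeds) != n:
            raise MalformedInputError("times and speeds length mismatch")
        if self.nn_speeds is not None:
            self.nn_speeds = np.asarray(self.nn_speeds, dtype=float)
            if len(self.nn_speeds) != n:
                raise MalformedInputError("nn_speeds length mismatch")
        if self.nn_ids is not None:
            self.nn_ids = np.asarray(self.nn_ids, dtype=object)
            if len(self.nn_ids) != n:
                raise MalformedInputError("nn_ids length mismatch")
        if (self.speeds < -1e-12).any():
            raise MalformedInputError("negative speed")
        cursor = 0
        for start, end in self.segments:
            if start != cursor or end <= start:
                raise MalformedInputError("segments must be ordered, disjoint and covering")
            seg_t = self.times[start:end]
            if len(seg_t) > 1 and not np.allclose(np.diff(seg_t), self.step, atol=1e-9):
                raise MalformedInputError("irregular time step within a segment")
            cursor = end
        if cursor != n:
            raise MalformedInputError("segments do not cover all indices")
        if n > 1 and (np.diff(self.times) <= 0).any():
            raise MalformedInputError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def load_trajectories(path, frame_rate: float, group_size: int,
                      trial_id: str | None = None) -> TrajectoryDataset:
    """Read one trial's trajectory CSV (columns frame,id,x,y,tracked)."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    if trial_id is None:
        trial_id = str(getattr(path, "stem", None) or str(path).rsplit("/", 1)[-1].removesuffix(".csv"))
    return TrajectoryDataset(trial_id=trial_id, frame_rate=frame_rate,
                             group_size=group_size, records=df)


def write_trajectories(ds: TrajectoryDataset, path) -> None:
    out = ds.records.copy()
    out["tracked"] = out["tracked"].astype(int)
    out.to_csv(path, index=False)


def filter_full_frames(ds: TrajectoryDataset) -> TrajectoryDataset:
    """Keep only frames at which all ``group_size`` individuals are tracked."""
    df = ds.records
    tracked_counts = df[df["tracked"]].groupby("frame")["id"].nunique()
    full = tracked_counts[tracked_counts == ds.group_size].index
    kept = df[df["frame"].isin(full) & df["tracked"]].reset_index(drop=True)
    return replace(ds, records=kept)


def _runs(frames: np.ndarray) -> list[np.ndarray]:
    """Split a sorted frame array into maximal runs of consecutive frames."""
    if len(frames) == 0:
        return []
    breaks = np.nonzero(np.diff(frames) != 1)[0] + 1
    return np.split(frames, breaks)


def smooth_positions(ds: TrajectoryDataset, window: int = 3) -> TrajectoryDataset:
    """Centred moving-window average of positions within tracked runs.

    The first and last ``(window - 1) // 2`` frames of each run are dropped
    so that every retained position is a full-window mean; runs shorter than
    ``window`` are discarded entirely.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be an odd integer >= 1")
    if window == 1:
        return replace(ds, records=ds.records[ds.records["tracked"]].reset_index(drop=True))
    half = (window - 1) // 2
    df = ds.records[ds.records["tracked"]]
    pieces = []
    for ind, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        xs, ys = sub["x"].to_numpy(), sub["y"].to_numpy()
        offset = 0
        for run in _runs(frames):
            n = len(run)
            if n >= window:
                kernel = np.ones(window) / window
                sx = np.convolve(xs[offset:offset + n], kernel, mode="valid")
                sy = np.convolve(ys[offset:offset + n], kernel, mode="valid")
                pieces.append(pd.DataFrame({
                    "frame": run[half:n - half], "id": ind,
                    "x": sx, "y": sy, "tracked": True,
                }))
            offset += n
    if pieces:
        out = pd.concat(pieces, ignore_index=True)
    else:
        out = pd.DataFrame(columns=_COLUMNS)
    return replace(ds, records=out)


def compute_speeds(ds: TrajectoryDataset) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """Instantaneous speeds from consecutive tracked positions.

    Returns, per individual, a list of runs; each run is ``(times, speeds)``
    where the speed over ``[t, t + 1/fps]`` is the Euclidean displacement
    divided by the frame interval and is assigned to time ``t``.  A run of a
    single frame yields no speed sample.
    """
    dt = ds.frame_interval
    out: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    df = ds.records[ds.records["tracked"]]
    for ind, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        xs, ys = sub["x"].to_numpy(), sub["y"].to_numpy()
        runs = []
        offset = 0
        for run in _runs(frames):
            n = len(run)
            if n >= 2:
                dx = np.diff(xs[offset:offset + n])
                dy = np.diff(ys[offset:offset + n])
                speeds = np.hypot(dx, dy) / dt
                runs.append((run[:-1] * dt, speeds))
            offset += n
        out[ind] = runs
    return out


def coarse_grain(raw: dict[str, list[tuple[np.ndarray, np.ndarray]]],
                 step: float = 1.0, *, frame_rate: float,
                 trial_id: str = "") -> list[SpeedSeries]:
    """Subsample raw speed runs to one sample every ``step`` seconds.

    Within each run, samples are kept at the run's first time point and
    every ``step`` thereafter; each run becomes one segment.  ``step`` must
    be a positive integer multiple of the frame interval.
    """
    k = step * frame_rate
    if step <= 0 or abs(k - round(k)) > 1e-6 or round(k) < 1:
        raise ParameterError("step must be a positive integer multiple of the frame interval")
    k = int(round(k))
    out = []
    for ind, runs in raw.items():
        times, speeds, segments = [], [], []
        cursor = 0
        for run_t, run_v in runs:
            sel = np.arange(0, len(run_t), k)
            if len(sel) == 0:
                continue
            times.append(run_t[sel])
            speeds.append(run_v[sel])
            segments.append((cursor, cursor + len(sel)))
            cursor += len(sel)
        if cursor == 0:
            continue
        out.append(SpeedSeries(
            individual_id=ind, trial_id=trial_id,
            times=np.concatenate(times), speeds=np.concatenate(speeds),
            step=step, segments=segments))
    return out


def attach_nearest_neighbour(ds: TrajectoryDataset,
                             series_set: list[SpeedSeries]) -> list[SpeedSeries]:
    """Attach the concurrent nearest-neighbour speed to each sample.

    ``ds`` must hold the (smoothed, complete-frame) positions from which the
    series were derived, so that every individual has a position and a
    coarse-grained speed at every retained sample time.  Ties in distance go
    to the lexicographically smallest id.
    """
    if ds.group_size < 2 or len(series_set) < 2:
        raise ConfigurationError("nearest neighbours require at least 2 individuals")
    fps = ds.frame_rate
    # positions indexed by (frame, id)
    df = ds.records[ds.records["tracked"]]
    pos = {(f, i): (x, y) for f, i, x, y in
           zip(df["frame"], df["id"], df["x"], df["y"])}
    speed_at = {}
    for s in series_set:
        for t, v in zip(s.times, s.speeds):
            speed_at[(int(round(t * fps)), s.individual_id)] = v
    ids = sorted(s.individual_id for s in series_set)
    out = []
    for s in series_set:
        nn_speeds = np.empty(len(s))
        nn_ids = np.empty(len(s), dtype=object)
        for j, t in enumerate(s.times):
            f = int(round(t * fps))
            me = pos.get((f, s.individual_id))
            if me is None:
                raise MalformedInputError(
                    f"no position for {s.individual_id} at frame {f}")
            best_id, best_d = None, np.inf
            for other in ids:
                if other == s.individual_id:
                    continue
                p = pos.get((f, other))
                if p is None:
                    raise MalformedInputError(f"no position for {other} at frame {f}")
                d = (p[0] - me[0]) ** 2 + (p[1] - me[1]) ** 2
                if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and
                                          (best_id is None or other < best_id)):
                    best_id, best_d = other, d
            if (f, best_id) not in speed_at:
                raise MalformedInputError(
                    f"no concurrent speed for neighbour {best_id} at frame {f}")
            nn_ids[j] = best_id
            nn_speeds[j] = speed_at[(f, best_id)]
        out.append(replace(s, nn_speeds=nn_speeds, nn_ids=nn_ids))
    return out


def lag_autocorrelation(series: SpeedSeries, lag: float) -> float:
    """Pearson correlation of (V(t), V(t+lag)) over within-segment pairs."""
    k = lag / series.step
    if abs(k - round(k)) > 1e-6 or round(k) < 1:
        raise ParameterError("lag must be a positive integer multiple of the sampling step")
    k = int(round(k))
    a, b = [], []
    for start, end in series.segments:
        if end - start > k:
            a.append(series.speeds[start:end - k])
            b.append(series.speeds[start + k:end])
    if not a:
        raise UndefinedResultError("no valid within-segment pairs")
    x = np.concatenate(a)
    y = np.concatenate(b)
    if len(x) < 3:
        raise UndefinedResultError("fewer than 3 valid pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedResultError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def preprocess(ds: TrajectoryDataset, step: float = 1.0,
               window: int = 3) -> list[SpeedSeries]:
    """Full pipeline: complete frames -> smoothing -> speeds -> coarse grain -> neighbours."""
    full = filter_full_frames(ds)
    smooth = smooth_positions(full, window=window)
    # smoothing drops run edges per individual; re-filter so every retained
    # frame still has all individuals (keeps neighbour speeds concurrent)
    smooth = filter_full_frames(smooth)
    raw = compute_speeds(smooth)
    series = coarse_grain(raw, step=step, frame_rate=ds.frame_rate,
                          trial_id=ds.trial_id)
    return attach_nearest_neighbour(smooth, series)


def write_speed_series(series_set: list[SpeedSeries], path) -> None:
    """Export to CSV with columns trial,id,time_s,speed,nn_id,nn_speed,segment."""
    rows = []
    for s in series_set:
        seg_index = np.empty(len(s), dtype=int)
        for g, (a, b) in enumerate(s.segments):
            seg_index[a:b] = g
        rows.append(pd.DataFrame({
            "trial": s.trial_id, "id": s.individual_id,
            "time_s": s.times, "speed": s.speeds,
            "nn_id": s.nn_ids if s.nn_ids is not None else "",
            "nn_speed": s.nn_speeds if s.nn_speeds is not None else np.nan,
            "segment": seg_index,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_speed_series(path) -> list[SpeedSeries]:
    df = pd.read_csv(path, dtype={"id": str, "trial": str})
    out = []
    for (trial, ind), sub in df.groupby(["trial", "id"], sort=True):
        sub = sub.sort_values("time_s")
        segs = []
        seg_ids = sub["segment"].to_numpy()
        bounds = np.nonzero(np.diff(seg_ids) != 0)[0] + 1
        edges = [0, *bounds.tolist(), len(sub)]
        segs = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
        times = sub["time_s"].to_numpy()
        step = np.nan
        for a, b in segs:
            if b - a > 1:
                step = float(times[a + 1] - times[a])
                break
        if np.isnan(step):
            step = 1.0
        nn_speed = sub["nn_speed"].to_numpy()
        has_nn = not np.isnan(nn_speed).all()
        out.append(SpeedSeries(
            individual_id=str(ind), trial_id=str(trial),
            times=times, speeds=sub["speed"].to_numpy(), step=step,
            segments=segs,
            nn_speeds=nn_speed if has_nn else None,
            nn_ids=sub["nn_id"].astype(str).to_numpy(dtype=object) if has_nn else None))
    return out


def subset_series(series: SpeedSeries, keep: np.ndarray) -> SpeedSeries | None:
    """Drop points flagged False in ``keep`` and rebuild segments.

    Every removed point splits its segment; retained single points become
    single-point segments.  Returns ``None`` if nothing is kept.
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != (len(series),):
        raise ParameterError("keep mask length mismatch")
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        return None
    old_seg = np.empty(len(series), dtype=int)
    for g, (a, b) in enumerate(series.segments):
        old_seg[a:b] = g
    segments = []
    start = 0
    for j in range(1, len(idx) + 1):
        if (j == len(idx) or idx[j] != idx[j - 1] + 1
                or old_seg[idx[j]] != old_seg[idx[j - 1]]):
            segments.append((start, j))
            start = j
    return replace(
        series,
        times=series.times[idx], speeds=series.speeds[idx],
        nn_speeds=None if series.nn_speeds is None else series.nn_speeds[idx],
        nn_ids=None if series.nn_ids is None else series.nn_ids[idx],
        segments=segments)
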