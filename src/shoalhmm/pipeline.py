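"""End-to-end orchestration: simulate/load -> preprocess -> metrics ->
fit -> compare -> permutation test -> decode -> characterise.

Every stage writes its documented CSV/JSON artefact into the output
directory and a machine-readable manifest records configuration hash,
seeds, package versions and per-stage wall times, so a run is fully
reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParameterError, ShoalHMMError
from .hmm_core import N_PARAMS, FitResult, fit_model, viterbi_decode
from .inference import compare_models, permutation_test
from .shoal_metrics import order_parameter_series
from .social_characterisation import (
    occupancy,
    social_count_per_timepoint,
    state_conditional_speeds,
)
from .synthetic_data import preset, simulate_driver_focal, simulate_group_positions
from .trajectory_io import load_trajectories, preprocess, write_speed_series

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(ShoalHMMError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str
    input_paths: list[str] = field(default_factory=list)
    sim_preset: str | None = None
    frame_rate: float = 10.0
    group_size: int = 12
    step: float = 1.0
    models: tuple[str, ...] = ("model1", "model2", "model3")
    n_starts: int = 10
    n_perm: int = 100
    run_permutation: bool = False
    remove_frac: float = 0.30
    n_rep: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ParameterError("step must be positive")
        if not self.input_paths and self.sim_preset is None:
            raise ParameterError("either input_paths or sim_preset required")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the artefact directory.

    Any stage failure raises :class:`StageError` labelled with the stage
    name; artefacts of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"shoalhmm": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                _write_json(out / "manifest.json", manifest)
                raise StageError(f"[{name}] {exc}") from exc
            manifest["stages"][name] = {
                "wall_time_s": round(time.perf_counter() - t0, 3),
                "outputs": result,
            }
            _write_json(out / "manifest.json", manifest)
            return result
        return wrap

    # stage 1: obtain speed series (simulation preset or trajectory files)
    series_holder = {}

    def _preprocess():
        outputs = []
        if config.sim_preset is not None:
            sim_cfg = preset(config.sim_preset)
            sim_cfg.seed = config.seed
            sim = simulate_driver_focal(sim_cfg, rng=np.random.default_rng(config.seed))
            series = sim.series
            traj = simulate_group_positions(
                sim_cfg, rng=np.random.default_rng(config.seed + 1))
            traj_path = out / "positions.csv"
            traj.records.assign(tracked=traj.records["tracked"].astype(int)) \
                .to_csv(traj_path, index=False)
            series_holder["trajectories"] = [traj]
            outputs.append(str(traj_path))
        else:
            series = []
            datasets = []
            for p in config.input_paths:
                ds = load_trajectories(p, frame_rate=config.frame_rate,
                                       group_size=config.group_size)
                datasets.append(ds)
                series.extend(preprocess(ds, step=config.step))
            series_holder["trajectories"] = datasets
        series_holder["series"] = series
        sp = out / "speed_series.csv"
        write_speed_series(series, sp)
        outputs.append(str(sp))
        return outputs

    stage("preprocess")(_preprocess)
    series = series_holder["series"]

    def _metrics():
        frames = []
        skipped = 0
        for ds in series_holder.get("trajectories", []):
            tab, sk = order_parameter_series(ds)
            frames.append(tab)
            skipped += sk
        path = out / "order_parameters.csv"
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        else:
            pd.DataFrame(columns=["trial", "time_s", "O_p", "O_r"]).to_csv(path, index=False)
        return [str(path), f"skipped_frames={skipped}"]

    stage("metrics")(_metrics)

    fits: dict[str, FitResult] = {}

    def _fit():
        outputs = []
        for kind in config.models:
            fit = fits[kind] = fit_model(
                series, kind, n_starts=config.n_starts,
                rng_seed=int(rng.integers(2 ** 31)))
            path = out / f"fit_{kind}.json"
            fit.to_json(path)
            outputs.append(str(path))
        return outputs

    stage("fit")(_fit)

    def _compare():
        comp = compare_models(list(fits.values()))
        path = out / "model_comparison.json"
        comp.to_json(path)
        return [str(path)]

    stage("compare")(_compare)

    def _permtest():
        if not config.run_permutation or "model3" not in fits or "model2" not in fits:
            return ["skipped"]
        res = permutation_test(series, n_perm=config.n_perm,
                               rng_seed=int(rng.integers(2 ** 31)),
                               fit_options={"n_starts": config.n_starts},
                               fits=fits)
        path = out / "permutation_test.json"
        res.to_json(path)
        return [str(path)]

    stage("permtest")(_permtest)

    decodings = []

    def _decode():
        kind = "model3" if "model3" in fits else sorted(fits, key=lambda k: fits[k].aic)[0]
        spec = fits[kind].spec
        for s in series:
            decodings.append(viterbi_decode(s, spec))
        rows = []
        for d, s in zip(decodings, series):
            rows.append(pd.DataFrame({"trial": s.trial_id, "id": s.individual_id,
                                      "time_s": s.times, "state": d.states}))
        path = out / "viterbi_states.csv"
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        return [str(path)]

    stage("decode")(_decode)

    def _characterise():
        occ = occupancy(decodings)
        cond = state_conditional_speeds(decodings, series)
        counts = social_count_per_timepoint(decodings, series)
        occ_path = out / "occupancy.csv"
        pd.DataFrame({"state": np.arange(1, len(occ.fraction_by_state) + 1),
                      "fraction": occ.fraction_by_state,
                      "n_points": occ.n_points}).to_csv(occ_path, index=False)
        hist_path = out / "social_counts.csv"
        pd.DataFrame({"k": np.arange(len(counts.histogram)),
                      "n_timepoints": counts.histogram}).to_csv(hist_path, index=False)
        cond_path = out / "state_conditional_speeds.csv"
        pd.concat([pd.DataFrame({"state": k, "speed": v})
                   for k, v in cond.items()], ignore_index=True).to_csv(cond_path, index=False)
        nn_path = out / "speeds_by_social_nn.csv"
        pd.concat([pd.DataFrame({"n_social_nn": k, "speed": v})
                   for k, v in counts.conditional_speeds.items()] or
                  [pd.DataFrame(columns=["n_social_nn", "speed"])],
                  ignore_index=True).to_csv(nn_path, index=False)
        return [str(occ_path), str(hist_path), str(cond_path), str(nn_path)]

    stage("characterise")(_characterise)
    return out
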