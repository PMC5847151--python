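"""Model comparison, the permutation test for social coupling, and
robustness-to-data-loss analysis.

The central statistic is ΔAIC = AIC(model 2) − AIC(model 3): positive
values favour the social model.  Because AIC-based selection between HMMs
with different state counts can be anti-conservative, the test of social
coupling is a permutation test: the nearest-neighbour speeds are shuffled
against the focal speeds (one global shuffle per replicate, destroying
temporal concurrence while preserving both marginal speed distributions
and the focal series' autocorrelation), model 3 is refitted, and the
p-value is the fraction of permutations whose ΔAIC reaches or exceeds the
observed one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hmm_core import FitResult, fit_model
from .trajectory_io import SpeedSeries, subset_series

__all__ = [
    "ModelComparison",
    "PermutationResult",
    "compare_models",
    "permutation_test",
    "robustness_subsample",
    "shuffle_nn_speeds",
]


@dataclass
class ModelComparison:
    """AIC table over fitted models and the headline ΔAIC."""

    aic_by_model: dict[str, float]
    delta_aic: float          # AIC(model2) - AIC(model3) when both present
    pairwise: dict[str, float]
    n_obs: int

    def to_json(self, path=None) -> str:
        s = json.dumps({"aic_by_model": self.aic_by_model,
                        "delta_aic": self.delta_aic,
                        "pairwise": self.pairwise, "n_obs": self.n_obs},
                       indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


@dataclass
class PermutationResult:
    """Observed ΔAIC against its permutation null distribution."""

    observed_delta: float
    permuted_deltas: list[float]
    n_perm: int
    p_value: float
    seed: int | None

    def to_json(self, path=None) -> str:
        s = json.dumps({"observed_delta": self.observed_delta,
                        "permuted_deltas": self.permuted_deltas,
                        "n_perm": self.n_perm, "p_value": self.p_value,
                        "seed": self.seed}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def compare_models(fits: list[FitResult]) -> ModelComparison:
    """AIC table and pairwise differences (lower AIC better).

    ``delta_aic`` is AIC(model2) − AIC(model3) when both are present,
    otherwise the difference between the first and last supplied fit.
    """
    if not fits:
        raise ParameterError("no fits supplied")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ParameterError("fits compare different data (n_obs mismatch)")
    table = {f.spec.model_kind: f.aic for f in fits}
    if len(table) != len(fits):
        raise ParameterError("duplicate model kinds in comparison")
    pairwise = {}
    kinds = list(table)
    for i, a in enumerate(kinds):
        for b in kinds[i + 1:]:
            pairwise[f"{a}-{b}"] = table[a] - table[b]
    if "model2" in table and "model3" in table:
        delta = table["model2"] - table["model3"]
    else:
        delta = table[kinds[0]] - table[kinds[-1]]
    return ModelComparison(aic_by_model=table, delta_aic=delta,
                           pairwise=pairwise, n_obs=n_obs.pop())


def shuffle_nn_speeds(series_set: list[SpeedSeries],
                      rng: np.random.Generator) -> list[SpeedSeries]:
    """One global shuffle of nn_speeds against speeds across all series."""
    lengths = [len(s) for s in series_set]
    pooled = np.concatenate([s.nn_speeds for s in series_set])
    perm = rng.permutation(len(pooled))
    pooled = pooled[perm]
    out = []
    offset = 0
    for s, ln in zip(series_set, lengths):
        out.append(dc_replace(s, nn_speeds=pooled[offset:offset + ln]))
        offset += ln
    return out


def permutation_test(series_set: list[SpeedSeries], n_perm: int = 100,
                     rng_seed: int | None = None,
                     fit_options: dict | None = None,
                     fits: dict[str, FitResult] | None = None) -> PermutationResult:
    """Permutation test of the model-2 → model-3 AIC improvement.

    Per replicate the (V(t), V_nn(t)) pairings are destroyed by one global
    shuffle of nn_speeds across the whole dataset, model 3 is refitted
    (warm-started at the original MLE plus random restarts) and its ΔAIC
    against the *original* model-2 fit is recorded.  The p-value counts
    permutations with ΔAIC ≥ observed (ties count as exceedances).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    opts = dict(fit_options or {})
    rng = np.random.default_rng(rng_seed)
    fits = dict(fits or {})
    if "model2" not in fits:
        fits["model2"] = fit_model(series_set, "model2",
                                   rng_seed=int(rng.integers(2 ** 31)), **opts)
    if "model3" not in fits:
        fits["model3"] = fit_model(series_set, "model3",
                                   rng_seed=int(rng.integers(2 ** 31)), **opts)
    aic2 = fits["model2"].aic
    observed = aic2 - fits["model3"].aic
    # permuted refits get the same optimisation effort as the observed fit
    # (original MLE as warm start, remaining starts random), so the null
    # distribution is not disadvantaged relative to the observed statistic
    warm = fits["model3"].spec
    perm_opts = dict(opts)
    deltas = []
    for _ in range(n_perm):
        shuffled = shuffle_nn_speeds(series_set, rng)
        refit = fit_model(shuffled, "model3", warm_start=warm,
                          rng_seed=int(rng.integers(2 ** 31)), **perm_opts)
        deltas.append(aic2 - refit.aic)
    p = sum(d >= observed for d in deltas) / n_perm
    return PermutationResult(observed_delta=float(observed),
                             permuted_deltas=[float(d) for d in deltas],
                             n_perm=n_perm, p_value=float(p),
                             seed=rng_seed if isinstance(rng_seed, int) else None)


def robustness_subsample(series_set: list[SpeedSeries],
                         remove_frac: float = 0.30, n_rep: int = 100,
                         rng_seed: int | None = None,
                         fit_options: dict | None = None,
                         min_points: int = 100) -> tuple[pd.DataFrame, int]:
    """Refit model 3 after randomly deleting a fraction of all data points.

    Per replicate, ``remove_frac`` of the pooled sample points are deleted
    uniformly at random (deletions split segments; single-point fragments
    are retained and contribute through the stationary distribution).
    Returns a (replicate × parameter) table and the number of replicates
    skipped for falling below ``min_points``.
    """
    if not (0 < remove_frac < 1) and remove_frac != 0:
        raise ParameterError("remove_frac must lie in [0, 1)")
    opts = dict(fit_options or {})
    rng = np.random.default_rng(rng_seed)
    total = sum(len(s) for s in series_set)
    n_remove = int(round(remove_frac * total))
    rows = []
    skipped = 0
    for rep in range(n_rep):
        drop = rng.choice(total, size=n_remove, replace=False)
        keep = np.ones(total, dtype=bool)
        keep[drop] = False
        reduced = []
        offset = 0
        for s in series_set:
            sub = subset_series(s, keep[offset:offset + len(s)])
            if sub is not None:
                reduced.append(sub)
            offset += len(s)
        if sum(len(s) for s in reduced) < min_points:
            skipped += 1
            continue
        fit = fit_model(reduced, "model3",
                        rng_seed=int(rng.integers(2 ** 31)), **opts)
        e1, e2, e3 = fit.spec.emissions
        t = fit.spec.transition
        rows.append({
            "replicate": rep, "mu1": e1.mean, "sigma1": e1.sd,
            "mu2": e2.mean, "sigma2": e2.sd, "sigma3": e3.sd,
            **{f"p{i+1}{j+1}": t[i, j] for i in range(3) for j in range(3)},
            "loglik": fit.loglik, "n_obs": fit.n_obs,
        })
    return pd.DataFrame(rows), skipped
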