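"""Gamma-emission hidden Markov models of individual speed.

Three nested models of a coarse-grained speed series V(t):

* model 1 — a single gamma distribution, V(t) ~ Gamma(mu, sigma)
  (mean/sd parameterisation), no dynamics; 2 parameters.
* model 2 — a 2-state HMM whose states carry constant-mean gamma
  emissions, capturing movement versus near-stationary phases;
  6 parameters (two means, two sds, two free transition probabilities).
* model 3 — model 2 plus a third, *social* state whose gamma emission
  mean equals the individual's nearest neighbour's concurrent speed
  V_nn(t), with a constant sd sigma3; 11 parameters (four gamma
  parameters, sigma3, six free transition probabilities).

Likelihoods are computed with the scaled forward algorithm.  Tracking gaps
partition each series into segments; the recursion restarts at the
stationary distribution of the transition matrix at every segment start
and segment contributions multiply (add in log space).

Fitting is by direct numerical maximum likelihood on unconstrained
transformed parameters (log means/sds, per-row multinomial-logit
transitions) with multi-start L-BFGS-B; states are relabelled after
fitting so that non-social states come in decreasing emission mean order
and the social state is always last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammainc

from . import _kernels
from .errors import (
    ConfigurationError,
    NumericalDegeneracyError,
    ParameterError,
)
from .trajectory_io import SpeedSeries

__all__ = [
    "GammaSpec",
    "SocialEmissionSpec",
    "HMMSpec",
    "FitResult",
    "StateDecoding",
    "gamma_logpdf",
    "stationary_distribution",
    "forward_loglik",
    "fit_model",
    "aic",
    "viterbi_decode",
    "N_PARAMS",
    "V_CLAMP",
    "MEAN_FLOOR",
]

#: Observation resolution threshold (cm/s).  Speeds at or below this are
#: treated as censored at zero: their emission probability is the gamma
#: mass P(V <= V_CLAMP) rather than a density.  Real data contain exact
#: zeros, where a gamma density is zero or divergent, and the social
#: emission can have shape << 1, putting substantial mass below any
#: resolvable speed; censoring keeps the likelihood finite *and* the
#: maximum-likelihood estimates consistent in that regime.
V_CLAMP = 1e-3

#: Floor (cm/s) applied to the social emission mean, which would otherwise
#: be an invalid gamma mean when the neighbour's speed is zero.
MEAN_FLOOR = 0.05

N_PARAMS = {"model1": 2, "model2": 6, "model3": 11}
_N_STATES = {"model1": 1, "model2": 2, "model3": 3}


@dataclass(frozen=True)
class GammaSpec:
    """Gamma emission with mean/sd parameterisation (cm/s)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.mean > 0 and self.sd > 0):
            raise ParameterError("gamma mean and sd must be positive")

    @property
    def shape(self) -> float:
        return self.mean ** 2 / self.sd ** 2

    @property
    def scale(self) -> float:
        return self.sd ** 2 / self.mean


@dataclass(frozen=True)
class SocialEmissionSpec:
    """Social-state emission: mean tracks the neighbour's concurrent speed.

    At time t the emission is Gamma(mean = max(V_nn(t), mean_floor),
    sd = ``sd``).
    """

    sd: float
    mean_floor: float = MEAN_FLOOR

    def __post_init__(self) -> None:
        if not (self.sd > 0 and self.mean_floor > 0):
            raise ParameterError("sd and mean_floor must be positive")


@dataclass
class HMMSpec:
    """Model structure: emissions, transition matrix, and model kind."""

    model_kind: str
    emissions: list
    transition: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in N_PARAMS:
            raise ConfigurationError(f"unknown model kind {self.model_kind!r}")
        if len(self.emissions) != _N_STATES[self.model_kind]:
            raise ConfigurationError("wrong number of emissions for model kind")
        if self.model_kind == "model3" and not isinstance(
                self.emissions[-1], SocialEmissionSpec):
            raise ConfigurationError("model3's last emission must be social")
        for e in self.emissions[:-1] if self.model_kind == "model3" else self.emissions:
            if not isinstance(e, GammaSpec):
                raise ConfigurationError("non-social emissions must be GammaSpec")
        if self.model_kind == "model1":
            self.transition = None
        else:
            t = np.asarray(self.transition, dtype=float)
            n = len(self.emissions)
            if t.shape != (n, n):
                raise ConfigurationError("transition matrix has wrong shape")
            if (t < -1e-12).any() or (t > 1 + 1e-12).any():
                raise ConfigurationError("transition entries must lie in [0, 1]")
            if np.abs(t.sum(axis=1) - 1).max() > 1e-10:
                raise ConfigurationError("transition rows must sum to 1")
            self.transition = t

    @property
    def n_states(self) -> int:
        return len(self.emissions)

    @property
    def social_index(self) -> int:
        return self.n_states - 1 if self.model_kind == "model3" else -1

    def to_dict(self) -> dict:
        ems = []
        for e in self.emissions:
            if isinstance(e, SocialEmissionSpec):
                ems.append({"kind": "social", "sd": e.sd, "mean_floor": e.mean_floor})
            else:
                ems.append({"kind": "gamma", "mean": e.mean, "sd": e.sd})
        return {
            "model_kind": self.model_kind,
            "emissions": ems,
            "transition": None if self.transition is None else self.transition.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMSpec":
        ems = []
        for e in d["emissions"]:
            if e["kind"] == "social":
                ems.append(SocialEmissionSpec(sd=e["sd"], mean_floor=e["mean_floor"]))
            else:
                ems.append(GammaSpec(mean=e["mean"], sd=e["sd"]))
        return cls(model_kind=d["model_kind"], emissions=ems,
                   transition=None if d["transition"] is None else np.array(d["transition"]))


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one dataset."""

    spec: HMMSpec
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    n_starts: int
    converged: bool
    seed: int | None = None

    def to_json(self, path=None) -> str:
        d = {"spec": self.spec.to_dict(), "loglik": self.loglik, "aic": self.aic,
             "n_params": self.n_params, "n_obs": self.n_obs,
             "n_starts": self.n_starts, "converged": self.converged,
             "seed": self.seed}
        s = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "FitResult":
        if hasattr(src, "read"):
            d = json.load(src)
        elif isinstance(src, str) and src.lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(spec=HMMSpec.from_dict(d["spec"]), loglik=d["loglik"],
                   aic=d["aic"], n_params=d["n_params"], n_obs=d["n_obs"],
                   n_starts=d["n_starts"], converged=d["converged"],
                   seed=d.get("seed"))


@dataclass
class StateDecoding:
    """Viterbi state sequence (1-based labels) aligned to a SpeedSeries."""

    states: np.ndarray
    n_states: int
    individual_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if len(self.states) and not (
                (self.states >= 1).all() and (self.states <= self.n_states).all()):
            raise ParameterError("states must lie in 1..n_states")


def gamma_logpdf(v, spec: GammaSpec, v_clamp: float = V_CLAMP):
    """Gamma emission log-probability under a mean/sd spec.

    Speeds above ``v_clamp`` evaluate to the log-density; speeds at or
    below it evaluate to the censored mass log P(V <= v_clamp), which is
    finite for every shape and keeps maximum likelihood consistent when a
    state's gamma shape is far below 1.
    """
    arr = np.asarray(v, dtype=float)
    if not np.isfinite(arr).all():
        raise ParameterError("speed values must be finite")
    out = stats.gamma.logpdf(np.maximum(arr, v_clamp), a=spec.shape, scale=spec.scale)
    cens = arr <= v_clamp
    if np.any(cens):
        mass = gammainc(spec.shape, v_clamp / spec.scale)
        out = np.where(cens, np.log(np.clip(mass, 1e-300, None)), out)
    return float(out) if np.isscalar(v) else out


def stationary_distribution(transition) -> np.ndarray:
    """Stationary law pi of a row-stochastic matrix (pi T = pi, sum 1).

    Raises :class:`NumericalDegeneracyError` when the chain has no unique
    stationary law (eigenvalue 1 with multiplicity > 1, i.e. reducible into
    closed classes) or the solution is not a probability vector.
    """
    t = np.asarray(transition, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ParameterError("transition must be square")
    if np.abs(t.sum(axis=1) - 1).max() > 1e-8 or (t < -1e-12).any():
        raise ParameterError("transition must be row-stochastic")
    vals, vecs = np.linalg.eig(t.T)
    close = np.abs(vals - 1) < 1e-9
    if close.sum() != 1:
        raise NumericalDegeneracyError("no unique stationary distribution")
    pi = np.real(vecs[:, close][:, 0])
    pi = pi / pi.sum()
    if (pi < -1e-10).any():
        raise NumericalDegeneracyError("stationary vector has negative mass")
    return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()


def _stationary_fast(t: np.ndarray) -> np.ndarray:
    """Linear-solve stationary law for strictly positive matrices (fit path)."""
    n = t.shape[0]
    a = t.T - np.eye(n)
    a[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(a, b)
    return pi


def _pack_data(series_set, need_nn: bool, v_clamp: float, mean_floor: float):
    """Flatten a SpeedSeries collection for the kernels."""
    if isinstance(series_set, SpeedSeries):
        series_set = [series_set]
    if not series_set:
        raise ParameterError("empty series set")
    vs, ms, starts, ends = [], [], [], []
    offset = 0
    for s in series_set:
        vs.append(s.speeds)
        if need_nn:
            if s.nn_speeds is None:
                raise ParameterError("model3 requires nn_speeds on every series")
            if not np.isfinite(s.nn_speeds).all():
                raise ParameterError("nn_speeds must be finite")
            ms.append(s.nn_speeds)
        for a, b in s.segments:
            starts.append(offset + a)
            ends.append(offset + b)
        offset += len(s)
    raw = np.concatenate(vs)
    censored = np.nonzero(raw <= v_clamp)[0]
    v = np.maximum(raw, v_clamp)
    logv = np.log(v)
    if need_nn:
        m = np.maximum(np.concatenate(ms), mean_floor)
    else:
        m = np.ones(len(v))
    logm = np.log(m)
    return (v, logv, m, logm,
            np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64),
            censored)


def _emission_matrix(v, logv, m, logm, censored, means, sds, social_idx, sd3,
                     v_clamp):
    """Per-point per-state emission log-probabilities with censoring.

    Density rows come from the JIT kernel; rows of points at or below
    ``v_clamp`` are replaced by the censored gamma mass of each state.
    """
    logb = _kernels.emission_logprobs(v, logv, m, logm, means, sds,
                                      social_idx, sd3)
    if censored.size:
        for s in range(len(means)):
            if s == social_idx:
                mc = m[censored]
                shape = mc * mc / (sd3 * sd3)
                x = v_clamp * mc / (sd3 * sd3)
            else:
                shape = means[s] ** 2 / sds[s] ** 2
                x = v_clamp * means[s] / sds[s] ** 2
            mass = gammainc(shape, x)
            logb[censored, s] = np.log(np.clip(mass, 1e-300, None))
    return logb


def _spec_arrays(spec: HMMSpec):
    means = np.empty(spec.n_states)
    sds = np.empty(spec.n_states)
    sd3 = 1.0
    floor = MEAN_FLOOR
    for i, e in enumerate(spec.emissions):
        if isinstance(e, SocialEmissionSpec):
            means[i] = np.nan
            sds[i] = e.sd
            sd3 = e.sd
            floor = e.mean_floor
        else:
            means[i] = e.mean
            sds[i] = e.sd
    return means, sds, sd3, floor


def forward_loglik(series_set, spec: HMMSpec, v_clamp: float = V_CLAMP) -> float:
    """Total log-likelihood over all segments of all series.

    Every segment is initialised at the stationary distribution of the
    transition matrix; segment contributions add.
    """
    means, sds, sd3, floor = _spec_arrays(spec)
    need_nn = spec.social_index >= 0
    v, logv, m, logm, starts, ends, cens = _pack_data(series_set, need_nn,
                                                      v_clamp, floor)
    if spec.model_kind == "model1":
        trans = np.ones((1, 1))
        pi = np.ones(1)
    else:
        trans = spec.transition
        pi = stationary_distribution(trans)
    logb = _emission_matrix(v, logv, m, logm, cens, means, sds,
                            spec.social_index, sd3, v_clamp)
    return float(_kernels.forward_from_logprobs(logb, starts, ends, trans, pi))


def aic(loglik: float, n_params: int) -> float:
    """Akaike Information Criterion, -2 loglik + 2 k (lower is better)."""
    return -2.0 * loglik + 2.0 * n_params


# ---------------------------------------------------------------------------
# parameter transforms


def _unpack_theta(theta: np.ndarray, model_kind: str, mean_floor: float):
    """Unconstrained vector -> (means, sds, sd3, trans, pi, social_idx)."""
    if model_kind == "model1":
        means = np.array([np.exp(theta[0])])
        sds = np.array([np.exp(theta[1])])
        return means, sds, 1.0, np.ones((1, 1)), np.ones(1), -1
    n = _N_STATES[model_kind]
    means = np.exp(theta[0:4:2].copy())
    sds = np.exp(theta[1:4:2].copy())
    if model_kind == "model2":
        logits = theta[4:6]
        sd3 = 1.0
        social = -1
        means_full, sds_full = means, sds
    else:
        sd3 = float(np.exp(theta[4]))
        logits = theta[5:11]
        social = 2
        means_full = np.array([means[0], means[1], np.nan])
        sds_full = np.array([sds[0], sds[1], sd3])
    trans = np.empty((n, n))
    k = 0
    for i in range(n):
        row = np.zeros(n)
        for j in range(n):
            if j != i:
                row[j] = logits[k]
                k += 1
        e = np.exp(row - row.max())
        trans[i] = e / e.sum()
    pi = _stationary_fast(trans)
    return means_full, sds_full, sd3, trans, pi, social


def _theta_from_spec(spec: HMMSpec) -> np.ndarray:
    means, sds, sd3, _ = _spec_arrays(spec)
    if spec.model_kind == "model1":
        return np.log([means[0], sds[0]])
    parts = [np.log(means[0]), np.log(sds[0]), np.log(means[1]), np.log(sds[1])]
    if spec.model_kind == "model3":
        parts.append(np.log(sd3))
    t = np.clip(spec.transition, 1e-10, None)
    for i in range(spec.n_states):
        for j in range(spec.n_states):
            if j != i:
                parts.append(np.log(t[i, j] / t[i, i]))
    return np.array(parts)


def _spec_from_arrays(model_kind, means, sds, sd3, trans, mean_floor) -> HMMSpec:
    if model_kind == "model1":
        return HMMSpec("model1", [GammaSpec(means[0], sds[0])])
    ems = [GammaSpec(means[0], sds[0]), GammaSpec(means[1], sds[1])]
    if model_kind == "model3":
        ems.append(SocialEmissionSpec(sd=sd3, mean_floor=mean_floor))
    return HMMSpec(model_kind, ems, transition=trans)


def _relabel(spec: HMMSpec) -> HMMSpec:
    """Order non-social states by decreasing mean; social state stays last."""
    if spec.model_kind == "model1":
        return spec
    n_free = 2
    order = np.argsort([-spec.emissions[i].mean for i in range(n_free)])
    perm = list(order) + ([2] if spec.model_kind == "model3" else [])
    ems = [spec.emissions[i] for i in perm]
    t = spec.transition[np.ix_(perm, perm)]
    return HMMSpec(spec.model_kind, ems, transition=t)


# ---------------------------------------------------------------------------
# fitting


def _initial_thetas(model_kind, v, sd3_guess, n_starts, rng, warm_start):
    q10, q60 = np.quantile(v, [0.10, 0.60])
    q10 = max(q10, 2 * V_CLAMP)
    q60 = max(q60, 4 * V_CLAMP)
    thetas = []
    if model_kind == "model1":
        base = np.log([v.mean(), max(v.std(), 1e-3)])
        thetas.append(base)
        for _ in range(n_starts - 1):
            thetas.append(base + rng.normal(0, 0.5, size=2))
    else:
        # deterministic first start: quantile means, mild sds, persistence 0.9
        n = _N_STATES[model_kind]
        base = [np.log(q60), np.log(0.7 * q60), np.log(q10), np.log(0.7 * q10)]
        if model_kind == "model3":
            base.append(np.log(sd3_guess))
        off = np.log(0.1 / (n - 1) / 0.9)  # p_ij / p_ii for persistence 0.9
        base += [off] * (n * (n - 1))
        base = np.array(base)
        thetas.append(base)
        for _ in range(n_starts - 1):
            jit = rng.normal(0, 0.5, size=base.shape)
            jit[-(len(base) - (5 if model_kind == "model3" else 4)):] = rng.normal(
                0, 1.0, size=(len(base) - (5 if model_kind == "model3" else 4)))
            thetas.append(base + jit)
    if warm_start is not None:
        thetas[0] = _theta_from_spec(warm_start)
    return thetas


def fit_model(series_set, model_kind: str, n_starts: int = 10,
              rng_seed: int | None = None, *,
              warm_start: HMMSpec | None = None,
              n_polish: int = 3, pilot_maxiter: int = 60, maxiter: int = 1000,
              v_clamp: float = V_CLAMP, mean_floor: float = MEAN_FLOOR,
              tol: float = 1e-8) -> FitResult:
    """Maximum-likelihood fit of one model to a SpeedSeries collection.

    One parameter set is fitted jointly across all series and segments (the
    likelihood is the product over segments).  ``n_starts`` initialisations
    are run as short pilot optimisations; the best ``n_polish`` are then
    polished to full tolerance, which makes multi-starting affordable on
    large datasets.  ``warm_start`` replaces the first (deterministic)
    initialisation.  Non-convergence on all starts is flagged via
    ``converged=False``, never raised.
    """
    if model_kind not in N_PARAMS:
        raise ConfigurationError(f"unknown model kind {model_kind!r}")
    if n_starts < 1:
        raise ParameterError("n_starts must be >= 1")
    rng = np.random.default_rng(rng_seed)
    need_nn = model_kind == "model3"
    v, logv, m, logm, starts, ends, cens = _pack_data(series_set, need_nn,
                                                      v_clamp, mean_floor)
    n_obs = len(v)
    if n_obs < 100:
        raise ParameterError("need at least 100 observations to fit")

    def nll(theta):
        try:
            means, sds, sd3, trans, pi, social = _unpack_theta(theta, model_kind, mean_floor)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12
        if not (np.isfinite(pi).all() and (pi > -1e-12).all()):
            return 1e12
        logb = _emission_matrix(v, logv, m, logm, cens, means, sds, social,
                                sd3, v_clamp)
        ll = _kernels.forward_from_logprobs(logb, starts, ends, trans, np.clip(pi, 0, None))
        if not np.isfinite(ll):
            return 1e12
        return -ll

    thetas = _initial_thetas(model_kind, v, max(np.std(v), 0.1), n_starts, rng, warm_start)
    bounds = [(-16.0, 16.0)] * len(thetas[0])
    pilots = []
    for th in thetas:
        res = optimize.minimize(nll, np.clip(th, -15, 15), method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": pilot_maxiter, "ftol": tol})
        pilots.append(res)
    pilots.sort(key=lambda r: r.fun)
    best = None
    converged = False
    for res in pilots[:max(1, n_polish)]:
        ref = optimize.minimize(nll, res.x, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": tol})
        if best is None or ref.fun < best.fun:
            best = ref
        converged = converged or bool(ref.success)
    means, sds, sd3, trans, pi, social = _unpack_theta(best.x, model_kind, mean_floor)
    spec = _relabel(_spec_from_arrays(model_kind, means, sds, sd3, trans, mean_floor))
    loglik = -best.fun
    return FitResult(spec=spec, loglik=loglik, aic=aic(loglik, N_PARAMS[model_kind]),
                     n_params=N_PARAMS[model_kind], n_obs=n_obs,
                     n_starts=n_starts, converged=converged,
                     seed=rng_seed if isinstance(rng_seed, int) else None)


def viterbi_decode(series: SpeedSeries, spec: HMMSpec,
                   v_clamp: float = V_CLAMP) -> StateDecoding:
    """Most probable state path (1-based), decoded per segment.

    Each segment is initialised at the stationary distribution, mirroring
    the likelihood computation.
    """
    means, sds, sd3, floor = _spec_arrays(spec)
    need_nn = spec.social_index >= 0
    v, logv, m, logm, starts, ends, cens = _pack_data([series], need_nn,
                                                      v_clamp, floor)
    if spec.model_kind == "model1":
        path = np.zeros(len(v), dtype=int)
    else:
        pi = stationary_distribution(spec.transition)
        logb = _emission_matrix(v, logv, m, logm, cens, means, sds,
                                spec.social_index, sd3, v_clamp)
        with np.errstate(divide="ignore"):
            log_trans = np.log(np.clip(spec.transition, 1e-300, None))
            log_pi = np.log(np.clip(pi, 1e-300, None))
        path = _kernels.viterbi_from_logprobs(logb, starts, ends, log_trans, log_pi)
    return StateDecoding(states=path + 1, n_states=spec.n_states,
                         individual_id=series.individual_id, trial_id=series.trial_id)
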