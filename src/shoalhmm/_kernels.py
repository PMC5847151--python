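"""JIT-compiled inner loops for the HMM likelihood and decoding.

These kernels are deliberately free of any model bookkeeping: they take
flat observation arrays, per-state gamma parameters (the social state's
time-varying mean is pre-resolved into per-point arrays) and segment
boundaries, and implement the scaled forward recursion and Viterbi
backtracking.  Each segment restarts from the supplied initial state
distribution, and segment log-likelihood contributions add.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def emission_logprobs(v, logv, m, logm, means, sds, social_idx, sd3):
    """Per-point, per-state gamma log-densities.

    ``v``/``logv``: clamped speeds and their logs.  ``m``/``logm``: the
    per-point social-state means (nearest-neighbour speed, floored) and
    their logs; ignored when ``social_idx < 0``.  Gamma parameterised by
    mean mu and sd sigma: shape = mu^2/sigma^2, scale = sigma^2/mu.
    """
    n = v.shape[0]
    n_states = means.shape[0]
    out = np.empty((n, n_states))
    for s in range(n_states):
        if s == social_idx:
            log_sd2 = 2.0 * math.log(sd3)
            inv_sd2 = 1.0 / (sd3 * sd3)
            for i in range(n):
                shape = m[i] * m[i] * inv_sd2
                inv_scale = m[i] * inv_sd2
                out[i, s] = ((shape - 1.0) * logv[i] - v[i] * inv_scale
                             + shape * (logm[i] - log_sd2) - math.lgamma(shape))
        else:
            shape = means[s] * means[s] / (sds[s] * sds[s])
            inv_scale = means[s] / (sds[s] * sds[s])
            const = shape * math.log(inv_scale) - math.lgamma(shape)
            for i in range(n):
                out[i, s] = (shape - 1.0) * logv[i] - v[i] * inv_scale + const
    return out


@njit(cache=True)
def forward_from_logprobs(logB, seg_starts, seg_ends, trans, pi):
    """Scaled forward algorithm; total log-likelihood over all segments.

    Each segment is initialised at ``pi`` and per-step normalisation keeps
    the recursion in the representable range regardless of length.
    """
    n_states = trans.shape[0]
    total = 0.0
    a = np.empty(n_states)
    a_new = np.empty(n_states)
    b = np.empty(n_states)
    for g in range(seg_starts.shape[0]):
        for t in range(seg_starts[g], seg_ends[g]):
            mb = logB[t, 0]
            for s in range(1, n_states):
                if logB[t, s] > mb:
                    mb = logB[t, s]
            if not np.isfinite(mb):
                return -np.inf
            for s in range(n_states):
                b[s] = math.exp(logB[t, s] - mb)
            if t == seg_starts[g]:
                for s in range(n_states):
                    a_new[s] = pi[s] * b[s]
            else:
                for s in range(n_states):
                    acc = 0.0
                    for j in range(n_states):
                        acc += a[j] * trans[j, s]
                    a_new[s] = acc * b[s]
            c = 0.0
            for s in range(n_states):
                c += a_new[s]
            if not (c > 0.0) or not np.isfinite(c):
                return -np.inf
            total += math.log(c) + mb
            for s in range(n_states):
                a[s] = a_new[s] / c
    return total


@njit(cache=True)
def viterbi_from_logprobs(logB, seg_starts, seg_ends, log_trans, log_pi):
    """Most probable state path per segment (0-based states)."""
    n, n_states = logB.shape
    states = np.empty(n, dtype=np.int64)
    for g in range(seg_starts.shape[0]):
        start, end = seg_starts[g], seg_ends[g]
        length = end - start
        delta = np.empty((length, n_states))
        psi = np.zeros((length, n_states), dtype=np.int64)
        for s in range(n_states):
            delta[0, s] = log_pi[s] + logB[start, s]
        for t in range(1, length):
            for s in range(n_states):
                best = delta[t - 1, 0] + log_trans[0, s]
                arg = 0
                for j in range(1, n_states):
                    cand = delta[t - 1, j] + log_trans[j, s]
                    if cand > best:
                        best = cand
                        arg = j
                delta[t, s] = best + logB[start + t, s]
                psi[t, s] = arg
        best = delta[length - 1, 0]
        arg = 0
        for s in range(1, n_states):
            if delta[length - 1, s] > best:
                best = delta[length - 1, s]
                arg = s
        states[start + length - 1] = arg
        for t in range(length - 1, 0, -1):
            arg = psi[t, arg]
            states[start + t - 1] = arg
    return states
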