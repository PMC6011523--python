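"""Numerically critical inner loops for the 2-state HMM machinery.

Compiled with numba when available; a no-op decorator keeps the package
importable without it (at a large speed cost on long series).

Conventions shared by every routine here (and by the simulator and the
enumeration oracles in the test suite):

* ``tmats[t]`` is the transition matrix governing the step from time
  ``t-1`` into time ``t`` (row ``tmats[0]`` is never used);
* state densities arrive per observation as a ``(T, 2)`` array.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=False)
def forward_core(dens: np.ndarray, tmats: np.ndarray, delta: np.ndarray) -> float:
    """Scaled forward recursion.

    ``dens`` must be the state densities rescaled so that each row's
    maximum is 1 (the caller adds back the sum of the per-row log
    maxima).  Returns the log-likelihood of the rescaled problem.
    """
    T = dens.shape[0]
    phi0 = delta[0] * dens[0, 0]
    phi1 = delta[1] * dens[0, 1]
    c = phi0 + phi1
    ll = np.log(c)
    phi0 /= c
    phi1 /= c
    for t in range(1, T):
        a0 = phi0 * tmats[t, 0, 0] + phi1 * tmats[t, 1, 0]
        a1 = phi0 * tmats[t, 0, 1] + phi1 * tmats[t, 1, 1]
        p0 = a0 * dens[t, 0]
        p1 = a1 * dens[t, 1]
        c = p0 + p1
        if c <= 0.0:  # numerical underflow at implausible parameters
            return -np.inf
        ll += np.log(c)
        phi0 = p0 / c
        phi1 = p1 / c
    return ll


@njit(cache=False)
def forward_backward(dens: np.ndarray, tmats: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Per-time posterior state probabilities (rows sum to 1)."""
    T = dens.shape[0]
    alpha = np.empty((T, 2))
    # scaled forward pass
    a0 = delta[0] * dens[0, 0]
    a1 = delta[1] * dens[0, 1]
    c = a0 + a1
    alpha[0, 0] = a0 / c
    alpha[0, 1] = a1 / c
    for t in range(1, T):
        a0 = alpha[t - 1, 0] * tmats[t, 0, 0] + alpha[t - 1, 1] * tmats[t, 1, 0]
        a1 = alpha[t - 1, 0] * tmats[t, 0, 1] + alpha[t - 1, 1] * tmats[t, 1, 1]
        p0 = a0 * dens[t, 0]
        p1 = a1 * dens[t, 1]
        c = p0 + p1
        alpha[t, 0] = p0 / c
        alpha[t, 1] = p1 / c
    # scaled backward pass, combined on the fly
    post = np.empty((T, 2))
    b0 = 1.0
    b1 = 1.0
    post[T - 1, 0] = alpha[T - 1, 0]
    post[T - 1, 1] = alpha[T - 1, 1]
    for t in range(T - 2, -1, -1):
        nb0 = tmats[t + 1, 0, 0] * dens[t + 1, 0] * b0 + tmats[t + 1, 0, 1] * dens[t + 1, 1] * b1
        nb1 = tmats[t + 1, 1, 0] * dens[t + 1, 0] * b0 + tmats[t + 1, 1, 1] * dens[t + 1, 1] * b1
        c = nb0 + nb1
        b0 = nb0 / c
        b1 = nb1 / c
        p0 = alpha[t, 0] * b0
        p1 = alpha[t, 1] * b1
        s = p0 + p1
        post[t, 0] = p0 / s
        post[t, 1] = p1 / s
    return post


@njit(cache=False)
def viterbi_path(logdens: np.ndarray, logtmats: np.ndarray, logdelta: np.ndarray) -> np.ndarray:
    """Global most-probable state path (0-based labels)."""
    T = logdens.shape[0]
    back = np.empty((T, 2), dtype=np.int8)
    v0 = logdelta[0] + logdens[0, 0]
    v1 = logdelta[1] + logdens[0, 1]
    for t in range(1, T):
        c00 = v0 + logtmats[t, 0, 0]
        c10 = v1 + logtmats[t, 1, 0]
        if c00 >= c10:
            n0 = c00 + logdens[t, 0]
            back[t, 0] = 0
        else:
            n0 = c10 + logdens[t, 0]
            back[t, 0] = 1
        c01 = v0 + logtmats[t, 0, 1]
        c11 = v1 + logtmats[t, 1, 1]
        if c01 >= c11:
            n1 = c01 + logdens[t, 1]
            back[t, 1] = 0
        else:
            n1 = c11 + logdens[t, 1]
            back[t, 1] = 1
        v0 = n0
        v1 = n1
    path = np.empty(T, dtype=np.int8)
    path[T - 1] = 0 if v0 >= v1 else 1
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


@njit(cache=False)
def simulate_chain(tmats: np.ndarray, delta: np.ndarray, uniforms: np.ndarray) -> np.ndarray:
    """Draw a state path from a time-varying 2-state Markov chain."""
    T = uniforms.shape[0]
    states = np.empty(T, dtype=np.int8)
    s = 0 if uniforms[0] < delta[0] else 1
    states[0] = s
    for t in range(1, T):
        stay = tmats[t, s, s]
        if uniforms[t] < stay:
            states[t] = s
        else:
            s = 1 - s
            states[t] = s
    return states
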