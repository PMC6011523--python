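"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's recursion code paths:
likelihoods are computed by explicit enumeration of all state paths and
decoding by explicit argmax over paths, so they can certify the forward
and Viterbi implementations on short series.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from seascapes import hmm


# ---------------------------------------------------------------------------
# brute-force oracles


def enumerate_loglik(spec: hmm.HMMSpec, odba, hours, tide=None) -> float:
    """Log-likelihood by summing over every state path (log-sum-exp)."""
    from scipy.special import logsumexp

    odba = np.asarray(odba, dtype=float)
    T = odba.size
    X = spec.design.matrix(np.asarray(hours, dtype=float), tide)
    logdens = spec.densities.logpdf(odba)
    mats = np.array([hmm.transition_matrix(spec.transitions, X[t]) for t in range(T)])
    logmats = np.log(mats)
    logdelta = np.log(spec.delta)
    terms = []
    for path in itertools.product((0, 1), repeat=T):
        lp = logdelta[path[0]] + logdens[0, path[0]]
        for t in range(1, T):
            lp += logmats[t, path[t - 1], path[t]] + logdens[t, path[t]]
        terms.append(lp)
    return float(logsumexp(terms))


def enumerate_viterbi(spec: hmm.HMMSpec, odba, hours, tide=None) -> np.ndarray:
    """Most probable path by explicit argmax over all paths (0-based)."""
    odba = np.asarray(odba, dtype=float)
    T = odba.size
    X = spec.design.matrix(np.asarray(hours, dtype=float), tide)
    logdens = spec.densities.logpdf(odba)
    mats = np.array([hmm.transition_matrix(spec.transitions, X[t]) for t in range(T)])
    logmats = np.log(mats)
    logdelta = np.log(spec.delta)
    best_lp, best_path = -np.inf, None
    for path in itertools.product((0, 1), repeat=T):
        lp = logdelta[path[0]] + logdens[0, path[0]]
        for t in range(1, T):
            lp += logmats[t, path[t - 1], path[t]] + logdens[t, path[t]]
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path)


def random_spec(rng: np.random.Generator, harmonic_order=None, with_tide=None) -> hmm.HMMSpec:
    """A random valid 2-state model specification."""
    if harmonic_order is None:
        harmonic_order = int(rng.integers(0, 3))
    if with_tide is None:
        with_tide = bool(rng.integers(0, 2))
    design = hmm.CovariateDesign(
        harmonic_order=harmonic_order,
        tidal_levels=hmm.TIDAL_LEVELS if with_tide else (),
    )
    p = design.n_columns
    shape = rng.uniform(0.5, 5.0, size=2)
    rate = rng.uniform(1.0, 50.0, size=2)
    delta = rng.dirichlet([1.0, 1.0])
    return hmm.HMMSpec(
        densities=hmm.StateDensities(shape, rate),
        transitions=hmm.TransitionModel(
            rng.normal(0.0, 1.0, size=p), rng.normal(0.0, 1.0, size=p)
        ),
        design=design,
        delta=delta,
    )


def random_inputs(rng: np.random.Generator, spec: hmm.HMMSpec, T: int):
    """Random observations/covariates compatible with a spec."""
    odba = rng.gamma(2.0, 0.05, size=T) + 1e-6
    hours = rng.uniform(0, 24, size=T)
    tide = (
        rng.choice(np.array(hmm.TIDAL_LEVELS, dtype=object), size=T)
        if len(spec.design.tidal_levels) > 1
        else None
    )
    return odba, hours, tide


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20180621)


@pytest.fixture
def plain_design():
    return hmm.CovariateDesign(harmonic_order=0, tidal_levels=())


@pytest.fixture
def homogeneous_spec(plain_design):
    """No covariates; moderately separated gamma states."""
    return hmm.HMMSpec(
        densities=hmm.StateDensities(np.array([2.0, 3.0]), np.array([40.0, 15.0])),
        transitions=hmm.TransitionModel(np.array([-2.0]), np.array([-1.0])),
        design=plain_design,
        delta=np.array([0.6, 0.4]),
    )


@pytest.fixture
def diel_spec():
    """Order-1 diel harmonics, no tide: night-elevated activity."""
    design = hmm.CovariateDesign(harmonic_order=1, tidal_levels=())
    return hmm.HMMSpec(
        densities=hmm.StateDensities(np.array([2.0, 3.0]), np.array([40.0, 15.0])),
        transitions=hmm.TransitionModel(
            np.array([-2.2, 0.3, -1.0]), np.array([-1.2, -0.3, 0.8])
        ),
        design=design,
        delta=np.array([0.5, 0.5]),
    )
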