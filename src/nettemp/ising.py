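"""Exact machinery for small-p Ising models.

The Ising model assigns probability P(x) = exp(-beta * H(x)) / Z to each of
the 2^p configurations x of p binary nodes, where the potential

    H(x) = -(tau' x + 1/2 x' Omega x)

carries node-specific external fields (thresholds) tau and symmetric pairwise
interactions (edge weights) Omega, and the inverse temperature beta scales
how strongly probability concentrates on low-energy (aligned) states.  With
the Boltzmann constant absorbed, temperature is T = 1/beta: hot networks are
near-uniform and high-entropy, cold ones aligned and stable.

Everything here is exact enumeration over the 2^p states (default limit
p <= 20); no approximate partition functions are implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import logsumexp

if TYPE_CHECKING:  # pragma: no cover
    from .panel import BinaryPanel

ENUMERATION_LIMIT = 20


class Encoding(str, Enum):
    """Node-state alphabet: spins {-1,+1} (PM1) or present/absent {0,1} (ZO)."""

    PM1 = "pm1"
    ZO = "zo"

    @property
    def alphabet(self) -> tuple[float, float]:
        return (-1.0, 1.0) if self is Encoding.PM1 else (0.0, 1.0)


@dataclass
class IsingParameters:
    """Edge weights Omega, thresholds tau and inverse temperature beta."""

    omega: np.ndarray
    tau: np.ndarray
    beta: float = 1.0
    encoding: Encoding = Encoding.PM1

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        p = self.tau.shape[0]
        if p < 1:
            raise ValueError("need at least one node")
        if self.omega.shape != (p, p):
            raise ValueError(f"omega must be {p}x{p}, got {self.omega.shape}")
        if not np.allclose(self.omega, self.omega.T, atol=1e-12, rtol=0):
            raise ValueError("omega must be symmetric")
        if np.any(np.abs(np.diag(self.omega)) > 1e-12):
            raise ValueError("omega must have zero diagonal")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError("beta must be a positive finite scalar")
        self.encoding = Encoding(self.encoding)

    @property
    def p(self) -> int:
        return self.tau.shape[0]


@dataclass
class StateDistribution:
    """All 2^p configurations with their probabilities and log Z."""

    states: np.ndarray  # (2^p, p), row order: binary counting, MSB = item 1
    probs: np.ndarray
    logZ: float


@lru_cache(maxsize=32)
def _state_matrix(p: int, encoding: Encoding) -> np.ndarray:
    """All 2^p configurations, binary counting order (first node = MSB)."""
    grid = ((np.arange(2**p)[:, None] >> np.arange(p - 1, -1, -1)) & 1)
    lo, hi = encoding.alphabet
    return np.where(grid == 1, hi, lo).astype(float)


@lru_cache(maxsize=32)
def _pair_products(p: int, encoding: Encoding) -> np.ndarray:
    """x_i * x_j for every state and every pair i<j: (2^p, p(p-1)/2)."""
    x = _state_matrix(p, encoding)
    iu, ju = np.triu_indices(p, k=1)
    return x[:, iu] * x[:, ju]


def _check_enumerable(p: int, limit: int = ENUMERATION_LIMIT) -> None:
    if p > limit:
        raise ValueError(
            f"p={p} exceeds the exact-enumeration limit of {limit} nodes "
            f"(2^{limit} states); no approximate partition function is provided"
        )


def hamiltonian(x: np.ndarray, params: IsingParameters) -> float:
    """Potential H(x) = -(tau' x + 1/2 x' Omega x); lower = more probable."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.p,):
        raise ValueError(f"state must have length {params.p}, got {x.shape}")
    if not set(np.unique(x)) <= set(params.encoding.alphabet):
        raise ValueError(
            f"state values outside the {params.encoding.value} alphabet"
        )
    return float(-(params.tau @ x + 0.5 * x @ params.omega @ x))


def _neg_energies(params: IsingParameters) -> np.ndarray:
    """-H(x) for all states, vectorized."""
    p = params.p
    x = _state_matrix(p, params.encoding)
    xp = _pair_products(p, params.encoding)
    iu, ju = np.triu_indices(p, k=1)
    return x @ params.tau + xp @ params.omega[iu, ju]


def state_distribution(
    params: IsingParameters, limit: int = ENUMERATION_LIMIT
) -> StateDistribution:
    """Exact Boltzmann distribution over all 2^p configurations.

    log Z is computed by log-sum-exp so it stays finite for |beta * H| up to
    the exp overflow range (~700).
    """
    _check_enumerable(params.p, limit)
    if not (np.all(np.isfinite(params.omega)) and np.all(np.isfinite(params.tau))):
        raise ValueError("non-finite parameters")
    logw = params.beta * _neg_energies(params)
    logZ = float(logsumexp(logw))
    probs = np.exp(logw - logZ)
    return StateDistribution(
        states=_state_matrix(params.p, params.encoding), probs=probs, logZ=logZ
    )


def log_likelihood(panel: "BinaryPanel | np.ndarray",
                   params: IsingParameters,
                   limit: int = ENUMERATION_LIMIT) -> float:
    """Exact log-likelihood of a complete panel under the model.

    Computed from the sufficient statistics (per-item sums and pairwise
    cross-products), so cost is one pass over the data plus one partition
    function; equal to the direct per-row sum of log-probabilities.
    """
    from .panel import BinaryPanel  # local import to avoid cycle

    if not isinstance(panel, BinaryPanel):
        arr = np.asarray(panel, dtype=float)
        panel = BinaryPanel(arr,
                            [f"item_{i+1}" for i in range(arr.shape[1])],
                            age=0.0, encoding=params.encoding)
    if panel.encoding != params.encoding:
        raise ValueError("panel and parameter encodings differ")
    if panel.p != params.p:
        raise ValueError("panel and parameter dimensions differ")
    n, s, c = panel.sufficient_stats()
    _check_enumerable(params.p, limit)
    iu, ju = np.triu_indices(params.p, k=1)
    logw = params.beta * _neg_energies(params)
    logZ = float(logsumexp(logw))
    return float(params.beta * (params.tau @ s + params.omega[iu, ju] @ c)
                 - n * logZ)


def gibbs_entropy(params: IsingParameters,
                  limit: int = ENUMERATION_LIMIT) -> float:
    """Gibbs entropy S = -sum_x P(x) ln P(x) in nats.

    Maximal at p*ln(2) as beta -> 0 (uniform) and non-increasing in beta at
    fixed (Omega, tau) since dS/dbeta = -beta * Var[H] <= 0.
    """
    dist = state_distribution(params, limit)
    logp = params.beta * _neg_energies(params) - dist.logZ
    return float(-(dist.probs @ logp))


def encode_transform(params: IsingParameters,
                     target: Encoding) -> IsingParameters:
    """Re-express the same distribution in the other node-state alphabet.

    PM1 -> ZO (substituting x = 2x' - 1): omega' = 4*omega and
    tau'_i = 2*tau_i - 2*sum_{j != i} omega_ij; the constant term is absorbed
    by the partition function, and beta is untouched.  The map is exact: the
    two parameterizations place identical probability on matched states.
    """
    target = Encoding(target)
    if target == params.encoding:
        raise ValueError("target encoding equals current encoding")
    row_sums = params.omega.sum(axis=1)  # diag is zero
    if params.encoding is Encoding.PM1:
        omega_new = 4.0 * params.omega
        tau_new = 2.0 * params.tau - 2.0 * row_sums
    else:
        omega_new = params.omega / 4.0
        tau_new = params.tau / 2.0 + row_sums / 4.0
    return IsingParameters(omega_new, tau_new, params.beta, target)


def global_strength(params: IsingParameters,
                    temperature_scaled: bool = False) -> float:
    """Global connectivity: sum of absolute edge weights over pairs i<j.

    With ``temperature_scaled`` the weights are first multiplied by beta, so
    under a shared Omega the scaled strength is exactly proportional to beta.
    """
    iu, ju = np.triu_indices(params.p, k=1)
    total = float(np.abs(params.omega[iu, ju]).sum())
    return params.beta * total if temperature_scaled else total
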