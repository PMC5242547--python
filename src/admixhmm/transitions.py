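"""Markov transition structure for the ancestry HMM.

Under an SMC'-based model of an admixed population of constant diploid size
``N`` founded ``t`` generations ago with a fraction ``m`` of ancestry from
population 1, the ancestry process along a single chromosome is a two-state
continuous "time" Markov chain in map distance, with per-Morgan switch rates

    lambda0 = 2 N m (1 - exp(-t / (2N)))        (ancestry 0 -> 1)
    lambda1 = 2 N (1 - m) (1 - exp(-t / (2N)))  (ancestry 1 -> 0)

The rates saturate for t >> 2N because a recombination event may back-coalesce
into the previous marginal genealogy, producing no ancestry junction.

A pooled sample of ``n`` chromosomes is modelled as the union of ``n``
independent single-chromosome processes; the HMM state is the count
``i`` of population-0 chromosomes in the pool.  The pooled count process is a
birth-death chain with generator

    i -> i+1 at rate (n - i) * lambda1,   i -> i-1 at rate i * lambda0,

whose transition matrix over an interval of d Morgans coincides with the
distribution of Binomial(i, P00(d)) + Binomial(n - i, P10(d)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom


@dataclass(frozen=True)
class DemographicParams:
    """Admixture model parameters.

    N : diploid population size (individuals), > 0
    m : proportion of ancestry from population 1 at founding, 0 < m < 1
    t : generations since the admixture pulse, >= 0
    """

    N: float
    m: float
    t: float

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError(f"N must be positive, got {self.N}")
        if not 0.0 < self.m < 1.0:
            raise ValueError(
                f"m must be strictly between 0 and 1, got {self.m} "
                "(degenerate admixture proportions leave no hidden-state "
                "uncertainty)"
            )
        if self.t < 0:
            raise ValueError(f"t must be non-negative, got {self.t}")


@dataclass(frozen=True)
class TractRates:
    """Per-Morgan ancestry switch rates (lambda0: 0->1, lambda1: 1->0)."""

    lam0: float
    lam1: float

    @property
    def total(self) -> float:
        return self.lam0 + self.lam1


def tract_rates(params: DemographicParams) -> TractRates:
    """SMC' per-Morgan ancestry tract switch rates for the given demography."""
    decay = 1.0 - np.exp(-params.t / (2.0 * params.N))
    scale = 2.0 * params.N * decay
    return TractRates(lam0=params.m * scale, lam1=(1.0 - params.m) * scale)


def single_chromosome_transition(rates: TractRates, d_morgans: float) -> np.ndarray:
    """2x2 transition matrix of the single-chromosome ancestry chain over
    ``d_morgans`` Morgans.

    Indexing follows the shared state convention (count of population-0
    chromosomes): index 1 is ancestry 0, index 0 is ancestry 1, so this is
    the n = 1 case of the pooled chain.  Closed form of
    expm(d * [[-lam1, lam1], [lam0, -lam0]]): the stationary projector plus an
    exponentially relaxing part with rate lam0 + lam1.
    """
    if d_morgans < 0:
        raise ValueError("distance must be non-negative")
    lam = rates.total
    if lam == 0.0:
        return np.eye(2)
    q0 = rates.lam1 / lam  # stationary Pr(ancestry 0) = Pr(state 1)
    q1 = rates.lam0 / lam
    decay = np.exp(-d_morgans * lam)
    return np.array(
        [
            [q1 + q0 * decay, q0 - q0 * decay],
            [q1 - q1 * decay, q0 + q1 * decay],
        ]
    )


def pool_transition(P2x2: np.ndarray, n: int) -> np.ndarray:
    """(n+1)x(n+1) transition matrix for the count of population-0 chromosomes
    in a pool of ``n`` independent chromosomes.

    ``P2x2`` uses the count-convention indexing of
    single_chromosome_transition, so P2x2[1, 0] is the per-chromosome
    probability of losing population-0 status over the interval and
    P2x2[0, 1] of gaining it.  From state i the new count is
    Binomial(i, 1 - P2x2[1,0]) + Binomial(n - i, P2x2[0,1]); with n = 1 the
    input is returned unchanged.
    """
    if n < 1:
        raise ValueError("pool size n must be >= 1")
    p_out = float(P2x2[1, 0])
    p_in = float(P2x2[0, 1])
    out = np.zeros((n + 1, n + 1))
    ks = np.arange(n + 1)
    for i in range(n + 1):
        keep = binom.pmf(ks[: i + 1], i, 1.0 - p_out)       # survivors of the i
        gain = binom.pmf(ks[: n - i + 1], n - i, p_in)      # recruits from the n-i
        out[i, :] = np.convolve(keep, gain)
    return out


def initial_distribution(m: float, n: int) -> np.ndarray:
    """Stationary distribution over the pooled state: Binomial(n, 1-m) on the
    count of population-0 chromosomes."""
    if not 0.0 < m < 1.0:
        raise ValueError("m must be strictly between 0 and 1")
    return binom.pmf(np.arange(n + 1), n, 1.0 - m)


class PoolTransitionKernel:
    """Exact transition operator of the pooled ancestry-count chain, usable for
    arbitrary inter-marker distances without forming a matrix per interval.

    The pooled chain is a birth-death process satisfying detailed balance with
    respect to its Binomial(n, lam1/(lam0+lam1)) stationary law, so its
    generator is diagonally similar to a symmetric tridiagonal matrix.  One
    symmetric eigendecomposition per (rates, n) then yields P(d) = exp(d Q) for
    every d, applied to state vectors with three small matrix-vector products.
    """

    def __init__(self, rates: TractRates, n: int):
        if n < 1:
            raise ValueError("pool size n must be >= 1")
        self.n = n
        self.rates = rates
        lam = rates.total
        self._identity = lam == 0.0
        self._cache: dict[float, np.ndarray] = {}
        if self._identity:
            return
        i = np.arange(n + 1)
        p0 = rates.lam1 / lam
        log_pi = (
            gammaln(n + 1)
            - gammaln(i + 1)
            - gammaln(n - i + 1)
            + i * np.log(p0)
            + (n - i) * np.log1p(-p0)
        )
        if log_pi.min() < -600.0:
            # extreme skew: sqrt(pi) underflows; degrade to dense expm route
            self._spectral = False
            birth = (n - i) * rates.lam1
            death = i * rates.lam0
            Q = np.diag(birth[:-1], 1) + np.diag(death[1:], -1)
            Q -= np.diag(Q.sum(axis=1))
            self._Q = Q
            return
        self._spectral = True
        sqrt_pi = np.exp(0.5 * log_pi)
        birth = (n - i[:-1]) * rates.lam1  # rate i -> i+1
        # symmetrized off-diagonal: sqrt(pi_i / pi_{i+1}) * birth_i
        off = birth * sqrt_pi[:-1] / sqrt_pi[1:]
        diag = -np.concatenate([birth, [0.0]]) - i * rates.lam0
        S = np.diag(diag) + np.diag(off, 1) + np.diag(off, -1)
        evals, evecs = np.linalg.eigh(S)
        self._evals = evals
        self._U = evecs
        self._sqrt_pi = sqrt_pi

    def matrix(self, d_morgans: float) -> np.ndarray:
        """Pooled (n+1)x(n+1) transition matrix over ``d_morgans`` Morgans."""
        if self._identity or d_morgans == 0.0:
            return np.eye(self.n + 1)
        key = float(f"{d_morgans:.12g}")
        P = self._cache.get(key)
        if P is None:
            if self._spectral:
                core = (self._U * np.exp(self._evals * d_morgans)) @ self._U.T
                P = (core * self._sqrt_pi[np.newaxis, :]) / self._sqrt_pi[:, np.newaxis]
            else:
                from scipy.linalg import expm

                P = expm(self._Q * d_morgans)
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            self._cache[key] = P
        return P

    def matrices(self, dists: np.ndarray) -> np.ndarray | None:
        """Batched (len(dists), n+1, n+1) transition matrices, or None when
        the state space is large enough that forming them is slower than the
        factorized propagate path (or when the spectral form is unavailable)."""
        K = self.n + 1
        if not self._identity and (not self._spectral or K > 12):
            return None
        dists = np.asarray(dists, dtype=float)
        if self._identity:
            return np.broadcast_to(np.eye(K), (dists.size, K, K)).copy()
        decay = np.exp(np.outer(dists, self._evals))
        left = self._U / self._sqrt_pi[:, np.newaxis]
        right = self._U * self._sqrt_pi[:, np.newaxis]
        P = np.einsum("ik,sk,jk->sij", left, decay, right, optimize=True)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def propagate(self, alpha: np.ndarray, d_morgans: float) -> np.ndarray:
        """Right-multiply row vector(s) ``alpha`` (shape (..., n+1)) by P(d)."""
        if self._identity or d_morgans == 0.0:
            return alpha
        if not self._spectral:
            return alpha @ self.matrix(d_morgans)
        w = (alpha / self._sqrt_pi) @ self._U
        w *= np.exp(self._evals * d_morgans)
        out = (w @ self._U.T) * self._sqrt_pi
        np.clip(out, 0.0, None, out=out)
        return out

    def propagate_back(self, beta: np.ndarray, d_morgans: float) -> np.ndarray:
        """Left-multiply column vector(s) ``beta`` (shape (..., n+1)) by P(d),
        i.e. compute P(d) @ beta for each row of the batch."""
        if self._identity or d_morgans == 0.0:
            return beta
        if not self._spectral:
            return beta @ self.matrix(d_morgans).T
        w = (beta * self._sqrt_pi) @ self._U
        w *= np.exp(self._evals * d_morgans)
        out = (w @ self._U.T) / self._sqrt_pi
        np.clip(out, 0.0, None, out=out)
        return out
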