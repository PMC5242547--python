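"""Emission probabilities of the ancestry HMM.

For a sample of ploidy ``n`` the hidden state ``i`` is the number of
chromosomes of population-0 ancestry at a site.  The observation is either a
read pileup (rA reads of allele A out of r) or a known sample genotype count
(CMA copies of allele A among the n chromosomes), together with the reference
panel allele counts (C0A out of C0 in panel 0; C1A out of C1 in panel 1).

The model integrates over the unknown population allele frequencies f0, f1
with independent uniform priors, sums over the latent sample allele counts
CM0A ~ Bin(i, f0) and CM1A ~ Bin(n-i, f1), splits reads over ancestries with
r0 ~ Bin(r, i/n), and draws allele-A reads with a symmetric per-read error
rate eps: a read from an ancestry-0 chromosome is A with probability
(1 - eps) CM0A/i + eps (1 - CM0A/i).

Two equivalent computations are provided:

* reference scalar forms (``component_emission``, ``pileup_emission``,
  ``genotype_emission``) that follow the constructive sums term by term; and
* a vectorized table builder (``emission_log_table``) that marginalizes the
  pileup over the latent total sample allele count CMA.  Because each read
  independently picks one of the n chromosomes uniformly, the probability a
  read is allele A given (CM0A, CM1A) collapses to
  eps + (1 - 2 eps) (CM0A + CM1A)/n, so

      Pr(rA | r, H=i) = sum_CMA Bin(rA; r, eps + (1-2eps) CMA/n)
                                * Pr(CMA, C0A, C1A | H=i),

  where the second factor is exactly the known-genotype emission.  The two
  routes are equal by binomial thinning; the test suite checks this on small
  instances against brute-force enumeration and numerical integration.

All accumulation is done in log space with integer log-gamma lookups, so
panel sizes and ploidies far beyond the factorial overflow range are safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom


@dataclass(frozen=True)
class ErrorModel:
    """Symmetric per-read error probability, constant across sites/samples."""

    eps: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.eps < 0.5:
            raise ValueError(f"error rate must be in [0, 0.5), got {self.eps}")


_GAMMALN_TABLE = gammaln(np.arange(2048, dtype=float))


def _gl(x: np.ndarray | int) -> np.ndarray | float:
    """gammaln at small non-negative integers via lookup table."""
    x = np.asarray(x)
    if x.max(initial=0) < _GAMMALN_TABLE.size:
        return _GAMMALN_TABLE[x]
    return gammaln(np.asarray(x, dtype=float))


def _log_binom_coef(n, k):
    return _gl(n + 1) - _gl(k + 1) - _gl(n - k + 1)


def log_panel_weight(C, CA, M, x):
    """log integral_0^1 Bin(CA; C, f) Bin(x; M, f) df  (flat Beta(1,1) prior).

    The closed form is C(C,CA) C(M,x) (CA+x)! (C-CA+M-x)! / (C+M+1)!.
    Accepts integer scalars or broadcastable integer arrays.
    """
    return (
        _log_binom_coef(C, CA)
        + _log_binom_coef(M, x)
        + _gl(CA + x + 1)
        + _gl(C - CA + M - x + 1)
        - _gl(C + M + 2)
    )


@lru_cache(maxsize=None)
def ancestry_read_split(r: int, n: int, i: int) -> np.ndarray:
    """Pr(r0 | r, H=i) for r0 = 0..r: Binomial(r, i/n) split of reads over the
    two ancestries.  Cached across calls; the returned array is read-only."""
    if not 0 <= i <= n:
        raise ValueError("state i must satisfy 0 <= i <= n")
    if r < 0:
        raise ValueError("read count must be non-negative")
    pmf = binom.pmf(np.arange(r + 1), r, i / n)
    pmf.setflags(write=False)
    return pmf


def component_emission(
    r0: int, r0A: int, C: int, CA: int, i_eff: int, eps: float
) -> float:
    """Pr(r0A, CA | r0, C, i_eff, eps): one ancestral population's factor.

    Sums over the latent sample allele count k ~ Bin(i_eff, f) jointly with the
    panel count CA ~ Bin(C, f) under a flat prior on f, then draws r0A A-reads
    from r0 reads with success probability eps + (1 - 2 eps) k / i_eff.

    With i_eff = 0 (no chromosomes of this ancestry in the sample) the state is
    incompatible with r0 > 0; for r0 = 0 only the panel factor remains, which
    is uniform 1/(C+1) under the flat frequency prior.
    """
    if not (0 <= r0A <= r0 and 0 <= CA <= C and i_eff >= 0):
        raise ValueError("invalid component emission arguments")
    if i_eff == 0:
        return 0.0 if r0 > 0 else 1.0 / (C + 1)
    k = np.arange(i_eff + 1)
    p_read = eps + (1.0 - 2.0 * eps) * k / i_eff
    read_term = binom.pmf(r0A, r0, p_read)
    weight = np.exp(log_panel_weight(C, CA, i_eff, k))
    return float(read_term @ weight)


def pileup_emission(
    rA: int,
    r: int,
    C0: int,
    C0A: int,
    C1: int,
    C1A: int,
    n: int,
    i: int,
    eps: float,
) -> float:
    """Pr(rA, C0A, C1A | r, C0, C1, H=i, eps): the pileup emission for state i,
    as the explicit sum over the read ancestry split r0 and the A-read split
    r0A.  Reference implementation used by tests and small problems; the
    vectorized table builder computes the identical quantity."""
    if not (0 <= rA <= r and 0 <= i <= n):
        raise ValueError("invalid pileup emission arguments")
    split = ancestry_read_split(r, n, i)
    total = 0.0
    for r0 in range(r + 1):
        if split[r0] == 0.0:
            continue
        r1 = r - r0
        inner = 0.0
        for r0A in range(max(0, rA - r1), min(r0, rA) + 1):
            inner += component_emission(r0, r0A, C0, C0A, i, eps) * component_emission(
                r1, rA - r0A, C1, C1A, n - i, eps
            )
        total += split[r0] * inner
    return total


def genotype_emission(CMA: int, C0: int, C0A: int, C1: int, C1A: int, n: int, i: int) -> float:
    """Pr(CMA, C0A, C1A | C0, C1, n, H=i) when sample genotypes are observed.

    Sums over the split of the CMA A-alleles between the i population-0
    chromosomes (CM0A = CMA - k) and the n-i population-1 chromosomes
    (CM1A = k), with each population's panel and sample counts tied through a
    flat-prior Beta integral over its allele frequency.
    """
    if not (0 <= CMA <= n and 0 <= i <= n):
        raise ValueError("invalid genotype emission arguments")
    lo = max(CMA - i, 0)
    hi = min(n - i, CMA)
    if lo > hi:
        return 0.0
    k = np.arange(lo, hi + 1)  # k = CM1A
    log_terms = log_panel_weight(C0, C0A, i, CMA - k) + log_panel_weight(
        C1, C1A, n - i, k
    )
    return float(np.exp(logsumexp(log_terms)))


# ---------------------------------------------------------------------------
# vectorized emission tables
# ---------------------------------------------------------------------------


def _log_panel_weights_by_count(C, CA, n: int) -> list[np.ndarray]:
    """For one panel (per-site counts C, CA: integer arrays of length S),
    return a list indexed by M = 0..n of (S, M+1) arrays of
    log_panel_weight(C, CA, M, x)."""
    C = np.asarray(C)[:, np.newaxis]
    CA = np.asarray(CA)[:, np.newaxis]
    out = []
    for M in range(n + 1):
        x = np.arange(M + 1)[np.newaxis, :]
        out.append(log_panel_weight(C, CA, M, x))
    return out


def genotype_log_table(C0, C0A, C1, C1A, n: int) -> np.ndarray:
    """log Pr(CMA, C0A, C1A | H=i) for all sites, states and genotype counts.

    Returns an array of shape (S, n+1 states, n+1 CMA values).
    """
    S = len(np.asarray(C0))
    A0 = _log_panel_weights_by_count(C0, C0A, n)
    A1 = _log_panel_weights_by_count(C1, C1A, n)
    out = np.full((S, n + 1, n + 1), -np.inf)
    for i in range(n + 1):
        la0 = A0[i]  # (S, i+1), index CM0A
        la1 = A1[n - i]  # (S, n-i+1), index CM1A
        c0 = la0.max(axis=1)
        c1 = la1.max(axis=1)
        e0 = np.exp(la0 - c0[:, np.newaxis])
        e1 = np.exp(la1 - c1[:, np.newaxis])
        G = np.zeros((S, n + 1))
        for x in range(i + 1):  # CM0A = x, CMA = x + CM1A
            G[:, x : x + n - i + 1] += e0[:, x, np.newaxis] * e1
        with np.errstate(divide="ignore"):
            out[:, i, :] = np.log(G) + (c0 + c1)[:, np.newaxis]
    return out


def emission_log_table(
    C0A,
    C0a,
    C1A,
    C1a,
    n: int,
    mode: str,
    obs,
    eps: float = 0.01,
) -> np.ndarray:
    """Per-site log emission vectors for one sample along one chromosome.

    Parameters
    ----------
    C0A, C0a, C1A, C1a : integer arrays (S,), reference panel allele counts.
    n : sample ploidy.
    mode : "pileup" or "genotype".
    obs : for pileup mode an (S, 2) array of (reads_A, reads_a); for genotype
        mode an (S,) array of sample A-allele counts CMA.
    eps : symmetric per-read error rate (ignored in genotype mode).

    Returns an (S, n+1) array of log Pr(observation | H = i).  Sites with no
    reads yield a state-independent (constant) row.
    """
    C0A = np.asarray(C0A, dtype=np.int64)
    C1A = np.asarray(C1A, dtype=np.int64)
    C0 = C0A + np.asarray(C0a, dtype=np.int64)
    C1 = C1A + np.asarray(C1a, dtype=np.int64)
    logG = genotype_log_table(C0, C0A, C1, C1A, n)
    if mode == "genotype":
        cma = np.asarray(obs, dtype=np.int64)
        if cma.min(initial=0) < 0 or cma.max(initial=0) > n:
            raise ValueError("genotype counts must satisfy 0 <= CMA <= ploidy")
        return np.take_along_axis(
            logG, cma[:, np.newaxis, np.newaxis].repeat(n + 1, axis=1), axis=2
        )[:, :, 0]
    if mode != "pileup":
        raise ValueError(f"unknown observation mode {mode!r}")
    obs = np.asarray(obs, dtype=np.int64)
    rA = obs[:, 0]
    r = obs.sum(axis=1)
    cma = np.arange(n + 1)
    p = eps + (1.0 - 2.0 * eps) * cma / n
    # log Bin(rA; r, p_CMA), shape (S, n+1); 0*log(0) handled as 0
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(p > 0.0, np.log(p), -np.inf)[np.newaxis, :]
        lq = np.where(p < 1.0, np.log1p(-p), -np.inf)[np.newaxis, :]
        read_ll = (
            _log_binom_coef(r, rA)[:, np.newaxis]
            + np.where(rA[:, np.newaxis] > 0, rA[:, np.newaxis] * lp, 0.0)
            + np.where((r - rA)[:, np.newaxis] > 0, (r - rA)[:, np.newaxis] * lq, 0.0)
        )
    return logsumexp(logG + read_ll[:, np.newaxis, :], axis=2)


def emission_tables(dataset, sample_spec, eps: float = 0.01) -> list[np.ndarray]:
    """Log emission tables for one sample, one (S, n+1) array per chromosome."""
    n = sample_spec.ploidy
    out = []
    for block in dataset.chromosomes:
        table = emission_log_table(
            block.panel0_A,
            block.panel0_a,
            block.panel1_A,
            block.panel1_a,
            n,
            sample_spec.mode,
            block.obs[sample_spec.sample_id],
            eps,
        )
        if np.any(np.all(np.isneginf(table), axis=1)):
            bad = int(np.flatnonzero(np.all(np.isneginf(table), axis=1))[0])
            raise ValueError(
                f"all-zero emission vector for sample {sample_spec.sample_id} "
                f"at {block.chrom}:{block.pos[bad]}"
            )
        out.append(table)
    return out
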