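"""Forward likelihood, posterior decoding, admixture-time estimation and
block-bootstrap confidence intervals.

The hidden chain for a sample of ploidy n runs over S = {0..n} (count of
population-0 chromosomes); chromosomes and samples are independent, so the
joint log-likelihood is the sum of per-sample per-chromosome forward passes.
The time since admixture t enters only through the transition rates, so
emission tables are computed once and shared across all likelihood
evaluations of the golden-section search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .emissions import emission_tables
from .transitions import (
    DemographicParams,
    PoolTransitionKernel,
    initial_distribution,
    tract_rates,
)


@dataclass
class TimeEstimate:
    """Maximum-likelihood time since admixture (generations)."""

    t_hat: float
    loglik: float
    bracket: tuple[float, float]
    converged: bool
    at_boundary: bool
    n_evaluations: int


@dataclass
class BootstrapCI:
    """Percentile block-bootstrap confidence interval for t."""

    point_estimate: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray


# ---------------------------------------------------------------------------
# prepared emission groups
# ---------------------------------------------------------------------------


class _PloidyGroup:
    """Samples sharing a ploidy, with stacked per-chromosome emission tensors
    so a single batched forward pass covers the whole group."""

    def __init__(self, ploidy, specs, dataset, eps):
        self.ploidy = ploidy
        self.specs = specs
        self.E = []  # per chromosome: (S, B, n+1) scaled emissions
        self.offsets = []  # per chromosome: (S, B) log-scale offsets
        self.dists = [np.asarray(b.dist_morgans, dtype=float) for b in dataset.chromosomes]
        tables = [emission_tables(dataset, spec, eps) for spec in specs]
        for ci in range(len(dataset.chromosomes)):
            logE = np.stack([t[ci] for t in tables], axis=1)  # (S, B, n+1)
            off = logE.max(axis=2)
            self.E.append(np.exp(logE - off[:, :, np.newaxis]))
            self.offsets.append(off)


def _prepare_groups(dataset, samples, eps):
    by_ploidy: dict[int, list] = {}
    for spec in samples:
        by_ploidy.setdefault(spec.ploidy, []).append(spec)
    return [
        _PloidyGroup(n, specs, dataset, eps) for n, specs in sorted(by_ploidy.items())
    ]


def _forward_chromosome(E, offsets, dists, kernel, pi, keep_alpha=False):
    """Scaled batched forward pass over one chromosome.

    Returns (per-sample log-likelihood (B,), scaling factors (S, B),
    scaled alphas (S, B, K) if requested).
    """
    S, B, K = E.shape
    Ps = kernel.matrices(dists)  # None for large state spaces
    alphas = np.empty((S, B, K)) if keep_alpha else None
    alpha = pi[np.newaxis, :] * E[0]
    c = alpha.sum(axis=1)
    if np.any(c <= 0.0):
        raise ValueError("zero forward mass at first marker")
    alpha /= c[:, np.newaxis]
    scales = np.empty((S, B))
    scales[0] = c
    ll = np.log(c) + offsets[0]
    if keep_alpha:
        alphas[0] = alpha
    for s in range(1, S):
        if Ps is not None:
            alpha = (alpha @ Ps[s]) * E[s]
        else:
            alpha = kernel.propagate(alpha, dists[s]) * E[s]
        c = alpha.sum(axis=1)
        if np.any(c <= 0.0):
            raise ValueError(f"zero forward mass at marker index {s}")
        alpha /= c[:, np.newaxis]
        scales[s] = c
        ll += np.log(c) + offsets[s]
        if keep_alpha:
            alphas[s] = alpha
    return ll, scales, alphas, Ps


def _group_loglik(group, params):
    rates = tract_rates(params)
    kernel = PoolTransitionKernel(rates, group.ploidy)
    pi = initial_distribution(params.m, group.ploidy)
    total = 0.0
    for E, off, d in zip(group.E, group.offsets, group.dists):
        ll, _, _, _ = _forward_chromosome(E, off, d, kernel, pi)
        total += float(ll.sum())
    return total


def forward_loglikelihood(dataset, sample, params: DemographicParams, eps=0.01) -> float:
    """Exact log-likelihood of one sample's observations under (N, m, t, eps),
    summed over chromosomes."""
    group = _PloidyGroup(sample.ploidy, [sample], dataset, eps)
    return _group_loglik(group, params)


def joint_loglikelihood(dataset, samples, params: DemographicParams, eps=0.01) -> float:
    """Joint log-likelihood over independent samples and chromosomes."""
    return sum(
        _group_loglik(g, params) for g in _prepare_groups(dataset, samples, eps)
    )


def posterior_decode_all(dataset, samples, params: DemographicParams, eps=0.01):
    """Forward-backward smoothing posteriors for several samples at once.

    Returns {sample_id: [per-chromosome (S, n+1) row-normalized arrays]}.
    Samples of equal ploidy share one batched pass.
    """
    out: dict[str, list] = {s.sample_id: [] for s in samples}
    for group in _prepare_groups(dataset, samples, eps):
        rates = tract_rates(params)
        kernel = PoolTransitionKernel(rates, group.ploidy)
        pi = initial_distribution(params.m, group.ploidy)
        for E, off, d in zip(group.E, group.offsets, group.dists):
            _, scales, alphas, Ps = _forward_chromosome(
                E, off, d, kernel, pi, keep_alpha=True
            )
            S, B, K = E.shape
            post = np.empty((S, B, K))
            beta = np.ones((B, K))
            post[S - 1] = alphas[S - 1]
            for s in range(S - 2, -1, -1):
                if Ps is not None:
                    beta = (E[s + 1] * beta) @ Ps[s + 1].swapaxes(0, 1)
                else:
                    beta = kernel.propagate_back(E[s + 1] * beta, d[s + 1])
                beta /= scales[s + 1][:, np.newaxis]
                post[s] = alphas[s] * beta
            post /= post.sum(axis=2, keepdims=True)
            for b, spec in enumerate(group.specs):
                out[spec.sample_id].append(post[:, b, :])
    return out


def posterior_decode(dataset, sample, params: DemographicParams, eps=0.01):
    """Forward-backward smoothing posteriors for one sample.

    Returns a list of (S, n+1) row-normalized arrays, one per chromosome.
    """
    return posterior_decode_all(dataset, [sample], params, eps)[sample.sample_id]


def map_state(posterior_row) -> int:
    """Posterior-mode state; ties break toward the smaller index."""
    return int(np.argmax(posterior_row))


def credible_interval(posterior_row, mass: float = 0.95) -> tuple[int, int]:
    """Central credible state range under the cumulative-span rule.

    Each state i occupies the span (F(i-1), F(i)) of the cumulative posterior;
    a state is included iff its span intersects the open central interval
    ((1-mass)/2, 1-(1-mass)/2).  Returns the inclusive (low, high) state range,
    which is contiguous and contains the posterior median state.
    """
    p = np.asarray(posterior_row, dtype=float)
    F = np.cumsum(p)
    lo_q = (1.0 - mass) / 2.0
    hi_q = 1.0 - lo_q
    F_prev = np.concatenate([[0.0], F[:-1]])
    keep = (F > lo_q) & (F_prev < hi_q)
    idx = np.flatnonzero(keep)
    if idx.size == 0:  # numerically degenerate row; fall back to the mode
        j = int(np.argmax(p))
        return j, j
    return int(idx[0]), int(idx[-1])


# ---------------------------------------------------------------------------
# time estimation
# ---------------------------------------------------------------------------

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def golden_section_maximize(f, lo: float, hi: float, tol: float):
    """Golden-section search for the maximum of a unimodal function on
    [lo, hi].  Returns (x_best, f(x_best), n_evaluations).  Deterministic."""
    if hi <= lo:
        raise ValueError("empty bracket")
    a, b = lo, hi
    x1 = b - _INVPHI * (b - a)
    x2 = a + _INVPHI * (b - a)
    f1, f2 = f(x1), f(x2)
    n_eval = 2
    while b - a > tol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + _INVPHI * (b - a)
            f2 = f(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - _INVPHI * (b - a)
            f1 = f(x1)
        n_eval += 1
    if f1 >= f2:
        return x1, f1, n_eval
    return x2, f2, n_eval


def estimate_admixture_time(
    dataset,
    samples,
    m: float,
    N: float,
    eps: float = 0.01,
    bracket: tuple[float, float] = (1.0, 10000.0),
    tol: float = 1.0,
) -> TimeEstimate:
    """Maximum-likelihood estimate of the shared time since admixture.

    t is optimized jointly over all samples and chromosomes by golden-section
    search on the summed forward log-likelihood; emission tables are computed
    once since they do not depend on t.
    """
    groups = _prepare_groups(dataset, samples, eps)

    def objective(t):
        params = DemographicParams(N=N, m=m, t=t)
        return sum(_group_loglik(g, params) for g in groups)

    t_hat, ll, n_eval = golden_section_maximize(objective, bracket[0], bracket[1], tol)
    at_boundary = t_hat <= bracket[0] + tol or t_hat >= bracket[1] - tol
    return TimeEstimate(
        t_hat=float(t_hat),
        loglik=float(ll),
        bracket=tuple(bracket),
        converged=True,
        at_boundary=at_boundary,
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# block bootstrap
# ---------------------------------------------------------------------------


def _dataset_blocks(dataset, block_size: int):
    """Partition every chromosome into contiguous runs of block_size markers
    (the final run of a chromosome may be shorter)."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    blocks = []
    for ci, block in enumerate(dataset.chromosomes):
        for start in range(0, block.n_markers, block_size):
            blocks.append((ci, start, min(start + block_size, block.n_markers)))
    return blocks


def _slice_block(dataset, ci, start, stop, new_name):
    from .io_formats import ChromosomeBlock

    b = dataset.chromosomes[ci]
    return ChromosomeBlock(
        chrom=new_name,
        pos=b.pos[start:stop],
        panel0_A=b.panel0_A[start:stop],
        panel0_a=b.panel0_a[start:stop],
        panel1_A=b.panel1_A[start:stop],
        panel1_a=b.panel1_a[start:stop],
        dist_morgans=b.dist_morgans[start:stop],
        obs={sid: o[start:stop] for sid, o in b.obs.items()},
    )


def block_bootstrap_time(
    dataset,
    samples,
    m: float,
    N: float,
    block_size: int,
    n_reps: int,
    seed: int,
    eps: float = 0.01,
    bracket: tuple[float, float] = (1.0, 10000.0),
    tol: float = 1.0,
) -> BootstrapCI:
    """Percentile confidence interval for t by resampling contiguous marker
    blocks with replacement up to the original marker count.

    Each resampled block enters the replicate as an independent chromosome
    (the distance entry at a block's first marker is ignored by the chain,
    so no artificial junction distances are introduced).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    from .io_formats import Dataset

    blocks = _dataset_blocks(dataset, block_size)
    total = dataset.n_markers
    rng = np.random.default_rng(seed)
    point = estimate_admixture_time(dataset, samples, m, N, eps, bracket, tol)
    reps = np.empty(n_reps)
    for rep in range(n_reps):
        chosen = []
        size = 0
        while size < total:
            ci, start, stop = blocks[rng.integers(len(blocks))]
            chosen.append(
                _slice_block(dataset, ci, start, stop, f"bootstrap{len(chosen)}")
            )
            size += stop - start
        rep_dataset = Dataset(chromosomes=chosen, samples=dataset.samples)
        est = estimate_admixture_time(rep_dataset, samples, m, N, eps, bracket, tol)
        reps[rep] = est.t_hat
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapCI(
        point_estimate=point.t_hat,
        ci_low=float(lo),
        ci_high=float(hi),
        replicates=reps,
    )
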