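"""Marker selection and ancestral-LD pruning of reference panels.

Linkage disequilibrium that pre-exists inside a source population (ancestral
LD) violates the conditional independence of markers given the local ancestry
state and inflates admixture-time estimates, so sites in strong LD within
either reference panel are thinned before inference.  Ancestry-informative
markers are those whose panel allele frequencies differ by at least
``min_diff`` (default 0.2).

A haplotype panel is a (chromosomes x sites) matrix of 0/1 allele indicators
with NaN for missing calls, plus per-site genetic positions in centimorgans.
The LD statistic is the absolute Pearson correlation of allele indicators
across chromosomes (written r_LD to avoid collision with read depth r),
computed on pairwise-complete observations within a genetic window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HaplotypePanel:
    """Phased/inbred reference haplotypes: rows are chromosomes, columns are
    sites; entries 0/1 or NaN (missing); ``pos_cm`` non-decreasing."""

    haplotypes: np.ndarray
    pos_cm: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=float)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[1] != self.pos_cm.size:
            raise ValueError("one genetic position required per site")
        if np.any(np.diff(self.pos_cm) < 0):
            raise ValueError("genetic positions must be non-decreasing")

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def call_rate(self) -> np.ndarray:
        if self.haplotypes.shape[0] == 0:
            return np.zeros(self.n_sites)
        return 1.0 - np.isnan(self.haplotypes).mean(axis=0)

    def frequencies(self) -> np.ndarray:
        """Per-site allele-1 frequency over non-missing calls (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.haplotypes, axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(count of allele 1, count of allele 0) per site."""
        called = ~np.isnan(self.haplotypes)
        ones = np.nansum(self.haplotypes, axis=0).astype(np.int64)
        return ones, called.sum(axis=0) - ones


def select_informative(panel0_freqs, panel1_freqs, min_diff: float = 0.2) -> np.ndarray:
    """Mask of ancestry-informative sites: |f0 - f1| >= min_diff (inclusive)."""
    f0 = np.asarray(panel0_freqs, dtype=float)
    f1 = np.asarray(panel1_freqs, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.abs(f0 - f1) >= min_diff


def call_rate_filter(panel0: HaplotypePanel, panel1: HaplotypePanel, min_rate: float = 0.5) -> np.ndarray:
    """Mask of sites with call rate >= min_rate in BOTH panels."""
    return (panel0.call_rate() >= min_rate) & (panel1.call_rate() >= min_rate)


def _pairwise_complete_r(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Pearson correlation over pairwise-complete rows; 0.0 when undefined
    (monomorphic column or < 2 complete pairs)."""
    ok = ~(np.isnan(col_a) | np.isnan(col_b))
    if ok.sum() < 2:
        return 0.0
    a = col_a[ok]
    b = col_b[ok]
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def pairwise_r(panel: HaplotypePanel, window_cm: float = 0.01):
    """All within-window site pairs and their LD.

    Returns a list of (site_a, site_b, r_LD) for every pair of sites whose
    genetic positions differ by at most ``window_cm`` centimorgans
    (site_a < site_b).  Pairs with undefined correlation are reported as 0.
    """
    out = []
    pos = panel.pos_cm
    H = panel.haplotypes
    for a in range(panel.n_sites):
        b = a + 1
        while b < panel.n_sites and pos[b] - pos[a] <= window_cm:
            out.append((a, b, _pairwise_complete_r(H[:, a], H[:, b])))
            b += 1
    return out


def prune_ld(
    panel0: HaplotypePanel,
    panel1: HaplotypePanel,
    threshold: float = 0.4,
    window_cm: float = 0.01,
) -> np.ndarray:
    """Greedy left-to-right LD pruning mask.

    A site is kept unless its |r_LD| with an already-kept site within the
    window exceeds ``threshold`` in either panel (the later site of a
    violating pair is dropped).  After pruning, no retained pair within the
    window violates the threshold in either panel.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    n_sites = panel0.n_sites
    if panel1.n_sites != n_sites:
        raise ValueError("panels must cover the same sites")
    pos = panel0.pos_cm
    keep = np.ones(n_sites, dtype=bool)
    kept: list[int] = []
    for b in range(n_sites):
        violated = False
        for a in reversed(kept):
            if pos[b] - pos[a] > window_cm:
                break
            for panel in (panel0, panel1):
                r_ld = _pairwise_complete_r(
                    panel.haplotypes[:, a], panel.haplotypes[:, b]
                )
                if abs(r_ld) > threshold:
                    violated = True
                    break
            if violated:
                break
        if violated:
            keep[b] = False
        else:
            kept.append(b)
    return keep


def preprocess_panels(
    panel0: HaplotypePanel,
    panel1: HaplotypePanel,
    min_call_rate: float = 0.5,
    min_diff: float = 0.2,
    ld_threshold: float = 0.4,
    window_cm: float = 0.01,
) -> np.ndarray:
    """Full marker-selection pipeline mask: call-rate filter, then
    informativeness selection, then ancestral-LD pruning (pruning sees only
    the sites that survived the first two filters)."""
    mask = call_rate_filter(panel0, panel1, min_call_rate)
    mask &= select_informative(panel0.frequencies(), panel1.frequencies(), min_diff)
    idx = np.flatnonzero(mask)
    sub0 = HaplotypePanel(panel0.haplotypes[:, idx], panel0.pos_cm[idx])
    sub1 = HaplotypePanel(panel1.haplotypes[:, idx], panel1.pos_cm[idx])
    ld_keep = prune_ld(sub0, sub1, ld_threshold, window_cm)
    out = np.zeros(panel0.n_sites, dtype=bool)
    out[idx[ld_keep]] = True
    return out
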