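"""Accuracy statistics comparing decoded posteriors with simulation truth.

For a sample of ploidy n with posterior table p(H_v = i | r) and true
population-0 chromosome counts I_v over S sites, the statistics are:

* mean posterior error, the posterior-weighted absolute state distance on the
  ancestry-frequency scale,

      E = sum_v sum_i p(H_v = i | r) |i - I_v| / (S n),

* the proportion of sites whose true state lies inside the 95% credible
  interval, and the mean interval width in state units (number of states in
  the interval minus one),
* the proportion of sites where the posterior-mode state equals the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm_engine import credible_interval


@dataclass
class AccuracyReport:
    mean_posterior_error: float
    ci_coverage: float
    ci_width: float
    mode_accuracy: float
    n_sites: int
    ploidy: int


def mean_posterior_error(posterior_table, truth_states, n: int) -> float:
    """E = sum_v sum_i p(H_v=i|r) |i - I_v| / (S n)."""
    post = np.asarray(posterior_table, dtype=float)
    truth = np.asarray(truth_states)
    if post.shape[0] != truth.shape[0]:
        raise ValueError("posterior table and truth differ in length")
    if post.shape[1] != n + 1:
        raise ValueError("posterior table does not match ploidy")
    states = np.arange(n + 1)
    dist = np.abs(states[np.newaxis, :] - truth[:, np.newaxis])
    return float((post * dist).sum() / (post.shape[0] * n))


def interval_stats(posterior_table, truth_states, mass: float = 0.95):
    """(coverage, mean width) of the central credible intervals.

    Coverage is the fraction of sites whose true state falls inside the
    interval; width is the mean interval span in state units (a single-state
    interval has width 0).
    """
    post = np.asarray(posterior_table, dtype=float)
    truth = np.asarray(truth_states)
    if post.shape[0] != truth.shape[0]:
        raise ValueError("posterior table and truth differ in length")
    hits = 0
    widths = np.empty(post.shape[0])
    for v in range(post.shape[0]):
        lo, hi = credible_interval(post[v], mass)
        widths[v] = hi - lo
        if lo <= truth[v] <= hi:
            hits += 1
    return hits / post.shape[0], float(widths.mean())


def mode_accuracy(posterior_table, truth_states) -> float:
    """Fraction of sites where the posterior-mode state equals the truth
    (argmax ties resolve to the smaller state)."""
    post = np.asarray(posterior_table, dtype=float)
    truth = np.asarray(truth_states)
    if post.shape[0] != truth.shape[0]:
        raise ValueError("posterior table and truth differ in length")
    return float((post.argmax(axis=1) == truth).mean())


def accuracy_report(posterior_table, truth_states, n: int, mass: float = 0.95) -> AccuracyReport:
    cov, width = interval_stats(posterior_table, truth_states, mass)
    return AccuracyReport(
        mean_posterior_error=mean_posterior_error(posterior_table, truth_states, n),
        ci_coverage=cov,
        ci_width=width,
        mode_accuracy=mode_accuracy(posterior_table, truth_states),
        n_sites=int(np.asarray(truth_states).shape[0]),
        ploidy=n,
    )


def pooled_accuracy_report(tables_and_truths, n: int, mass: float = 0.95) -> AccuracyReport:
    """Accuracy statistics pooled over sites of several samples of one ploidy
    (statistics are computed over the concatenated marker-sample pairs)."""
    posts = np.concatenate([np.asarray(p) for p, _ in tables_and_truths])
    truths = np.concatenate([np.asarray(t) for _, t in tables_and_truths])
    return accuracy_report(posts, truths, n, mass)


def replicate_summary(records) -> pd.DataFrame:
    """Condition-level means of t-hat and the accuracy statistics.

    ``records`` is an iterable of dicts with at least the keys ``condition``,
    ``true_t`` and ``t_hat`` and optionally the AccuracyReport fields; one row
    per condition is returned, averaging within each condition over
    replicates (statistics were already pooled over sites within each
    replicate).  Conditions without records are simply absent.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        return df
    value_cols = [
        c
        for c in (
            "true_t",
            "t_hat",
            "mean_posterior_error",
            "ci_coverage",
            "ci_width",
            "mode_accuracy",
        )
        if c in df.columns
    ]
    out = df.groupby("condition", sort=False)[value_cols].mean()
    out["n_replicates"] = df.groupby("condition", sort=False).size()
    return out.reset_index()
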