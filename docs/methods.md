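# Methods

## The model

`admixhmm` infers local ancestry along the chromosomes of individuals,
inbred lines or sequencing pools sampled from a population formed by
admixture between two source populations (labelled 0 and 1). A sample of
ploidy `n` — one haploid genome, a diploid, or a pool of `b` equally
represented diploids treated as `n = 2b` — is modelled by a hidden Markov
chain `{H_v}` over the marker index `v`, where the state `i ∈ {0, …, n}` is
the number of chromosomes in the sample carrying population-0 ancestry at
that site. This convention (state = count of population-0 chromosomes) is
used in every module; for `n = 1`, state 1 is ancestry 0.

### Emissions

At each biallelic marker we observe reference-panel allele counts
(`C0A` of `C0` alleles A in panel 0, `C1A` of `C1` in panel 1) and, per
sample, either a read pileup (`rA` of `r` reads supporting A) or a known
genotype count (`CMA` copies of A among the `n` chromosomes). The emission
probability integrates over the unknown population allele frequencies `f0`,
`f1` with independent uniform priors per site, treating the panel counts and
the sample's latent allele counts as binomial draws from the same frequency:

* panel: `CjA ~ Bin(Cj, fj)`,
* sample: `CM0A ~ Bin(i, f0)`, `CM1A ~ Bin(n−i, f1)`,
* reads: each read picks one of the `n` chromosomes uniformly
  (`r0 ~ Bin(r, i/n)`) and reports allele A with probability
  `(1−ε)·CM0A/i + ε·(1−CM0A/i)` for an ancestry-0 read (symmetric error
  rate `ε`, default 0.01; reads matching neither allele are assumed
  discarded upstream).

The Beta integrals collapse to ratios of factorials, evaluated with
log-gamma lookups so arbitrarily large panels and ploidies cannot overflow.
Because both panel and sample counts bind to the *same* frequency, the model
propagates the double binomial sampling noise of pool-seq rather than
treating pool frequencies as known.

Two algebraically identical routes compute the pileup emission. The
reference route sums explicitly over the read ancestry split `(r0, r0A)`
with a per-population component term. The production route marginalizes
over the latent total `CMA = CM0A + CM1A`: since every read is an
independent uniform draw from the `n` chromosomes, the probability a read
shows A given the latent counts is `ε + (1−2ε)·CMA/n`, hence

    Pr(rA | r, H=i) = Σ_CMA Bin(rA; r, ε + (1−2ε)·CMA/n) · Pr(CMA, C0A, C1A | H=i),

where the second factor is exactly the known-genotype emission. This is the
binomial thinning identity; the suite verifies the equality exhaustively on
small instances and against adaptive numerical integration of the defining
integrals. With `i = 0` the state contributes only through `r0 = 0`, so the
`0/0` success probability is never evaluated (guarded explicitly).

A site with no reads (`r = 0`) produces a state-independent emission, which
is how missing pileup observations are encoded; genotype mode has no missing
code and requires pre-filtered sites.

### Transitions

Under an SMC'-based model of an admixed population of constant diploid size
`N`, founded `t` generations ago with fraction `m` of ancestry from
population 1, the per-Morgan ancestry switch rates on one chromosome are

    λ0 = 2Nm(1 − e^(−t/2N))        (ancestry 0 → 1)
    λ1 = 2N(1−m)(1 − e^(−t/2N))    (ancestry 1 → 0).

The saturation for `t ≳ 2N` reflects back-coalescence: recombination events
that rejoin the previous marginal genealogy leave no junction. The
single-chromosome transition over `d` Morgans is the two-state
continuous-chain solution with relaxation `e^(−d(λ0+λ1))`. A pool of `n`
chromosomes is approximated as `n` independent copies of this chain, so the
state count moves as `Bin(i, 1−P_keep) + Bin(n−i, P_gain)` over an interval.
Tract non-independence among chromosomes is a known violation of this
approximation; its consequences (downward time bias in large pools) are
quantified by simulation, not modelled.

Internally the pooled chain is propagated through its birth–death generator
(`i → i+1` at rate `(n−i)λ1`, `i → i−1` at rate `iλ0`), which satisfies
detailed balance with respect to the Binomial(`n`, `λ1/(λ0+λ1)`) stationary
law and is therefore diagonally similar to a symmetric tridiagonal matrix.
One symmetric eigendecomposition per `(t, n)` yields the exact transition
operator for every inter-marker distance; for small state spaces (`n+1 ≤
12`) the per-interval matrices are formed in a single batched einsum, for
large pools the factorized operator is applied directly (three small
matrix–vector products per marker). When the stationary law underflows the
square-root range (pools beyond ~600 chromosomes at extreme `m`), the code
falls back to dense `expm` per distinct distance. Equality with the direct
binomial construction and with 2^n path enumeration is pinned by tests.

The first marker of each chromosome uses the stationary state distribution
Binomial(`n`, `1−m`); its distance entry is ignored. A distance of zero
yields the identity, so duplicated map positions are harmless.

### Likelihood, decoding, time estimation

Forward and forward–backward recursions run with per-site normalization;
the normalizers accumulate the log-likelihood (numerically equivalent to a
log-space recursion, but vectorizable across the samples of one ploidy).
Chromosomes and samples are independent, so the joint log-likelihood is a
sum. Emission tables do not depend on `t` and are computed once per run.

The time since admixture is estimated by golden-section search on the
summed log-likelihood, shared across all samples and chromosomes (the
likelihood is assumed unimodal in `t`). Defaults: bracket `[1, 10000]`
generations, absolute tolerance 1 generation, both exposed as flags. An
estimate within the tolerance of a bracket endpoint is flagged as a
boundary solution. `m` ∈ {0, 1} is rejected at input: without ancestry
uncertainty the hidden chain is degenerate.

Confidence intervals for `t` come from a block bootstrap: contiguous blocks
of markers (default 500) are resampled with replacement up to the original
marker count, each block re-entering as an independent chromosome — the
chain never crosses block joins, so no artificial junction distances are
introduced — and `t` is re-estimated per replicate; the 2.5%/97.5%
replicate percentiles are reported. A single whole-dataset block is allowed
and degenerates to the point estimate.

The per-site 95% credible interval over the ordered state axis uses a
cumulative-span rule: state `i` occupies the span `(F(i−1), F(i))` of the
cumulative posterior and is included iff that span intersects the open
central interval `(0.025, 0.975)`. This makes the interval contiguous,
containing the median state, and equal to `{mode}` for concentrated
posteriors; interval width is reported in state units (states included
minus one). The posterior-mode state breaks ties toward the smaller index.

## Marker selection and ancestral LD pruning

Linkage disequilibrium that pre-exists within a source population violates
the conditional independence of markers given ancestry and inflates time
estimates, so reference panels are pruned before inference: among all site
pairs within 0.01 cM, whenever the absolute Pearson correlation of allele
indicators (pairwise-complete, |r_LD|) exceeds the threshold in either
panel, the later site is dropped (greedy left-to-right; deterministic).
The default threshold 0.4 is calibrated for Drosophila-scale ancestral LD;
populations with extensive LD (e.g. humans) need substantially more
stringent pruning, which should be established by simulation for the data
at hand. The pipeline order is: call-rate filter (≥ 50% in both panels) →
ancestry-informative selection (|f0 − f1| ≥ 0.2, inclusive) → LD pruning.
Pairs with an undefined correlation (monomorphic columns) are treated as
unlinked.

## Synthetic data generator

The simulator emulates the validation setting end to end and is the basis
of every quantitative check in the package.

* **Ancestral variation.** Candidate marker positions are uniform over a
  10 Mb arm mapped at a constant 2.5 cM/Mb (L = 0.25 Morgans). True
  frequencies follow `f0 ~ Uniform(0,1)`,
  `f1 = clamp(f0 + Normal(0, σ_div), 0, 1)` with `σ_div = 0.4`; the
  clamping fixes a share of sites in population 1, mimicking
  bottleneck-driven fixation, and leaves well over 30% of sites passing the
  0.2 informativeness filter. Panel (50 chromosomes per population) and
  donor (150) haplotypes are drawn binomially and independently per site,
  so the default panels carry no ancestral LD; a founder-mosaic option
  (`ld_founders`) generates bottlenecked panels with real LD for exercising
  the pruning stage, and an import hook accepts externally simulated
  haplotype matrices (e.g. coalescent output). Defaults are a deliberate
  desk-scale compromise: 24 000 candidate sites (~12 000 retained) against
  the much denser variation of a real fly chromosome arm.
* **Ancestry tracts.** Either iid draws from the model's own alternating
  exponential renewal process (rates λ0, λ1; initial ancestry
  Bernoulli(1−m)) — the correct null for calibration checks — or an
  explicit hermaphroditic diploid Wright–Fisher population: founding pulse
  (fraction `m` of unadmixed ancestry-1 individuals) or continuous
  migration (Binomial(N, rate) unadmixed replacements per generation into
  an initially pure ancestry-0 population), Poisson(L) crossovers placed
  uniformly without interference, and optional additive viability selection
  at ancestry-fixed loci (weights `1, 1+s, 1+2s` per locus, multiplicative
  across loci, realized by rejection against the maximum weight; `s ~
  Uniform[0.005, 0.05]` when drawn). The forward simulator tracks ancestry
  on the grid of retained markers plus selected loci as boolean matrices —
  exact for all downstream uses, with tract boundaries reported at grid
  resolution.
* **Mosaics and reads.** Each maximal same-ancestry run of a sampled copy
  is filled from a distinct held-out donor haplotype of that ancestry (no
  donor reuse within a copy). Pools of `ploidy` copies yield sample allele
  counts `CMA`; reads are `r ~ Poisson(depth)` with
  `rA ~ Bin(r, (1−ε)CMA/n + ε(1−CMA/n))`, depth defaulting to the ploidy
  so that per-chromosome coverage is constant across pooling strategies.

What the generator does *not* emulate: real site-frequency spectra and
ancestral LD (default panels are iid per site), recombination-map error,
reference-panel/admixed-population frequency divergence, mapping bias, or
indel/error-profile structure. Passing tests therefore demonstrate
correctness of the inference machinery and robustness to the modelled
violations (continuous migration, selection, tract non-independence), not
performance on any particular real dataset.

## Accuracy statistics

Against simulation truth `I_v` (true population-0 count per marker) the
package reports: the mean posterior error
`E = Σ_v Σ_i p(H_v=i|r)·|i−I_v| / (S·n)` (an ancestry-frequency-scale error
in [0,1]); the fraction of sites whose truth falls in the 95% credible
interval; the mean interval width in state units; and the fraction of sites
where the posterior mode equals the truth. Statistics are pooled over the
marker–sample pairs of a replicate, then averaged across replicates.

## Scaled validation study

`scripts/acceptance.py` reruns the deviation-from-neutrality study at desk
scale: N = 1000 (vs 10 000 at full scale), 10 replicates per condition,
40 sampled copies analyzed as 40 haploids or 20 diploids, conditions
(continuous migration at 5×10⁻⁴ from t=100; 4×10⁻³ from t=500; single
pulse at t=100 with 2 selected loci; pulse at t=500 with 20 loci;
migration 5×10⁻⁴ from t=500). The inference is given the simulation's `N`
and the realized sampled ancestry fraction as `m`, mirroring the assumption
that the global ancestry proportion is known. Haploid runs report the mean
time estimate; diploid runs additionally decode at the estimated time and
report mode accuracy and mean posterior error. Replicate seeds derive from
the single `--seed` argument via `numpy.random.SeedSequence`.

Expected qualitative behavior, reproduced by the suite: continuous
migration and widespread ancestry-linked selection both shorten apparent
tract age and bias `t̂` downward (migration to roughly the mean residence
time of surviving migrant ancestry; selection increasingly with the number
of loci), while local-ancestry accuracy stays high; pools of many
chromosomes (ploidy 100 check) show a strong downward time bias from tract
non-independence with mean posterior error still below 0.1.

## Numerical choices and limitations

* All probability accumulation in log space or with per-site normalization;
  factorial ratios via a log-gamma lookup table (exact integer arguments).
* Transition caching keyed on distance to 12 significant digits inside a
  kernel; kernels rebuilt per candidate `t`.
* Ties in the posterior mode break toward fewer population-0 chromosomes;
  credible intervals use open-interval span intersection.
* Golden-section assumes unimodality of the likelihood in `t`; multimodal
  likelihoods (not observed in the validation range) would need a grid scan.
* Two source populations only; no two-pulse or multi-way admixture, no
  site-specific or asymmetric error rates, no Viterbi path output, no
  modelling of residual ancestral LD — pruning is the supported mitigation.
* Estimates of `t` are only as good as the genetic map and the assumed `N`;
  `t̂` saturates near `N` generations for small populations (coalescence),
  and under-estimation is expected for large pools and for non-pulse
  demography.
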