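"""Synthetic admixed-population data: ancestral panels, ancestry tracts,
mosaic haplotypes and read pileups.

The generator emulates the validation setting of the method: two
differentiated ancestral populations segregating biallelic markers on a
chromosome arm of ``L`` Morgans, an admixed population founded (or
continuously seeded) from them, and shotgun read counts over the sampled
chromosomes.  Ancestry tracts come either from independent draws of the
SMC'-rate exponential tract model (the HMM's own assumption, useful for
bias-free calibration checks) or from an explicit forward-time Wright-Fisher
population with recombination, optional continuous migration and optional
additive viability selection at ancestry-fixed loci.

The forward simulator tracks ancestry on the fixed grid of candidate marker
and selected-locus positions as boolean matrices, which is exact for every
quantity consumed downstream (mosaic construction, truth states, fitness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ChromosomeBlock, Dataset, SampleSpec
from .preprocess import HaplotypePanel, preprocess_panels
from .transitions import DemographicParams, tract_rates

#: Drosophila-like defaults: a 10 Mb chromosome arm at 2.5 cM/Mb.
DEFAULT_CHROM_BP = 10_000_000
DEFAULT_LENGTH_MORGANS = 0.25


@dataclass(frozen=True)
class SelectionLocus:
    """An ancestry-fixed selected locus: the ancestry label is the allele."""

    position: float  # Morgans
    s: float  # additive selective coefficient per favored allele copy
    favored_ancestry: int  # 0 or 1


@dataclass(frozen=True)
class AncestryTract:
    """Half-open [start, end) tract of one ancestry on one chromosome copy."""

    copy_id: int
    start: float
    end: float
    ancestry: int


@dataclass
class SimConfig:
    """Study conditions for one synthetic admixture experiment."""

    t: float
    N: int = 10_000
    m: float = 0.5
    length_morgans: float = DEFAULT_LENGTH_MORGANS
    chrom_bp: int = DEFAULT_CHROM_BP
    n_candidate_sites: int = 24_000
    panel_size: int = 50
    donor_size: int = 150
    sigma_div: float = 0.4
    migration_mode: str = "pulse"  # "pulse" | "continuous"
    migration_rate: float = 0.0  # per-generation replacement fraction
    selection_loci: tuple[SelectionLocus, ...] = ()
    n_copies: int = 40
    mean_depth: float | None = None  # None -> equal to sample ploidy
    eps: float = 0.01
    min_diff: float = 0.2
    ld_threshold: float = 0.4
    window_cm: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.migration_mode not in ("pulse", "continuous"):
            raise ValueError(f"unknown migration mode {self.migration_mode!r}")
        for locus in self.selection_loci:
            if not 0.0 <= locus.position < self.length_morgans:
                raise ValueError("selected locus outside the chromosome")


def draw_selection_loci(n_loci: int, length_morgans: float, rng) -> tuple[SelectionLocus, ...]:
    """Selected loci at uniform positions with s ~ Uniform[0.005, 0.05] and
    the favored ancestry chosen by fair coin."""
    return tuple(
        SelectionLocus(
            position=float(rng.uniform(0.0, length_morgans)),
            s=float(rng.uniform(0.005, 0.05)),
            favored_ancestry=int(rng.integers(2)),
        )
        for _ in range(n_loci)
    )


# ---------------------------------------------------------------------------
# ancestral panels
# ---------------------------------------------------------------------------


@dataclass
class PanelSim:
    """Simulated ancestral variation at the candidate marker sites."""

    pos_bp: np.ndarray
    pos_morgans: np.ndarray
    f0: np.ndarray  # true allele-A frequency, population 0
    f1: np.ndarray
    panel0: HaplotypePanel
    panel1: HaplotypePanel
    donors0: np.ndarray  # held-out haplotypes used as mosaic donors
    donors1: np.ndarray


def _founder_copy_haplotypes(n_chroms, f, pos_cm, n_founders, switch_per_cm, rng):
    """Haplotypes built by mosaic copying from a small founder set: emulates a
    bottlenecked (reduced diversity, elevated LD) source population."""
    n_sites = f.size
    founders = (rng.random((n_founders, n_sites)) < f).astype(float)
    out = np.empty((n_chroms, n_sites))
    d_cm = np.diff(pos_cm, prepend=pos_cm[0])
    p_switch = 1.0 - np.exp(-switch_per_cm * d_cm)
    for c in range(n_chroms):
        switches = rng.random(n_sites) < p_switch
        switches[0] = True
        ids = rng.integers(n_founders, size=int(switches.sum()))
        track = np.zeros(n_sites, dtype=np.int64)
        track[switches] = 1
        track = np.cumsum(track) - 1
        out[c] = founders[ids[track], np.arange(n_sites)]
    return out


def simulate_ancestral_panels(
    n_sites: int,
    panel_sizes: tuple[int, int] = (50, 50),
    donor_sizes: tuple[int, int] = (150, 150),
    sigma_div: float = 0.4,
    chrom_bp: int = DEFAULT_CHROM_BP,
    length_morgans: float = DEFAULT_LENGTH_MORGANS,
    ld_founders: tuple[int, int] = (0, 0),
    haplotypes: tuple[np.ndarray, np.ndarray] | None = None,
    seed=None,
) -> PanelSim:
    """Two differentiated ancestral panels plus held-out donor haplotypes.

    Per-site true frequencies follow f0 ~ Uniform(0, 1) and
    f1 = clamp(f0 + Normal(0, sigma_div), 0, 1); the clamping fixes a fraction
    of sites in population 1, giving it reduced diversity.  Haplotypes are
    drawn binomially and independently per site; passing ``ld_founders``
    (founder-set sizes per population) instead builds chromosomes as founder
    mosaics, introducing within-population LD.  ``haplotypes`` accepts two
    externally simulated (chromosomes x sites) 0/1 matrices (e.g. coalescent
    output); rows beyond the panel size become donors.
    """
    if min(panel_sizes) < 2:
        raise ValueError("panel size must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pos_bp = np.sort(rng.choice(np.arange(1, chrom_bp + 1), size=n_sites, replace=False))
    pos_m = pos_bp * (length_morgans / chrom_bp)
    pos_cm = pos_m * 100.0
    if haplotypes is not None:
        mats = [np.asarray(h, dtype=float) for h in haplotypes]
        freqs = [h.mean(axis=0) for h in mats]
    else:
        f0 = rng.uniform(0.0, 1.0, n_sites)
        f1 = np.clip(f0 + rng.normal(0.0, sigma_div, n_sites), 0.0, 1.0)
        freqs = [f0, f1]
        mats = []
        for pop, f in enumerate(freqs):
            total = panel_sizes[pop] + donor_sizes[pop]
            if ld_founders[pop] > 0:
                mats.append(
                    _founder_copy_haplotypes(
                        total, f, pos_cm, ld_founders[pop], 100.0, rng
                    )
                )
            else:
                mats.append((rng.random((total, n_sites)) < f).astype(float))
    return PanelSim(
        pos_bp=pos_bp,
        pos_morgans=pos_m,
        f0=freqs[0],
        f1=freqs[1],
        panel0=HaplotypePanel(mats[0][: panel_sizes[0]], pos_cm),
        panel1=HaplotypePanel(mats[1][: panel_sizes[1]], pos_cm),
        donors0=mats[0][panel_sizes[0] :],
        donors1=mats[1][panel_sizes[1] :],
    )


# ---------------------------------------------------------------------------
# ancestry tracts
# ---------------------------------------------------------------------------


def simulate_tracts_iid(
    params: DemographicParams, L: float, n_copies: int, seed=None
) -> list[list[AncestryTract]]:
    """Chromosome copies as independent alternating-exponential renewal
    processes with the SMC' per-Morgan switch rates: ancestry-0 segment
    lengths ~ Exp(lambda0), ancestry-1 ~ Exp(lambda1), initial ancestry 0 with
    probability 1 - m."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rates = tract_rates(params)
    lam = (rates.lam0, rates.lam1)
    copies = []
    for copy_id in range(n_copies):
        tracts = []
        pos = 0.0
        anc = 0 if rng.random() < (1.0 - params.m) else 1
        while pos < L:
            if lam[anc] > 0.0:
                length = rng.exponential(1.0 / lam[anc])
            else:
                length = np.inf
            end = min(pos + length, L)
            tracts.append(AncestryTract(copy_id, pos, end, anc))
            pos = end
            anc = 1 - anc
        copies.append(tracts)
    return copies


def ancestry_at(tracts: list[AncestryTract], positions: np.ndarray) -> np.ndarray:
    """Ancestry label of one chromosome copy at each position (Morgans)."""
    starts = np.array([t.start for t in tracts])
    labels = np.array([t.ancestry for t in tracts], dtype=np.uint8)
    idx = np.searchsorted(starts, positions, side="right") - 1
    return labels[np.clip(idx, 0, len(tracts) - 1)]


def tracts_from_grid(row: np.ndarray, grid: np.ndarray, L: float, copy_id: int = 0):
    """Tract structure of one gridded ancestry vector; boundaries are placed
    midway between adjacent grid points of differing ancestry."""
    row = np.asarray(row)
    change = np.flatnonzero(row[1:] != row[:-1])
    bounds = [0.0] + [(grid[c] + grid[c + 1]) / 2.0 for c in change] + [L]
    labels = np.concatenate([row[change], [row[-1]]]) if change.size else row[:1]
    return [
        AncestryTract(copy_id, bounds[k], bounds[k + 1], int(labels[k]))
        for k in range(len(bounds) - 1)
    ]


# ---------------------------------------------------------------------------
# forward-time Wright-Fisher admixture
# ---------------------------------------------------------------------------


def _make_gametes(pop, parents, grid, L, rng):
    """One gamete per entry of ``parents`` (indices of diploid individuals).
    ``pop`` has shape (2N, G); individual j owns rows 2j and 2j+1.

    Crossover counts are Poisson(L); the frequent 0- and 1-crossover gametes
    are formed with single vectorized gathers, only multi-crossover gametes
    take the per-gamete path.
    """
    n = parents.size
    ks = rng.poisson(L, n)
    coin = rng.integers(0, 2, n)
    out = np.empty((n, grid.size), dtype=pop.dtype)
    plain = ks == 0
    out[plain] = pop[2 * parents[plain] + coin[plain]]
    single = ks == 1
    if np.any(single):
        idx = np.flatnonzero(single)
        xs = rng.uniform(0.0, L, idx.size)
        after = grid[np.newaxis, :] > xs[:, np.newaxis]  # True past the crossover
        first = pop[2 * parents[idx] + coin[idx]]
        second = pop[2 * parents[idx] + 1 - coin[idx]]
        out[idx] = np.where(after, second, first)
    for j in np.flatnonzero(ks >= 2):
        xs = np.sort(rng.uniform(0.0, L, ks[j]))
        take_second = (np.searchsorted(xs, grid, side="right") + coin[j]) % 2
        a = pop[2 * parents[j]]
        b = pop[2 * parents[j] + 1]
        out[j] = np.where(take_second == 0, a, b)
    return out


def simulate_admixed_forward(config: SimConfig, grid: np.ndarray, seed=None) -> np.ndarray:
    """Forward Wright-Fisher simulation of an admixed population; returns the
    (n_copies, len(grid)) ancestry matrix of the sampled chromosome copies,
    drawn one per distinct individual (alternating homologues).

    The population is hermaphroditic and diploid with ``config.N``
    individuals.  A pulse founding seeds a fraction m of individuals from
    ancestry 1; continuous migration instead starts from pure ancestry 0 and
    replaces a Binomial(N, rate) set of individuals with unadmixed ancestry-1
    migrants each generation.  Gametes receive Poisson(L) crossovers placed
    uniformly (no interference).  Selection, when configured, acts on
    offspring viability: fitness multiplies 1 + s * (favored-allele copies)
    over loci and proposals are accepted by rejection against the maximum.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    N = config.N
    L = config.length_morgans
    grid = np.asarray(grid, dtype=float)
    sel_idx = np.array(
        [int(np.searchsorted(grid, loc.position)) for loc in config.selection_loci],
        dtype=np.int64,
    )
    sel_s = np.array([loc.s for loc in config.selection_loci])
    sel_fav = np.array([loc.favored_ancestry for loc in config.selection_loci], dtype=np.uint8)
    w_max = float(np.prod(1.0 + 2.0 * sel_s)) if sel_s.size else 1.0

    pop = np.zeros((2 * N, grid.size), dtype=np.uint8)
    if config.migration_mode == "pulse":
        n_mig = int(round(config.m * N))
        pop[: 2 * n_mig] = 1
        perm = rng.permutation(N)  # randomize which individuals are migrants
        pop = pop.reshape(N, 2, -1)[perm].reshape(2 * N, -1)

    t = int(round(config.t))
    for _ in range(t):
        new = np.empty_like(pop)
        filled = 0
        while filled < N:
            need = N - filled
            mothers = rng.integers(0, N, need)
            fathers = rng.integers(0, N, need)
            g1 = _make_gametes(pop, mothers, grid, L, rng)
            g2 = _make_gametes(pop, fathers, grid, L, rng)
            if sel_s.size:
                fav_count = (g1[:, sel_idx] == sel_fav).astype(np.int64) + (
                    g2[:, sel_idx] == sel_fav
                )
                w = np.prod(1.0 + sel_s * fav_count, axis=1)
                ok = rng.random(need) < w / w_max
            else:
                ok = np.ones(need, dtype=bool)
            k = int(ok.sum())
            if k:
                new[2 * filled : 2 * (filled + k) : 2] = g1[ok]
                new[2 * filled + 1 : 2 * (filled + k) : 2] = g2[ok]
                filled += k
        pop = new
        if config.migration_mode == "continuous" and config.migration_rate > 0.0:
            n_mig = rng.binomial(N, config.migration_rate)
            if n_mig:
                who = rng.choice(N, n_mig, replace=False)
                pop[2 * who] = 1
                pop[2 * who + 1] = 1

    if config.n_copies > N:
        raise ValueError("population too small for the requested sample")
    who = rng.choice(N, config.n_copies, replace=False)
    homolog = np.arange(config.n_copies) % 2
    return pop[2 * who + homolog].copy()


# ---------------------------------------------------------------------------
# mosaics and reads
# ---------------------------------------------------------------------------


def build_mosaic(
    copy_ancestries: np.ndarray,
    donors0: np.ndarray,
    donors1: np.ndarray,
    rng,
) -> np.ndarray:
    """Allele sequences for admixed chromosome copies.

    ``copy_ancestries`` is (n_copies, S) of 0/1 ancestry labels at the marker
    sites; each maximal same-ancestry run is assigned a distinct held-out
    donor haplotype of that ancestry (no donor reuse within a copy) and the
    donor's alleles are copied onto the run.  Returns (n_copies, S) alleles.
    """
    donors = (np.asarray(donors0), np.asarray(donors1))
    n_copies, S = copy_ancestries.shape
    out = np.empty((n_copies, S), dtype=np.uint8)
    for c in range(n_copies):
        row = copy_ancestries[c]
        change = np.flatnonzero(row[1:] != row[:-1]) + 1
        starts = np.concatenate([[0], change])
        stops = np.concatenate([change, [S]])
        order = [rng.permutation(len(donors[0])), rng.permutation(len(donors[1]))]
        used = [0, 0]
        for a, b in zip(starts, stops):
            anc = int(row[a])
            if used[anc] >= len(order[anc]):
                raise ValueError(
                    f"donor pool for ancestry {anc} exhausted on copy {c}"
                )
            donor = order[anc][used[anc]]
            used[anc] += 1
            out[c, a:b] = donors[anc][donor, a:b]
    return out


def simulate_reads(sample_allele_counts, n: int, mean_depth: float, eps: float, rng):
    """Poisson-depth binomial read counts for one sample.

    Depth r ~ Poisson(mean_depth) per site; A-reads
    rA ~ Binomial(r, (1 - eps) CMA/n + eps (1 - CMA/n)).  Returns an (S, 2)
    array of (reads_A, reads_a).
    """
    cma = np.asarray(sample_allele_counts)
    if cma.min(initial=0) < 0 or cma.max(initial=0) > n:
        raise ValueError("sample allele counts must lie in [0, ploidy]")
    r = rng.poisson(mean_depth, cma.shape)
    p = eps + (1.0 - 2.0 * eps) * cma / n
    rA = rng.binomial(r, p)
    return np.stack([rA, r - rA], axis=1)


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------


@dataclass
class PopulationSim:
    """Simulated admixed chromosomes plus the ancestral variation they carry."""

    config: SimConfig
    panels: PanelSim
    retained: np.ndarray  # mask over candidate sites after preprocessing
    copy_ancestry: np.ndarray  # (n_copies, S_retained) 0/1 labels
    copy_alleles: np.ndarray  # (n_copies, S_retained) 0/1 alleles
    realized_m: float  # ancestry-1 fraction among the sampled copies

    @property
    def pos_bp(self) -> np.ndarray:
        return self.panels.pos_bp[self.retained]

    @property
    def pos_morgans(self) -> np.ndarray:
        return self.panels.pos_morgans[self.retained]


def simulate_population(config: SimConfig, tract_model: str = "forward") -> PopulationSim:
    """Simulate panels, ancestry tracts and mosaic alleles under ``config``.

    ``tract_model`` selects the forward Wright-Fisher simulator ("forward") or
    the iid exponential tract model ("iid"); the latter ignores migration mode
    and selection.
    """
    rng = np.random.default_rng(config.seed)
    panels = simulate_ancestral_panels(
        config.n_candidate_sites,
        (config.panel_size, config.panel_size),
        (config.donor_size, config.donor_size),
        config.sigma_div,
        config.chrom_bp,
        config.length_morgans,
        seed=rng,
    )
    retained = preprocess_panels(
        panels.panel0,
        panels.panel1,
        min_diff=config.min_diff,
        ld_threshold=config.ld_threshold,
        window_cm=config.window_cm,
    )
    marker_pos = panels.pos_morgans[retained]
    if tract_model == "forward":
        # ancestry only needs tracking at the analyzed markers + selected loci
        sel_pos = np.array([l.position for l in config.selection_loci])
        grid = np.union1d(marker_pos, sel_pos) if sel_pos.size else marker_pos
        anc_grid = simulate_admixed_forward(config, grid, seed=rng)
        anc = anc_grid[:, np.searchsorted(grid, marker_pos)]
    elif tract_model == "iid":
        params = DemographicParams(N=config.N, m=config.m, t=config.t)
        tracts = simulate_tracts_iid(params, config.length_morgans, config.n_copies, seed=rng)
        anc = np.stack([ancestry_at(tr, marker_pos) for tr in tracts])
    else:
        raise ValueError(f"unknown tract model {tract_model!r}")
    alleles = build_mosaic(
        anc,
        panels.donors0[:, retained],
        panels.donors1[:, retained],
        rng,
    )
    return PopulationSim(
        config=config,
        panels=panels,
        retained=retained,
        copy_ancestry=anc,
        copy_alleles=alleles,
        realized_m=float(anc.mean()),
    )


def make_read_dataset(
    pop: PopulationSim, ploidy: int, mean_depth: float | None = None, seed=None
):
    """Group the simulated copies into samples of the given ploidy, simulate
    read pileups and assemble the counts Dataset plus the truth state table.

    Returns (dataset, truth) where truth maps sample_id to the (S,) array of
    true population-0 chromosome counts per marker.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    config = pop.config
    if config.n_copies % ploidy:
        raise ValueError("n_copies must be divisible by the sample ploidy")
    depth = float(ploidy if mean_depth is None else mean_depth)
    n_samples = config.n_copies // ploidy
    c0A, c0a = _panel_counts(pop.panels.panel0, pop.retained)
    c1A, c1a = _panel_counts(pop.panels.panel1, pop.retained)
    pos_m = pop.pos_morgans
    dist = np.diff(pos_m, prepend=pos_m[0] if len(pos_m) else 0.0)
    specs = []
    obs = {}
    truth = {}
    for j in range(n_samples):
        copies = slice(j * ploidy, (j + 1) * ploidy)
        cma = pop.copy_alleles[copies].sum(axis=0)
        sid = f"s{j}"
        specs.append(SampleSpec(sid, ploidy, "pileup"))
        obs[sid] = simulate_reads(cma, ploidy, depth, config.eps, rng)
        truth[sid] = (pop.copy_ancestry[copies] == 0).sum(axis=0)
    block = ChromosomeBlock(
        chrom="chr1",
        pos=pop.pos_bp,
        panel0_A=c0A,
        panel0_a=c0a,
        panel1_A=c1A,
        panel1_a=c1a,
        dist_morgans=dist,
        obs=obs,
    )
    return Dataset(chromosomes=[block], samples=specs), truth


def make_genotype_dataset(pop: PopulationSim, ploidy: int):
    """As make_read_dataset but with exactly observed sample genotype counts
    (genotype-mode observations); deterministic given the population."""
    config = pop.config
    if config.n_copies % ploidy:
        raise ValueError("n_copies must be divisible by the sample ploidy")
    n_samples = config.n_copies // ploidy
    c0A, c0a = _panel_counts(pop.panels.panel0, pop.retained)
    c1A, c1a = _panel_counts(pop.panels.panel1, pop.retained)
    pos_m = pop.pos_morgans
    dist = np.diff(pos_m, prepend=pos_m[0] if len(pos_m) else 0.0)
    specs, obs, truth = [], {}, {}
    for j in range(n_samples):
        copies = slice(j * ploidy, (j + 1) * ploidy)
        sid = f"s{j}"
        specs.append(SampleSpec(sid, ploidy, "genotype"))
        obs[sid] = pop.copy_alleles[copies].sum(axis=0).astype(np.int64)
        truth[sid] = (pop.copy_ancestry[copies] == 0).sum(axis=0)
    block = ChromosomeBlock(
        chrom="chr1",
        pos=pop.pos_bp,
        panel0_A=c0A,
        panel0_a=c0a,
        panel1_A=c1A,
        panel1_a=c1a,
        dist_morgans=dist,
        obs=obs,
    )
    return Dataset(chromosomes=[block], samples=specs), truth


def _panel_counts(panel: HaplotypePanel, mask: np.ndarray):
    ones, zeros = panel.allele_counts()
    return ones[mask], zeros[mask]
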