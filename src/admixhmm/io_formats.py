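"""Counts-file, sample-specification and posterior-table input/output.

The counts file is a tab-separated text table with one row per biallelic
marker:

    chrom  pos  panel0_A  panel0_a  panel1_A  panel1_a  dist_morgans  <obs...>

followed, in sample-specification order, by two columns (reads_A, reads_a)
for each pileup-mode sample or one column (CMA, the count of A alleles among
the sample's chromosomes) for each genotype-mode sample.  ``dist_morgans`` is
the recombination distance in Morgans to the previous marker on the same
chromosome; the value on the first marker of a chromosome is ignored.

The sample specification file is tab-separated with three columns:
sample_id, ploidy, mode ("pileup" or "genotype").

Posterior output is tab-separated: chrom, pos, then for each sample one
column per state labelled ``<sample>:<i>`` where i counts population-0
chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_FIXED_COLUMNS = 7


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    ploidy: int
    mode: str = "pileup"

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError(f"ploidy must be >= 1, got {self.ploidy}")
        if self.mode not in ("pileup", "genotype"):
            raise ValueError(f"mode must be 'pileup' or 'genotype', got {self.mode!r}")

    @property
    def n_columns(self) -> int:
        return 2 if self.mode == "pileup" else 1


@dataclass
class ChromosomeBlock:
    """All markers of one chromosome, in increasing position order.

    ``obs`` maps sample_id to an (S, 2) array of (reads_A, reads_a) for pileup
    samples or an (S,) array of CMA counts for genotype samples.  A missing
    pileup observation is encoded as reads_A = reads_a = 0, which yields a
    state-independent emission.
    """

    chrom: str
    pos: np.ndarray
    panel0_A: np.ndarray
    panel0_a: np.ndarray
    panel1_A: np.ndarray
    panel1_a: np.ndarray
    dist_morgans: np.ndarray
    obs: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return len(self.pos)


@dataclass
class Dataset:
    chromosomes: list[ChromosomeBlock]
    samples: list[SampleSpec]

    @property
    def n_markers(self) -> int:
        return sum(b.n_markers for b in self.chromosomes)

    def sample(self, sample_id: str) -> SampleSpec:
        for spec in self.samples:
            if spec.sample_id == sample_id:
                return spec
        raise KeyError(sample_id)


class CountsFormatError(ValueError):
    """Malformed counts file (column count, parse, or ordering problem)."""


def read_sample_specs(path) -> list[SampleSpec]:
    specs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise CountsFormatError(
                    f"{path}:{lineno}: expected 3 columns (sample_id, ploidy, mode)"
                )
            try:
                ploidy = int(fields[1])
            except ValueError as exc:
                raise CountsFormatError(
                    f"{path}:{lineno}: non-integer ploidy {fields[1]!r}"
                ) from exc
            specs.append(SampleSpec(fields[0], ploidy, fields[2]))
    if not specs:
        raise CountsFormatError(f"{path}: no samples defined")
    return specs


def _validate_row(values, lineno, path):
    if min(values[:4]) < 0:
        raise CountsFormatError(f"{path}:{lineno}: negative panel count")
    if values[0] + values[1] < 1 or values[2] + values[3] < 1:
        raise CountsFormatError(f"{path}:{lineno}: empty reference panel at site")


def read_counts_file(path, sample_specs: list[SampleSpec]) -> Dataset:
    """Parse a counts file into a Dataset, enforcing ordering and count
    invariants.  Rows must be grouped by chromosome with strictly increasing
    positions inside each chromosome."""
    expected = _FIXED_COLUMNS + sum(s.n_columns for s in sample_specs)
    rows_by_chrom: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise CountsFormatError(
                    f"{path}:{lineno}: expected {expected} columns, found {len(fields)}"
                )
            chrom = fields[0]
            try:
                pos = int(fields[1])
                panel = [int(x) for x in fields[2:6]]
                dist = float(fields[6])
                obs = [int(x) for x in fields[_FIXED_COLUMNS:]]
            except ValueError as exc:
                raise CountsFormatError(
                    f"{path}:{lineno}: non-numeric field ({exc})"
                ) from exc
            _validate_row(panel, lineno, path)
            if dist < 0:
                raise CountsFormatError(f"{path}:{lineno}: negative distance")
            if min(obs, default=0) < 0:
                raise CountsFormatError(f"{path}:{lineno}: negative observation count")
            block = rows_by_chrom.setdefault(chrom, [])
            if block and pos <= block[-1][0]:
                raise CountsFormatError(
                    f"{path}:{lineno}: position {pos} on {chrom} does not increase"
                )
            block.append((pos, panel, dist, obs))
    if not rows_by_chrom:
        raise CountsFormatError(f"{path}: no data rows")
    chromosomes = []
    for chrom, rows in rows_by_chrom.items():
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        panel = np.array([r[1] for r in rows], dtype=np.int64)
        dist = np.array([r[2] for r in rows], dtype=float)
        obs_flat = np.array([r[3] for r in rows], dtype=np.int64)
        obs = {}
        col = 0
        for spec in sample_specs:
            if spec.mode == "pileup":
                obs[spec.sample_id] = obs_flat[:, col : col + 2]
                col += 2
            else:
                cma = obs_flat[:, col]
                if cma.max(initial=0) > spec.ploidy:
                    raise CountsFormatError(
                        f"{path}: genotype count exceeds ploidy for sample "
                        f"{spec.sample_id} on {chrom}"
                    )
                obs[spec.sample_id] = cma
                col += 1
        chromosomes.append(
            ChromosomeBlock(
                chrom=chrom,
                pos=pos,
                panel0_A=panel[:, 0],
                panel0_a=panel[:, 1],
                panel1_A=panel[:, 2],
                panel1_a=panel[:, 3],
                dist_morgans=dist,
                obs=obs,
            )
        )
    return Dataset(chromosomes=chromosomes, samples=list(sample_specs))


def write_counts_file(dataset: Dataset, path) -> None:
    """Write a Dataset in canonical form (distances as shortest repr floats);
    read_counts_file(write_counts_file(d)) round-trips exactly."""
    with open(path, "w") as fh:
        for block in dataset.chromosomes:
            for s in range(block.n_markers):
                fields = [
                    block.chrom,
                    str(int(block.pos[s])),
                    str(int(block.panel0_A[s])),
                    str(int(block.panel0_a[s])),
                    str(int(block.panel1_A[s])),
                    str(int(block.panel1_a[s])),
                    repr(float(block.dist_morgans[s])),
                ]
                for spec in dataset.samples:
                    o = block.obs[spec.sample_id]
                    if spec.mode == "pileup":
                        fields.extend([str(int(o[s, 0])), str(int(o[s, 1]))])
                    else:
                        fields.append(str(int(o[s])))
                fh.write("\t".join(fields) + "\n")


def write_sample_specs(specs: list[SampleSpec], path) -> None:
    with open(path, "w") as fh:
        for spec in specs:
            fh.write(f"{spec.sample_id}\t{spec.ploidy}\t{spec.mode}\n")


def write_posteriors(posterior_tables: dict, dataset: Dataset, path, tol: float = 1e-6) -> None:
    """Write per-site posterior state distributions for each sample.

    ``posterior_tables`` maps sample_id to a list of (S, n+1) arrays, one per
    chromosome, aligned with ``dataset.chromosomes``.  Every row must sum to 1
    within ``tol``.
    """
    sample_ids = [s.sample_id for s in dataset.samples if s.sample_id in posterior_tables]
    header = ["chrom", "pos"]
    for sid in sample_ids:
        n_states = posterior_tables[sid][0].shape[1]
        header.extend(f"{sid}:{i}" for i in range(n_states))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for ci, block in enumerate(dataset.chromosomes):
            tables = [np.asarray(posterior_tables[sid][ci]) for sid in sample_ids]
            for tab in tables:
                err = np.abs(tab.sum(axis=1) - 1.0).max(initial=0.0)
                if err > tol:
                    raise ValueError(
                        f"posterior rows do not sum to 1 (max deviation {err:.3g})"
                    )
            for s in range(block.n_markers):
                fields = [block.chrom, str(int(block.pos[s]))]
                for tab in tables:
                    fields.extend(f"{v:.6f}" for v in tab[s])
                fh.write("\t".join(fields) + "\n")


def read_posteriors(path):
    """Read a posterior table written by write_posteriors.

    Returns (chrom array, pos array, {sample_id: (S, n+1) array}).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    sample_cols: dict[str, list[str]] = {}
    for col in df.columns[2:]:
        sid = col.rsplit(":", 1)[0]
        sample_cols.setdefault(sid, []).append(col)
    tables = {sid: df[cols].to_numpy() for sid, cols in sample_cols.items()}
    return df["chrom"].to_numpy(), df["pos"].to_numpy(), tables
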