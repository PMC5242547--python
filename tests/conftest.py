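import numpy as np
import pytest

from admixhmm import ChromosomeBlock, Dataset, SampleSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dataset(rng, n_markers=4, samples=None, max_panel=4, max_depth=4):
    """A small random but valid dataset for oracle comparisons."""
    if samples is None:
        samples = [SampleSpec("a", 2, "pileup")]
    pos = np.sort(rng.choice(np.arange(1, 10_000), n_markers, replace=False))
    C0 = rng.integers(1, max_panel + 1, n_markers)
    C1 = rng.integers(1, max_panel + 1, n_markers)
    C0A = rng.integers(0, C0 + 1)
    C1A = rng.integers(0, C1 + 1)
    obs = {}
    for spec in samples:
        if spec.mode == "pileup":
            r = rng.integers(0, max_depth + 1, n_markers)
            rA = rng.integers(0, r + 1)
            obs[spec.sample_id] = np.stack([rA, r - rA], axis=1)
        else:
            obs[spec.sample_id] = rng.integers(0, spec.ploidy + 1, n_markers)
    block = ChromosomeBlock(
        chrom="chr1",
        pos=pos,
        panel0_A=C0A,
        panel0_a=C0 - C0A,
        panel1_A=C1A,
        panel1_a=C1 - C1A,
        dist_morgans=np.concatenate([[0.0], rng.uniform(0.001, 0.05, n_markers - 1)]),
        obs=obs,
    )
    return Dataset(chromosomes=[block], samples=samples)
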