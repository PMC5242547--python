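"""Emission model tests: worked values, numerical-integration oracles,
normalization, and equivalence of the scalar and vectorized routes."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom

from admixhmm import (
    ancestry_read_split,
    component_emission,
    emission_log_table,
    genotype_emission,
    pileup_emission,
)
from admixhmm.emissions import ErrorModel


def comp_oracle(r0, r0A, C, CA, ieff, eps):
    """Numerical integration of the defining construction: panel counts and
    latent sample counts binomial in the frequency, flat prior, error-tilted
    read draw."""
    if ieff == 0:
        return (1.0 / (C + 1)) if r0 == 0 else 0.0

    def integrand(f):
        tot = 0.0
        for k in range(ieff + 1):
            p = eps + (1 - 2 * eps) * k / ieff
            tot += binom.pmf(r0A, r0, p) * binom.pmf(k, ieff, f)
        return tot * binom.pmf(CA, C, f)

    return quad(integrand, 0, 1, limit=200)[0]


def pileup_oracle(rA, r, C0, C0A, C1, C1A, n, i, eps):
    """Full constructive sum over the read ancestry split with per-ancestry
    numerically integrated components."""
    total = 0.0
    for r0 in range(r + 1):
        w = binom.pmf(r0, r, i / n)
        if w == 0.0:
            continue
        r1 = r - r0
        for r0A in range(max(0, rA - r1), min(r0, rA) + 1):
            total += (
                w
                * comp_oracle(r0, r0A, C0, C0A, i, eps)
                * comp_oracle(r1, rA - r0A, C1, C1A, n - i, eps)
            )
    return total


def genotype_oracle(CMA, C0, C0A, C1, C1A, n, i):
    """Separable double integral over (f0, f1) of the defining model."""

    def one(C, CA, M, x):
        return quad(
            lambda f: binom.pmf(CA, C, f) * binom.pmf(x, M, f), 0, 1, limit=200
        )[0]

    tot = 0.0
    for cm0a in range(0, i + 1):
        cm1a = CMA - cm0a
        if not 0 <= cm1a <= n - i:
            continue
        tot += one(C0, C0A, i, cm0a) * one(C1, C1A, n - i, cm1a)
    return tot


class TestAncestryReadSplit:
    def test_state_equal_ploidy_forces_all_reads(self):
        assert ancestry_read_split(3, 2, 2)[3] == pytest.approx(1.0)

    def test_even_split_binomial(self):
        np.testing.assert_allclose(ancestry_read_split(2, 2, 1), [0.25, 0.5, 0.25])

    @pytest.mark.parametrize("r,n,i", [(0, 1, 0), (4, 3, 2), (5, 2, 0), (6, 4, 4)])
    def test_normalized(self, r, n, i):
        assert ancestry_read_split(r, n, i).sum() == pytest.approx(1.0)


class TestComponentEmission:
    def test_worked_values(self):
        assert component_emission(1, 1, 1, 1, 1, 0.0) == pytest.approx(1 / 3)
        assert component_emission(0, 0, 1, 1, 1, 0.0) == pytest.approx(1 / 2)
        # no chromosomes of this ancestry: flat beta-binomial over the panel
        assert component_emission(0, 0, 3, 2, 0, 0.0) == pytest.approx(1 / 4)
        assert component_emission(2, 1, 3, 2, 0, 0.1) == 0.0

    def test_matches_integration_oracle(self, rng):
        for _ in range(40):
            C = int(rng.integers(1, 5))
            CA = int(rng.integers(0, C + 1))
            ieff = int(rng.integers(0, 4))
            r0 = int(rng.integers(0, 5)) if ieff else 0
            r0A = int(rng.integers(0, r0 + 1))
            eps = float(rng.uniform(0, 0.3))
            got = component_emission(r0, r0A, C, CA, ieff, eps)
            want = comp_oracle(r0, r0A, C, CA, ieff, eps)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-14)


class TestGenotypeEmission:
    def test_worked_value(self):
        assert genotype_emission(1, 1, 1, 1, 0, 1, 1) == pytest.approx(1 / 6)

    def test_matches_integration_oracle(self, rng):
        for _ in range(30):
            C0 = int(rng.integers(1, 5))
            C1 = int(rng.integers(1, 5))
            C0A = int(rng.integers(0, C0 + 1))
            C1A = int(rng.integers(0, C1 + 1))
            n = int(rng.integers(1, 5))
            i = int(rng.integers(0, n + 1))
            CMA = int(rng.integers(0, n + 1))
            got = genotype_emission(CMA, C0, C0A, C1, C1A, n, i)
            want = genotype_oracle(CMA, C0, C0A, C1, C1A, n, i)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-14)

    def test_population_label_swap_symmetry(self, rng):
        for _ in range(10):
            C0, C1 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            C0A, C1A = int(rng.integers(0, C0 + 1)), int(rng.integers(0, C1 + 1))
            n = int(rng.integers(1, 4))
            i = int(rng.integers(0, n + 1))
            CMA = int(rng.integers(0, n + 1))
            a = genotype_emission(CMA, C0, C0A, C1, C1A, n, i)
            b = genotype_emission(CMA, C1, C1A, C0, C0A, n, n - i)
            assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("n,C0,C1", [(1, 2, 3), (3, 4, 2), (4, 1, 1)])
    def test_total_probability(self, n, C0, C1):
        for i in range(n + 1):
            tot = sum(
                genotype_emission(CMA, C0, C0A, C1, C1A, n, i)
                for CMA in range(n + 1)
                for C0A in range(C0 + 1)
                for C1A in range(C1 + 1)
            )
            assert tot == pytest.approx(1.0, abs=1e-10)


class TestPileupEmission:
    def test_no_reads_is_state_uninformative(self):
        vals = [pileup_emission(0, 0, 3, 2, 2, 1, 2, i, 0.01) for i in range(3)]
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])
        # equals the product of flat beta-binomial panel terms
        assert vals[0] == pytest.approx((1 / 4) * (1 / 3))

    def test_factorization_example(self):
        # n=1, i=1: population-1 contributes only its panel term 1/(C1+1)
        for C1, C1A in [(1, 0), (2, 1), (3, 3)]:
            got = pileup_emission(1, 1, 1, 1, C1, C1A, 1, 1, 0.0)
            assert got == pytest.approx((1 / 3) * (1 / (C1 + 1)), rel=1e-12)

    @pytest.mark.parametrize("r,C0,C1,n", [(2, 2, 2, 1), (3, 2, 3, 2), (4, 4, 4, 3)])
    def test_total_probability(self, r, C0, C1, n):
        for i in range(n + 1):
            tot = sum(
                pileup_emission(rA, r, C0, C0A, C1, C1A, n, i, 0.07)
                for rA in range(r + 1)
                for C0A in range(C0 + 1)
                for C1A in range(C1 + 1)
            )
            assert tot == pytest.approx(1.0, abs=1e-10)

    def test_matches_integration_oracle(self, rng):
        for _ in range(30):
            C0, C1 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            C0A, C1A = int(rng.integers(0, C0 + 1)), int(rng.integers(0, C1 + 1))
            n = int(rng.integers(1, 5))
            i = int(rng.integers(0, n + 1))
            r = int(rng.integers(0, 5))
            rA = int(rng.integers(0, r + 1))
            eps = float(rng.uniform(0, 0.3))
            got = pileup_emission(rA, r, C0, C0A, C1, C1A, n, i, eps)
            want = pileup_oracle(rA, r, C0, C0A, C1, C1A, n, i, eps)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-14)

    def test_error_rate_shrinks_discrimination(self):
        # fixed, fully informative panel; an all-A pileup favors state n
        ratios = []
        for eps in (0.0, 0.05, 0.15, 0.3):
            e_n = pileup_emission(4, 4, 4, 4, 4, 0, 2, 2, eps)
            e_0 = pileup_emission(4, 4, 4, 4, 4, 0, 2, 0, eps)
            ratios.append(e_n / e_0)
        assert all(a > b >= 1.0 for a, b in zip(ratios, ratios[1:]))


class TestEmissionTable:
    def test_matches_scalar_reference_exhaustively(self):
        """The vectorized latent-count route equals the explicit read-split
        sums everywhere on a small grid of instances."""
        eps = 0.013
        for C0, C1, n in [(1, 2, 1), (2, 2, 2), (3, 1, 3)]:
            cases = list(
                itertools.product(
                    range(C0 + 1), range(C1 + 1), range(4)
                )
            )
            for C0A, C1A, r in cases:
                for rA in range(r + 1):
                    tab = emission_log_table(
                        np.array([C0A]),
                        np.array([C0 - C0A]),
                        np.array([C1A]),
                        np.array([C1 - C1A]),
                        n,
                        "pileup",
                        np.array([[rA, r - rA]]),
                        eps,
                    )
                    for i in range(n + 1):
                        ref = pileup_emission(rA, r, C0, C0A, C1, C1A, n, i, eps)
                        assert np.exp(tab[0, i]) == pytest.approx(ref, rel=1e-10)

    def test_genotype_mode_matches_scalar(self, rng):
        for _ in range(20):
            C0, C1 = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            C0A, C1A = int(rng.integers(0, C0 + 1)), int(rng.integers(0, C1 + 1))
            n = int(rng.integers(1, 5))
            CMA = int(rng.integers(0, n + 1))
            tab = emission_log_table(
                np.array([C0A]),
                np.array([C0 - C0A]),
                np.array([C1A]),
                np.array([C1 - C1A]),
                n,
                "genotype",
                np.array([CMA]),
            )
            for i in range(n + 1):
                ref = genotype_emission(CMA, C0, C0A, C1, C1A, n, i)
                assert np.exp(tab[0, i]) == pytest.approx(ref, rel=1e-10)

    def test_large_panels_do_not_overflow(self):
        tab = emission_log_table(
            np.array([480]),
            np.array([20]),
            np.array([30]),
            np.array([470]),
            4,
            "pileup",
            np.array([[7, 1]]),
            0.01,
        )
        assert np.all(np.isfinite(tab))
        # strongly A-skewed panel 0 and A-heavy reads: more population-0
        # chromosomes must be more likely
        assert tab[0, 4] > tab[0, 0]


class TestErrorModel:
    def test_bounds(self):
        ErrorModel(0.0)
        ErrorModel(0.49)
        with pytest.raises(ValueError):
            ErrorModel(0.5)
        with pytest.raises(ValueError):
            ErrorModel(-0.01)
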