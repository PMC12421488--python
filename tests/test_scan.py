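import math

import numpy as np
import pytest

from urbanpurge.genotypes import MISSING
from urbanpurge.scan import (
    pbs,
    pi_from_counts,
    site_fst_components,
    tajima_constants,
    tajimas_d,
    window_fst,
    window_scan,
)

from conftest import make_matrix, random_matrix


class TestSiteFst:
    def test_fixed_difference(self):
        num, den = site_fst_components(1.0, 10, 0.0, 10)
        assert num == pytest.approx(1.0) and den == pytest.approx(1.0)

    def test_symmetric_intermediate(self):
        num, den = site_fst_components(0.5, 10, 0.5, 10)
        assert num == pytest.approx(-1 / 18)
        assert den == pytest.approx(0.5)

    def test_hand_example(self):
        num, den = site_fst_components(0.5, 10, 0.2, 10)
        assert num == pytest.approx(0.044444, abs=1e-6)
        assert den == pytest.approx(0.5)
        assert num / den == pytest.approx(0.088889, abs=1e-6)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            site_fst_components(0.5, 1, 0.5, 10)


class TestPi:
    def test_toy_window(self):
        # 10 called sites, one SNP at derived count 1 of 4 alleles
        assert pi_from_counts([1], [4], 10) == pytest.approx(0.05)

    def test_monomorphic_contributes_zero(self):
        assert pi_from_counts([0, 4], [4, 4], 5) == pytest.approx(0.0)


class TestTajimasD:
    def test_constants_against_independent_formulas(self):
        """Oracle: re-derive the Tajima normalising constants through
        an independent symbolic-style evaluation."""
        from fractions import Fraction

        n = 7
        a1 = sum(Fraction(1, i) for i in range(1, n))
        a2 = sum(Fraction(1, i * i) for i in range(1, n))
        b1 = Fraction(n + 1, 3 * (n - 1))
        b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
        k = tajima_constants(n)
        assert k["a1"] == pytest.approx(float(a1))
        assert k["e1"] == pytest.approx(float(c1 / a1))
        assert k["e2"] == pytest.approx(float(c2 / (a1**2 + a2)))

    def test_worked_example(self):
        # n=4 haplotypes, 3 SNPs at derived counts {1,2,1}
        pi_hat = sum(2 * i * (4 - i) / (4 * 3) for i in (1, 2, 1))
        assert pi_hat == pytest.approx(5 / 3)
        d = tajimas_d(4, 3, pi_hat)
        assert d == pytest.approx(0.168, abs=5e-4)

    def test_no_snps_is_undefined(self):
        assert math.isnan(tajimas_d(10, 0, 0.0))


class TestPbs:
    def test_zero(self):
        assert pbs(0.0, 0.0, 0.0) == pytest.approx(0.0)

    def test_worked_examples(self):
        assert pbs(0.2, 0.2, 0.05) == pytest.approx(0.19750, abs=1e-5)
        assert pbs(0.2, 0.2, 0.2) == pytest.approx(0.111572, abs=1e-6)

    def test_negative_fst_clamped(self):
        assert pbs(-0.3, 0.0, 0.0) == pytest.approx(0.0)

    def test_fst_one_is_finite(self):
        assert np.isfinite(pbs(1.0, 0.0, 0.0))

    def test_nan_propagates(self):
        assert math.isnan(pbs(float("nan"), 0.1, 0.1))


def brute_force_window_fst(gm, pop_a, pop_b):
    """Independent per-site loop implementation of ratio-of-sums FST."""
    ia = [k for k, p in enumerate(gm.pop) if p == pop_a]
    ib = [k for k, p in enumerate(gm.pop) if p == pop_b]
    s_num = s_den = 0.0
    for s in range(gm.n_sites):
        da = na = db = nb = 0
        for k in ia:
            g = gm.genotypes[s, k]
            if g != MISSING:
                da += int(g)
                na += 2
        for k in ib:
            g = gm.genotypes[s, k]
            if g != MISSING:
                db += int(g)
                nb += 2
        if na < 2 or nb < 2:
            continue
        p1, p2 = da / na, db / nb
        s_num += (p1 - p2) ** 2 - p1 * (1 - p1) / (na - 1) - p2 * (1 - p2) / (nb - 1)
        s_den += p1 * (1 - p2) + p2 * (1 - p1)
    return s_num / s_den if s_den > 0 else float("nan")


class TestWindowScan:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for rep in range(5):
            gm = random_matrix(rng, n_sites=200, n_ind=14, missing_frac=0.15)
            got = window_fst(gm, "urban", "rural")
            want = brute_force_window_fst(gm, "urban", "rural")
            assert got == pytest.approx(want, abs=1e-12)

    def test_all_monomorphic_window(self):
        g = np.zeros((5, 6), dtype=np.int8)
        gm = make_matrix(g, pop=["urban"] * 3 + ["rural"] * 3, chrom_length=100)
        df = window_scan(gm, ["urban", "rural"], window_bp=100, step_bp=100)
        assert len(df) == 1
        row = df.iloc[0]
        assert row.pi == pytest.approx(0.0)
        assert math.isnan(row.tajd)
        assert row.fst_num == pytest.approx(0.0) and row.fst_den == pytest.approx(0.0)

    def test_empty_windows_are_emitted(self):
        g = np.array([[1, 0, 1, 0]], dtype=np.int8)
        gm = make_matrix(
            g, pop=["urban", "urban", "rural", "rural"], pos=[5], chrom_length=300
        )
        df = window_scan(gm, ["urban", "rural"], window_bp=100, step_bp=100)
        assert len(df) == 3
        assert df.iloc[1].n_snps == 0 and df.iloc[2].n_snps == 0

    def test_haploid_mode_equals_diploid_on_homozygotes(self, rng):
        g_hap = rng.integers(0, 2, size=(100, 10)).astype(np.int8)
        gm_dip = make_matrix(
            (2 * g_hap).astype(np.int8),
            pop=["urban"] * 5 + ["rural"] * 5,
            chrom_length=1000,
        )
        gm_hapm = make_matrix(
            g_hap, pop=["urban"] * 5 + ["rural"] * 5, ploidy=1, chrom_length=1000
        )
        d_dip = window_scan(gm_dip, ["urban", "rural"], 1000, 1000, ploidy=1)
        d_hap = window_scan(gm_hapm, ["urban", "rural"], 1000, 1000, ploidy=1)
        assert d_dip.iloc[0].fst == pytest.approx(d_hap.iloc[0].fst, abs=1e-12)
        assert d_dip.iloc[0].pi == pytest.approx(d_hap.iloc[0].pi, abs=1e-12)

    def test_three_groups_adds_pbs(self, rng):
        g = rng.integers(0, 3, size=(60, 9)).astype(np.int8)
        gm = make_matrix(
            g, pop=["urban"] * 3 + ["rural"] * 3 + ["outgroup"] * 3, chrom_length=600
        )
        df = window_scan(gm, ["urban", "rural", "outgroup"], 600, 600)
        assert np.isfinite(df.iloc[0].pbs)

    def test_windows_are_half_open(self, rng):
        g = np.array([[1, 0], [1, 0]], dtype=np.int8)
        gm = make_matrix(g, pop=["urban", "urban"], pos=[99, 100], chrom_length=200)
        df = window_scan(gm, ["urban", "urban"], window_bp=100, step_bp=100)
        assert df.iloc[0].n_snps == 1  # pos 99 in [0,100), pos 100 in [100,200)
        assert df.iloc[1].n_snps == 1
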