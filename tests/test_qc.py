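import numpy as np
import pytest

from urbanpurge.genotypes import MISSING
from urbanpurge.qc import (
    KinshipUndefinedError,
    cohort_inbreeding,
    inbreeding_f,
    king_kinship,
    pairwise_kinship,
    prune_related,
)

from conftest import make_matrix


class TestKingKinship:
    def test_self_comparison_is_half(self, rng):
        g = rng.integers(0, 3, size=(200, 1)).astype(np.int8)
        gm = make_matrix(np.hstack([g, g]), pop=["pop0", "pop0"])
        k = king_kinship(gm, 0, 1)
        assert k.phi == pytest.approx(0.5)
        assert k.r == pytest.approx(1.0)

    def test_count_arithmetic_example(self):
        # 4 double-het sites, 1 opposite-homozygote site, het totals 6 and 5
        gi = np.array([1, 1, 1, 1, 0, 1, 1, 0, 2], dtype=np.int8)
        gj = np.array([1, 1, 1, 1, 2, 0, 0, 1, 2], dtype=np.int8)
        gm = make_matrix(np.column_stack([gi, gj]))
        k = king_kinship(gm, 0, 1)
        assert (gi == 1).sum() + (gj == 1).sum() == 11
        assert k.phi == pytest.approx((4 - 2) / 11)

    def test_symmetry(self, rng):
        g = rng.integers(0, 3, size=(300, 4)).astype(np.int8)
        gm = make_matrix(g)
        assert king_kinship(gm, 1, 3).phi == pytest.approx(king_kinship(gm, 3, 1).phi)

    def test_missing_sites_excluded(self):
        gi = np.array([1, MISSING, 1], dtype=np.int8)
        gj = np.array([1, 1, MISSING], dtype=np.int8)
        k = king_kinship(make_matrix(np.column_stack([gi, gj])), 0, 1)
        assert k.n_sites == 1 and k.phi == pytest.approx(0.5)

    def test_no_heterozygotes_raises(self):
        g = np.array([[0, 0], [2, 2]], dtype=np.int8)
        with pytest.raises(KinshipUndefinedError):
            king_kinship(make_matrix(g), 0, 1)

    def test_unrelated_individuals_near_zero(self, rng):
        """Exchangeable unrelated genomes: mean phi within [-0.02, 0.02]."""
        n_pairs, n_sites = 100, 5000
        p = rng.beta(0.5, 0.5, n_sites).clip(0.05, 0.95)
        phis = []
        for _ in range(n_pairs):
            g = (rng.random((n_sites, 2, 2)) < p[:, None, None]).sum(2).astype(np.int8)
            gm = make_matrix(g)
            phis.append(king_kinship(gm, 0, 1).phi)
        assert abs(np.mean(phis)) < 0.02


class TestPruneRelated:
    @staticmethod
    def _kin(rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["id_i", "id_j", "phi", "r"])

    def test_no_flagged_pairs_keeps_all(self):
        kin = self._kin([("A", "B", 0.01, 0.02)])
        assert prune_related(kin, {"A": 10, "B": 5}) == ["A", "B"]

    def test_lower_coverage_member_removed(self):
        kin = self._kin([("A", "B", 0.3, 0.6)])
        assert prune_related(kin, {"A": 10, "B": 5}) == ["A"]

    def test_triangle_greedy_trace(self):
        """A-B and B-C flagged, coverage A > B > C: removing B resolves
        both pairs against the current kept set, so C is retained."""
        kin = self._kin([("A", "B", 0.3, 0.6), ("B", "C", 0.3, 0.6)])
        kept = prune_related(kin, {"A": 10, "B": 5, "C": 1})
        assert kept == ["A", "C"]

    def test_both_thresholds_must_exceed(self):
        kin = self._kin([("A", "B", 0.3, 0.2)])  # r below 0.25
        assert prune_related(kin, {"A": 1, "B": 2}) == ["A", "B"]

    def test_theta_only_rule_flags_superset(self):
        kin = self._kin([("A", "B", 0.10, 0.20), ("C", "D", 0.3, 0.6)])
        default = prune_related(kin, {k: ord(k) for k in "ABCD"})
        loose = prune_related(
            kin, {k: ord(k) for k in "ABCD"}, theta_thr=0.0884, r_thr=None
        )
        assert set(loose) <= set(default)

    def test_missing_coverage_raises(self):
        kin = self._kin([("A", "B", 0.3, 0.6)])
        with pytest.raises(ValueError):
            prune_related(kin, {"A": 1})


class TestInbreeding:
    def test_direct_arithmetic(self):
        # 30 observed hets, expected 50 -> F = 0.4
        n_sites = 100
        g = np.zeros((n_sites, 2), dtype=np.int8)
        g[:30, 0] = 1
        p = np.full(n_sites, 0.5)  # expected het 2*0.25*100 = 50
        f = inbreeding_f(make_matrix(g), 0, freqs=p)
        assert f.f_hat == pytest.approx(1 - 30 / 50)
        g2 = g.copy()
        g2[:, 0] = 0
        g2[:30, 0] = 1
        assert inbreeding_f(make_matrix(g2), 0, freqs=p).f_hat == pytest.approx(0.4)

    def test_outbred_individual_near_zero(self, rng):
        n_sites = 10_000
        p = rng.uniform(0.1, 0.9, n_sites)
        g = (rng.random((n_sites, 10, 2)) < p[:, None, None]).sum(2).astype(np.int8)
        gm = make_matrix(g)
        f = inbreeding_f(gm, 0, freqs=p)
        assert abs(f.f_hat) < 0.05

    def test_zero_expected_het_raises(self):
        g = np.zeros((5, 2), dtype=np.int8)
        with pytest.raises(ValueError):
            inbreeding_f(make_matrix(g), 0, freqs=np.zeros(5))

    def test_cohort_frame_shape(self, rng):
        g = rng.integers(0, 3, size=(500, 6)).astype(np.int8)
        gm = make_matrix(g, pop=["urban"] * 3 + ["rural"] * 3)
        df = cohort_inbreeding(gm, "urban")
        assert len(df) == 3 and set(df.columns) >= {"id", "f_hat", "n_sites"}


def test_pairwise_kinship_covers_all_pairs(rng):
    g = rng.integers(0, 3, size=(100, 5)).astype(np.int8)
    df = pairwise_kinship(make_matrix(g))
    assert len(df) == 10
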