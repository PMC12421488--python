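import collections

import numpy as np
import pytest
from scipy import stats

from urbanpurge.model import DemographicModel, EffectDFE, make_scenario
from urbanpurge.scan import window_fst
from urbanpurge.simulate import (
    WrightFisherEngine,
    load_cohort_model,
    selfing_rate,
    simulate_im,
    simulate_load_cohort,
    simulate_windows,
)


def small_model(**kw):
    base = dict(
        n_anc=100,
        n_urban=30,
        n_rural=100,
        t_split=20,
        mu=5e-6,
        window_length=20_000,
        m_ur=0.05,
        m_ru=0.01,
    )
    base.update(kw)
    return DemographicModel(**base)


class TestDeterminism:
    def test_identical_model_seed_identical_output(self):
        m = small_model(seed=42)
        a = simulate_im(m, 10, 10)
        b = simulate_im(m, 10, 10)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.pos, b.pos)

    def test_different_seeds_differ(self):
        a = simulate_im(small_model(seed=1), 10, 10)
        b = simulate_im(small_model(seed=2), 10, 10)
        assert a.n_sites != b.n_sites or not np.array_equal(a.genotypes, b.genotypes)


class TestEngineDynamics:
    def test_heterozygosity_decay_matches_wright_fisher(self):
        """With mu = 0 and no migration, E[H_t] = H_0 (1 - 1/2N)^t."""
        N, T, M = 50, 30, 2000
        rng = np.random.default_rng(0)
        eng = WrightFisherEngine(10**7, 0.0, rng, linked=False)
        eng._prune = lambda: None  # keep lost/fixed sites in the average
        eng.init_sites(
            np.arange(M), np.full(M, "intergenic", dtype=object), np.ones(M), np.ones(M)
        )
        haps = (rng.random((2 * N, M)) < 0.5).astype(np.uint8)
        eng.add_population("d", haps, selfing=0.0)
        q0 = haps.mean(axis=0)
        h0 = float((2 * q0 * (1 - q0)).mean())
        for _ in range(T):
            eng.generation({"d": (N, [("d", 1.0)])})
        q = eng.haps["d"].mean(axis=0)
        h_t = float((2 * q * (1 - q)).mean())
        expected = h0 * (1 - 1 / (2 * N)) ** T
        assert h_t == pytest.approx(expected, rel=0.08)

    def test_realized_inbreeding_matches_target(self):
        """Partial selfing at sigma = 2f/(1+f) gives equilibrium F = f."""
        N, T, M, f = 150, 40, 3000, 0.3
        rng = np.random.default_rng(3)
        eng = WrightFisherEngine(10**7, 0.0, rng, linked=False)
        eng._prune = lambda: None
        eng.init_sites(
            np.arange(M), np.full(M, "intergenic", dtype=object), np.ones(M), np.ones(M)
        )
        haps = (rng.random((2 * N, M)) < 0.5).astype(np.uint8)
        eng.add_population("d", haps, selfing=selfing_rate(f))
        for _ in range(T):
            eng.generation({"d": (N, [("d", 1.0)])})
        H = eng.haps["d"]
        q = H.mean(axis=0)
        het = (H[0::2] != H[1::2]).mean(axis=0)
        mask = (q > 0.05) & (q < 0.95)
        f_hat = 1 - het[mask].sum() / (2 * q[mask] * (1 - q[mask])).sum()
        assert f_hat == pytest.approx(f, abs=0.05)


class TestScenarios:
    def test_complete_isolation_reaches_high_fst(self):
        """m = 0 and a deep split drive windowed FST toward 1."""
        m = small_model(
            n_anc=30, n_urban=20, n_rural=20, t_split=250, m_ur=0.0, m_ru=0.0, mu=2e-5
        )
        vals = [
            window_fst(simulate_im(m, 10, 10, seed=s), "urban", "rural")
            for s in range(25)
        ]
        assert np.nanmean(vals) > 0.9

    def test_no_split_no_differentiation(self):
        m = small_model(t_split=0, mu=2e-5)
        vals = [
            window_fst(simulate_im(m, 15, 15, seed=s), "urban", "rural")
            for s in range(40)
        ]
        assert abs(np.nanmean(vals)) < 0.03

    def test_sweep_fixes_focal_allele_in_urban_sample(self):
        m = make_scenario(small_model(seed=5), "sweep")
        gm = simulate_im(m, 10, 10)
        assert gm.focal_freq_urban == 1.0

    def test_sweep_reduces_urban_diversity(self):
        """Hitchhiking: urban sample heterozygosity collapses under s=1."""
        neutral_pi, sweep_pi = [], []
        for s in range(8):
            for kind, acc in (("neutral", neutral_pi), ("sweep", sweep_pi)):
                m = make_scenario(small_model(), kind)
                gm = simulate_im(m, 10, 10, seed=s)
                u = np.flatnonzero(gm.pop == "urban")
                d, n = gm.derived_counts(u)
                poly = (d > 0) & (d < n)
                acc.append(
                    float((2 * d[poly] * (n[poly] - d[poly]) / (n[poly] * (n[poly] - 1))).sum())
                )
        p = stats.mannwhitneyu(sweep_pi, neutral_pi, alternative="less").pvalue
        assert p < 0.01

    def test_sample_size_validation(self):
        with pytest.raises(ValueError):
            simulate_im(small_model(), n_sample_urban=100)


class TestLoadCohort:
    def test_category_proportions_match_dfe(self):
        dfe = EffectDFE().neutral()  # label-only, no selection thinning
        m = load_cohort_model(window_length=2_000_000, seed=11)
        gm = simulate_load_cohort(m, dfe, n_sample_urban=20, n_sample_rural=10)
        counts = collections.Counter(gm.effect)
        total = gm.n_sites
        observed = [counts[c] for c in dfe.categories]
        expected = [dfe.proportions[c] * total for c in dfe.categories]
        chi = stats.chisquare(observed, expected)
        assert chi.pvalue > 1e-4  # multinomial labelling

    def test_neutral_dfe_spectra_indistinguishable(self):
        """With all s = 0, category-conditional spectra share one shape."""
        dfe = EffectDFE().neutral()
        m = load_cohort_model(window_length=2_000_000)
        pooled = {c: np.zeros(3) for c in ("intergenic", "high")}
        for s in range(4):
            gm = simulate_load_cohort(m, dfe, 20, 10, seed=s)
            d, n = gm.derived_counts()
            frac = d / n
            bins = np.digitize(frac, [0.1, 0.5])
            for c in pooled:
                sel = gm.effect == c
                for b in range(3):
                    pooled[c][b] += ((bins == b) & sel).sum()
        table = np.array([pooled["intergenic"], pooled["high"]])
        p = stats.chi2_contingency(table).pvalue
        assert p > 0.01

    def test_effect_labels_consumed_downstream(self):
        gm = simulate_load_cohort(
            load_cohort_model(window_length=1_000_000), n_sample_urban=20,
            n_sample_rural=10, seed=2
        )
        assert set(gm.effect) <= {"intergenic", "low", "moderate", "high"}
        assert gm.n_sites > 100


def test_simulate_windows_labels_chromosomes():
    m = small_model()
    wins = simulate_windows(m, 3, 8, 8, seed=1)
    assert [next(iter(w.chrom_lengths)) for w in wins] == ["w0000", "w0001", "w0002"]
    assert all(w.n_individuals == 16 for w in wins)
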