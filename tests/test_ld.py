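import numpy as np
import pytest

from ldne import (LDConfig, composite_pair_ld, correct_for_sampling,
                  inbreeding_coefficient, recombination_fraction,
                  summarize_ld)

from conftest import make_matrix


class TestCompositePairLD:
    def test_identical_vectors_give_d2_equal_w(self):
        # perfect association with maximal homozygote excess: D^2 = W
        x = np.array([0, 2] * 20, dtype=float)
        p = composite_pair_ld(x, x)
        assert p.D2 == pytest.approx(p.W, rel=1e-12)

    def test_hwe_perfect_association(self):
        # random-union-of-gametes genotypes at two fully linked loci
        rng = np.random.default_rng(1)
        a, b = rng.integers(0, 2, 4000), rng.integers(0, 2, 4000)
        x = (a + b).astype(float)
        p = composite_pair_ld(x, x)
        # composite covariance = var includes the heterozygote term, so
        # D2/W = (1 + ~0)..; here D2/W -> 1 only via sampling correction path
        assert p.D2 / p.W == pytest.approx(1.0, rel=0.15)

    def test_constant_locus_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            composite_pair_ld(np.ones(10), np.arange(10, dtype=float))

    def test_missing_entries_use_shared_individuals(self):
        x = np.array([0, 1, 2, np.nan, 1, 0, 2, 1])
        y = np.array([0, 1, 2, 1, np.nan, 0, 2, 1])
        ok = ~(np.isnan(x) | np.isnan(y))
        p = composite_pair_ld(x, y)
        q = composite_pair_ld(x[ok], y[ok])
        assert p.D2 == pytest.approx(q.D2) and p.W == pytest.approx(q.W)


class TestSamplingCorrection:
    def test_permutation_oracle_mean_zero(self):
        """Corrected delta^2 between independent loci averages to zero."""
        rng = np.random.default_rng(7)
        n, reps = 100, 4000
        x = rng.binomial(2, 0.3, n).astype(float)
        num = w = 0.0
        for _ in range(reps):
            y = rng.permutation(rng.binomial(2, 0.45, n)).astype(float)
            p = composite_pair_ld(x, y)
            num += correct_for_sampling(p.D2, p.W, n)
            w += p.W
        vals = num / w
        # null per-pair SD of D2/W is ~sqrt(2)/(n-1); 3 SE over reps
        se = np.sqrt(2.0) / (n - 1) / np.sqrt(reps)
        assert abs(vals) < 3 * se

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            correct_for_sampling(0.1, 0.01, 3)

    def test_large_n_limit_is_raw_ratio(self):
        assert correct_for_sampling(0.02, 0.05, 10**9) == \
            pytest.approx(0.02, rel=1e-6)

    def test_perfect_association_near_one(self):
        n = 200
        x = np.array([0, 2] * (n // 2), dtype=float)
        p = composite_pair_ld(x, x)
        d2 = correct_for_sampling(p.D2, p.W, n) / p.W
        assert d2 == pytest.approx(1.0, abs=2.0 / n)


class TestRecombinationFraction:
    def test_different_chromosomes(self):
        assert recombination_fraction(123.0, same_chromosome=False) == 0.5

    def test_zero_distance(self):
        assert recombination_fraction(0.0) == 0.0

    def test_haldane_50cM(self):
        assert recombination_fraction(50.0) == \
            pytest.approx((1 - np.exp(-1)) / 2, abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            recombination_fraction(-1.0)


class TestInbreedingCoefficient:
    def test_all_heterozygous(self):
        g = make_matrix(np.ones((50, 20), dtype=int))
        f = inbreeding_coefficient(g)
        # the small-sample-unbiased H_exp shifts the extreme by 1/(2n-1)
        assert f == pytest.approx(-1.0, abs=0.025)

    def test_all_homozygous_half_frequency(self):
        dos = np.array([[0] * 10 + [2] * 10] * 8).T.reshape(20, 8)
        g = make_matrix(dos)
        assert inbreeding_coefficient(g) == pytest.approx(1.0)

    def test_hardy_weinberg_sample_near_zero(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, 600), size=(150, 600))
        f = inbreeding_coefficient(make_matrix(dos))
        assert abs(f) < 0.02

    def test_haploid_undefined(self):
        g = make_matrix(np.array([[0, 1], [1, 0], [0, 1], [1, 1]]), ploidy=1)
        with pytest.raises(ValueError):
            inbreeding_coefficient(g)


class TestSummarizeLD:
    def test_requires_genetic_positions(self):
        g = make_matrix(np.random.default_rng(0).binomial(2, 0.4, (20, 10)),
                        cM=[np.nan] * 10)
        with pytest.raises(ValueError, match="genetic positions"):
            summarize_ld(g)

    def test_single_chromosome_has_no_unlinked_summary(self):
        rng = np.random.default_rng(0)
        g = make_matrix(rng.binomial(2, 0.4, (20, 30)),
                        cM=np.linspace(0, 50, 30))
        with pytest.warns(UserWarning, match="single chromosome"):
            obs = summarize_ld(g)
        assert np.isnan(obs.delta2_unlinked)
        assert np.isfinite(obs.delta2_weak)

    def test_allele_relabelling_invariance(self, panmictic_sim):
        g, _ = panmictic_sim
        obs = summarize_ld(g, LDConfig(seed=3))
        flipped = g.take_sites(np.arange(g.n_sites))
        rng = np.random.default_rng(4)
        sel = rng.random(g.n_sites) < 0.5
        flipped.dosages[:, sel] = 2 - flipped.dosages[:, sel]
        obs2 = summarize_ld(flipped, LDConfig(seed=3))
        assert obs2.delta2_unlinked == pytest.approx(obs.delta2_unlinked,
                                                     rel=1e-9)
        assert obs2.delta2_weak == pytest.approx(obs.delta2_weak, rel=1e-9)

    def test_missing_data_matches_complete_subset(self):
        """Pairwise-complete path agrees with per-pair NaN computation."""
        rng = np.random.default_rng(11)
        dos = rng.binomial(2, 0.4, (40, 24)).astype(np.int8)
        miss = rng.random(dos.shape) < 0.1
        g = make_matrix(dos, chrom=["1"] * 12 + ["2"] * 12, missing=miss,
                        cM=list(np.linspace(0, 60, 12)) * 2)
        obs = summarize_ld(g, LDConfig(min_pairs_per_bin=1))
        num = w = 0.0
        X = np.where(miss, np.nan, dos).astype(float)
        for i in range(12):
            for j in range(12, 24):
                try:
                    p = composite_pair_ld(X[:, i], X[:, j])
                except ValueError:
                    continue
                nshared = int((~np.isnan(X[:, i]) & ~np.isnan(X[:, j])).sum())
                num += correct_for_sampling(p.D2, p.W, nshared)
                w += p.W
        assert obs.delta2_unlinked == pytest.approx(num / w, rel=1e-9)

    def test_fully_differentiated_demes_wahlund_extreme(self):
        """Two pooled demes fixed for alternative alleles: delta2 between
        unlinked loci approaches F_hat^2 with F_hat ~ 1."""
        dos = np.zeros((40, 40), dtype=np.int8)
        dos[20:, :] = 2
        g = make_matrix(dos, chrom=["1"] * 20 + ["2"] * 20,
                        cM=list(np.linspace(0, 50, 20)) * 2)
        obs = summarize_ld(g, LDConfig(seed=0))
        f = inbreeding_coefficient(g)
        assert f == pytest.approx(1.0, abs=0.02)
        assert obs.delta2_unlinked == pytest.approx(f * f, rel=0.05)

    def test_bins_monotone_decay_on_equilibrium_sim(self, panmictic_summary):
        b = panmictic_summary.bins
        assert (np.diff(b["c_mean"]) > 0).all()
        lo = b[b.c_mean < 0.02]["delta2"].mean()
        hi = b[b.c_mean > 0.2]["delta2"].mean()
        assert lo > hi  # LD decays with recombination

    def test_bin_pair_minimum_respected(self, panmictic_summary):
        assert (panmictic_summary.bins["n_pairs"] >= 100).all()

    def test_drop_chromosome_parts(self, panmictic_summary):
        sub = panmictic_summary.drop_chromosome("1")
        assert np.isfinite(sub.delta2_unlinked)
        assert len(sub.parts["weak"]) == len(panmictic_summary.parts["weak"]) - 1
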