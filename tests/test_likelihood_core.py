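"""The genotype-likelihood model, null moments and the standardized test."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from metareid import (
    ErrorModel,
    ObservationSet,
    SiteKey,
    empirical_pvalue,
    genotype_likelihood,
    hwe_genotype_freqs,
    likelihood_score,
    null_moments,
    standardize_and_test,
)


def make_obs(n, k):
    sites = [SiteKey("1", 100 + i, "A", "G") for i in range(len(n))]
    return ObservationSet(sites=sites, n=np.asarray(n), k=np.asarray(k))


class TestGenotypeLikelihood:
    def test_heterozygote_collapses_to_coin_flips(self, em):
        # error terms cancel for g=1: every base is ref or alt w.p. 1/2
        assert genotype_likelihood(1, 3, 2, em) == pytest.approx(0.125)

    def test_homozygote_endpoints(self, em):
        assert genotype_likelihood(0, 1, 1, em) == pytest.approx(1 - 1e-6)
        assert genotype_likelihood(2, 2, 2, em) == pytest.approx(1e-12, rel=1e-9)

    def test_domain_errors(self, em):
        with pytest.raises(ValueError):
            genotype_likelihood(3, 1, 0, em)
        with pytest.raises(ValueError):
            genotype_likelihood(0, 1, 2, em)

    @given(
        g=st.sampled_from([0, 1, 2]),
        n=st.integers(min_value=1, max_value=12),
        eps=st.sampled_from([1e-6, 1e-3, 0.01, 0.2]),
    )
    def test_total_probability_over_read_outcomes(self, g, n, eps):
        em = ErrorModel(eps)
        total = sum(
            math.comb(n, k) * genotype_likelihood(g, n, k, em) for k in range(n + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(
        g=st.sampled_from([0, 1, 2]),
        n=st.integers(min_value=1, max_value=10),
        data=st.data(),
    )
    def test_ref_alt_relabeling_symmetry(self, g, n, data):
        """Swapping ref and alt (k -> n-k, g -> 2-g) leaves L unchanged."""
        em = ErrorModel()
        k = data.draw(st.integers(min_value=0, max_value=n))
        assert genotype_likelihood(g, n, k, em) == pytest.approx(
            genotype_likelihood(2 - g, n, n - k, em), rel=1e-12
        )


class TestHWE:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.0, (1, 0, 0)), (0.5, (0.25, 0.5, 0.25)), (0.2, (0.64, 0.32, 0.04))],
    )
    def test_closed_form(self, p, expected):
        np.testing.assert_allclose(hwe_genotype_freqs(p), expected, atol=1e-15)

    def test_sums_to_one_vectorized(self):
        p = np.linspace(0, 1, 101)
        np.testing.assert_allclose(hwe_genotype_freqs(p).sum(axis=0), 1.0, atol=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hwe_genotype_freqs(1.5)


class TestLikelihoodScore:
    def test_two_het_sites_single_reads(self, em):
        obs = make_obs([1, 1], [1, 0])
        ls, n_sites, n_bases = likelihood_score(obs, np.array([1, 1]), em)
        assert ls == pytest.approx(2 * math.log(0.5))
        assert (n_sites, n_bases) == (2, 2)

    def test_hom_ref_site(self, em):
        obs = make_obs([2], [2])
        ls, _, _ = likelihood_score(obs, np.array([0]), em)
        assert ls == pytest.approx(2 * math.log1p(-1e-6))

    def test_missing_dosages_skipped_and_uncounted(self, em):
        obs = make_obs([1, 5], [1, 5])
        ls, n_sites, n_bases = likelihood_score(obs, np.array([0, -1]), em)
        assert (n_sites, n_bases) == (1, 1)
        ls_all, _, _ = likelihood_score(obs, np.array([0, 0]), em)
        assert ls_all < ls + 1e-12

    def test_all_missing_gives_no_overlap_signal(self, em):
        obs = make_obs([1], [1])
        ls, n_sites, n_bases = likelihood_score(obs, np.array([-1]), em)
        assert math.isnan(ls) and n_sites == 0 and n_bases == 0

    def test_matches_per_site_loop_oracle(self, em):
        rng = np.random.default_rng(3)
        n = rng.integers(1, 6, 100)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        g = rng.integers(0, 3, 100)
        obs = make_obs(n, k)
        ls, _, _ = likelihood_score(obs, g, em)
        oracle = sum(
            math.log(genotype_likelihood(int(gi), int(ni), int(ki), em))
            for gi, ni, ki in zip(g, n, k)
        )
        assert ls == pytest.approx(oracle, rel=1e-12)


class TestNullMoments:
    def test_degenerate_frequency_zero_variance(self, em):
        obs = make_obs([3], [1])
        e, v = null_moments(obs, np.array([0.0]), em)
        assert v == 0.0
        assert e == pytest.approx(math.log(genotype_likelihood(0, 3, 1, em)))

    def test_single_site_closed_form(self, em):
        obs = make_obs([1], [1])
        e, _ = null_moments(obs, np.array([0.5]), em)
        expected = (
            0.25 * math.log1p(-1e-6) + 0.5 * math.log(0.5) + 0.25 * math.log(1e-6)
        )
        assert e == pytest.approx(expected, rel=1e-12)

    def test_ref_alt_relabeling_invariance(self, em):
        rng = np.random.default_rng(9)
        n = rng.integers(1, 5, 50)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        p = rng.uniform(0.05, 0.95, 50)
        obs = make_obs(n, k)
        flipped = make_obs(n, n - k)
        e1, v1 = null_moments(obs, p, em)
        e2, v2 = null_moments(flipped, 1.0 - p, em)
        assert e1 == pytest.approx(e2, rel=1e-10)
        assert v1 == pytest.approx(v2, rel=1e-10)

    def test_site_subset_restricts_the_moments(self, em):
        obs = make_obs([1, 2, 3], [1, 1, 0])
        p = np.array([0.2, 0.4, 0.6])
        e_full, v_full = null_moments(obs, p, em)
        e_sub, v_sub = null_moments(obs, p, em, site_subset=np.array([0, 2]))
        e_left, v_left = null_moments(obs, p, em, site_subset=np.array([1]))
        assert e_sub + e_left == pytest.approx(e_full, rel=1e-12)
        assert v_sub + v_left == pytest.approx(v_full, rel=1e-12)


class TestStandardizeAndTest:
    def test_score_at_expectation_gives_half(self):
        z, p = standardize_and_test(-5.0, -5.0, 2.0)
        assert z == 0.0 and p == 0.5

    def test_three_sigma_tail(self):
        z, p = standardize_and_test(-2.0, -5.0, 1.0)
        assert z == pytest.approx(3.0)
        assert p == pytest.approx(1.3499e-3, rel=1e-3)

    def test_zero_variance_is_na(self):
        z, p = standardize_and_test(-1.0, -1.0, 0.0)
        assert math.isnan(z) and math.isnan(p)


class TestEmpiricalPValue:
    def test_formula_floor_and_ceiling(self, em):
        obs = make_obs([1, 1], [1, 1])
        p = np.array([0.5, 0.5])
        # score higher than anything attainable -> floor 1/(n_draws+1)
        assert empirical_pvalue(10.0, obs, p, em, n_draws=999, seed=0) == 1 / 1000
        # score below anything attainable -> 1.0
        assert empirical_pvalue(-1e9, obs, p, em, n_draws=999, seed=0) == 1.0

    def test_deterministic_under_seed(self, em):
        rng = np.random.default_rng(5)
        obs = make_obs(rng.integers(1, 4, 30), rng.integers(0, 2, 30))
        p = rng.uniform(0.1, 0.9, 30)
        a = empirical_pvalue(-20.0, obs, p, em, n_draws=2000, seed=7)
        b = empirical_pvalue(-20.0, obs, p, em, n_draws=2000, seed=7)
        assert a == b

    def test_null_calibration_uniform(self, em):
        """Empirical P of null-drawn scores is ~uniform on {1/1000, ..., 1}."""
        rng = np.random.default_rng(11)
        m = 50
        n = rng.integers(1, 3, m)
        k = np.array([rng.integers(0, ni + 1) for ni in n])
        p = rng.uniform(0.1, 0.9, m)
        obs = make_obs(n, k)
        from metareid.likelihood_core import log_likelihood_by_genotype

        table = log_likelihood_by_genotype(obs.n, obs.k, em)
        pvals = []
        for _ in range(500):
            g = rng.binomial(2, p)
            ls_null = float(table[g, np.arange(m)].sum())
            pvals.append(
                empirical_pvalue(ls_null, obs, p, em, n_draws=999, seed=rng.integers(2**31))
            )
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
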