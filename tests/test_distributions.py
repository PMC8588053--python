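import numpy as np
import pytest
from scipy import stats

from afmpore import (
    GammaParams,
    gamma_fit_mle,
    gamma_fit_moments,
    jarque_bera,
    jarque_bera_statistic,
    jb_critical,
    kruskal_wallis,
    pairwise_discrimination,
    sample_moments,
)


class TestSampleMoments:
    def test_symmetric_data_has_zero_skewness(self):
        m = sample_moments([-1.0, 0.0, 1.0])
        assert m.skewness_b1 == pytest.approx(0.0, abs=1e-12)

    def test_hand_expanded_central_moments(self):
        # {0,0,0,1}: m2=3/16, m3=3/32, m4=21/256 via direct expansion
        m = sample_moments([0.0, 0.0, 0.0, 1.0])
        assert m.mean == 0.25
        assert m.skewness_b1 == pytest.approx((3 / 32) / (3 / 16) ** 1.5, rel=1e-12)
        assert m.kurtosis_b2 == pytest.approx((21 / 256) / (3 / 16) ** 2, rel=1e-12)

    def test_gamma_sample_skewness_matches_closed_form(self, rng):
        x = rng.gamma(0.6, 1.0, 1_000_000)
        m = sample_moments(x)
        assert m.skewness_b1 == pytest.approx(2 / np.sqrt(0.6), rel=0.03)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_moments([1.0])
        with pytest.raises(ValueError):
            sample_moments([2.0, 2.0, 2.0])


class TestJarqueBera:
    @pytest.mark.parametrize(
        "n, b1, b2, expected",
        [(304, 2.307, 9.048, 733), (304, 2.833, 12.482, 1545), (304, 4.776, 39.379, 17919)],
    )
    def test_statistic_from_published_fluid_moments(self, n, b1, b2, expected):
        assert round(jarque_bera_statistic(n, b1, b2)) == expected

    def test_gaussian_moments_give_zero(self):
        assert jarque_bera_statistic(100, 0.0, 3.0) == 0.0

    def test_pass_fail_against_critical_value(self):
        m = sample_moments(np.random.default_rng(0).gamma(0.7, 12.0, 304))
        res = jarque_bera(m, critical_value=5.7)
        assert res.statistic > 5.7 and not res.passes_normality

    def test_statistic_nonnegative_and_zero_only_at_gaussian_moments(self, rng):
        for _ in range(200):
            x = rng.normal(size=20)
            m = sample_moments(x)
            jb = jarque_bera_statistic(m.n, m.skewness_b1, m.kurtosis_b2)
            assert jb >= 0.0
            if jb == 0.0:
                assert m.skewness_b1 == 0.0 and m.kurtosis_b2 == 3.0


class TestJBCritical:
    def test_converges_to_chi2_quantile_at_large_n(self):
        crit = jb_critical(5000, alpha=0.05, replicates=40_000, seed=3)
        assert crit == pytest.approx(stats.chi2.ppf(0.95, 2), abs=0.3)

    def test_finite_sample_criticals_below_asymptote(self):
        c60 = jb_critical(60, replicates=20_000, seed=1)
        c304 = jb_critical(304, replicates=20_000, seed=2)
        assert c60 < c304 < stats.chi2.ppf(0.95, 2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            jb_critical(5)
        with pytest.raises(ValueError):
            jb_critical(60, replicates=100)


class TestKruskalWallis:
    def test_two_group_hand_ranked_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.h_statistic == pytest.approx(27 / 7, rel=1e-6)
        assert res.p_value == pytest.approx(stats.chi2.sf(27 / 7, 1), rel=1e-9)
        assert res.dof == 1

    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([[1, 2], [1, 2]])
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_defined_as_zero(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.h_statistic == 0.0 and res.p_value == 1.0

    def test_invariant_under_strictly_monotone_transform(self, rng):
        a, b = rng.normal(size=15), rng.normal(1.0, 1.0, size=12)
        base = kruskal_wallis([a, b])
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            res = kruskal_wallis([f(a), f(b)])
            assert res.h_statistic == pytest.approx(base.h_statistic, rel=1e-9)

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestGammaFitting:
    def test_moment_inversion_of_published_pair(self):
        p = gamma_fit_moments(9.45, 2.314)
        assert p.shape_a == pytest.approx(0.747, abs=5e-4)
        assert p.scale_b == pytest.approx(12.65, abs=5e-3)

    def test_skewness_two_gives_unit_shape(self):
        assert gamma_fit_moments(5.0, 2.0).shape_a == pytest.approx(1.0)

    def test_moment_round_trip_is_identity(self):
        p = GammaParams(0.75, 12.6)
        q = gamma_fit_moments(p.mean, p.skewness)
        assert q.shape_a == pytest.approx(p.shape_a, rel=1e-12)
        assert q.scale_b == pytest.approx(p.scale_b, rel=1e-12)

    def test_mle_recovers_exponential_shape(self, rng):
        fit = gamma_fit_mle(rng.gamma(1.0, 3.0, 20_000))
        assert fit.shape_a == pytest.approx(1.0, rel=0.05)

    def test_mle_beats_moment_start_in_likelihood(self, rng):
        for _ in range(10):
            x = rng.gamma(0.7, 10.0, 500)
            mle = gamma_fit_mle(x)
            mom = gamma_fit_moments(float(x.mean()), sample_moments(x).skewness_b1)
            assert mle.log_likelihood(x) >= mom.log_likelihood(x) - 1e-8

    def test_degenerate_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            gamma_fit_mle(np.full(50, 3.0))
        with pytest.raises(ValueError):
            gamma_fit_mle(np.concatenate([np.ones(20), [-1.0]]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GammaParams(-1.0, 2.0)
        with pytest.raises(ValueError):
            gamma_fit_moments(5.0, -2.0)


class TestPairwiseDiscrimination:
    def test_skewed_gamma_samples_take_nonparametric_branch(self, rng):
        a = rng.gamma(0.7, 12.0, 304)
        b = rng.gamma(0.75, 12.6, 304)
        res = pairwise_discrimination(a, b, jb_critical_a=5.7, jb_critical_b=5.7)
        assert res.branch == "kruskal-wallis"
        assert not res.jb_a.passes_normality

    def test_gaussian_samples_take_parametric_branch(self, rng):
        a = rng.normal(10.0, 1.0, 60)
        b = rng.normal(10.0, 1.0, 60)
        res = pairwise_discrimination(a, b, jb_critical_a=5.1, jb_critical_b=5.1)
        assert res.branch in ("t-pooled", "t-welch")
        assert res.levene_p is not None

    def test_identical_samples_do_not_reject(self, rng):
        a = rng.normal(10.0, 1.0, 60)
        res = pairwise_discrimination(a, a, jb_critical_a=5.1, jb_critical_b=5.1)
        assert res.p_value > 0.9

    def test_parametric_type_one_error_calibrated(self, rng):
        # equal-mean Gaussian pairs: p-values roughly uniform
        ps = []
        for _ in range(200):
            a, b = rng.normal(size=40), rng.normal(size=40)
            ps.append(pairwise_discrimination(a, b, jb_critical_a=50, jb_critical_b=50).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
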