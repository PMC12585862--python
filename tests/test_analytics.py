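import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from microassembly import (
    SpeciesTraits,
    afd_binomial_limit,
    afd_exact,
    afd_uniform_solution,
    alpha,
    bc_asymmetric,
    bc_symmetric,
    bc_symmetric_limit,
    monodominance_probs,
    multinomial_limit,
    neutral_moments,
    prob_all_A,
    prob_all_B,
    prob_cooccurrence,
)

from conftest import make_traits


class TestAlpha:
    def test_empty_symmetric_is_half(self, neutral_symmetric):
        assert alpha(0, 0, neutral_symmetric) == pytest.approx(0.5)

    def test_intermediate_regime_formula(self, neutral_symmetric):
        # all rates equal: alpha = (N_A + 1)/(N + 2)
        assert alpha(3, 8, neutral_symmetric) == pytest.approx(4 / 10)

    def test_high_dispersal_state_independent(self):
        traits = make_traits(r_a=1e-9, c_a=2.0, r_b=1e-9, c_b=1.0)
        for n_a, n in [(0, 0), (5, 10), (90, 100)]:
            assert alpha(n_a, n, traits) == pytest.approx(2 / 3, abs=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(
        n=st.integers(0, 200),
        frac=st.floats(0, 1),
        r_a=st.floats(0.01, 10),
        c_a=st.floats(0, 10),
        r_b=st.floats(0.01, 10),
        c_b=st.floats(0, 10),
    )
    def test_alpha_is_a_probability(self, n, frac, r_a, c_a, r_b, c_b):
        if n == 0 and c_a + c_b == 0:
            return  # no event can occur: alpha is a documented domain error
        n_a = int(round(frac * n))
        a = alpha(n_a, n, make_traits(r_a, c_a, r_b, c_b))
        assert 0.0 <= a <= 1.0


class TestAfdExact:
    def test_two_step_uniform(self, neutral_symmetric):
        d = afd_exact(2, neutral_symmetric)
        assert np.allclose(d.probabilities, [1 / 3, 1 / 3, 1 / 3], atol=1e-15)

    def test_unreachable_species_concentrates_mass(self):
        traits = make_traits(r_a=1.0, c_a=1.0, r_b=1.0, c_b=0.0)
        d = afd_exact(30, traits)
        assert d.probabilities[-1] == pytest.approx(1.0)

    def test_cap_is_enforced_with_guidance(self, neutral_symmetric):
        with pytest.raises(ValueError, match="closed-form"):
            afd_exact(6000, neutral_symmetric)
        # and the override works
        afd_exact(10, neutral_symmetric, max_size=10)

    @settings(derandomize=True, max_examples=30)
    @given(
        n=st.integers(0, 60),
        r_a=st.floats(0.1, 5),
        c_a=st.floats(0.01, 5),
        r_b=st.floats(0.1, 5),
        c_b=st.floats(0.01, 5),
    )
    def test_normalized_and_nonnegative(self, n, r_a, c_a, r_b, c_b):
        d = afd_exact(n, make_traits(r_a, c_a, r_b, c_b))
        assert abs(d.probabilities.sum() - 1.0) < 1e-12
        assert np.all(d.probabilities >= 0)


class TestBoundaryClosedForms:
    def test_single_recruit_symmetric(self, neutral_symmetric):
        assert prob_all_B(1, neutral_symmetric) == pytest.approx(0.5)
        assert prob_all_A(1, neutral_symmetric) == pytest.approx(0.5)

    def test_low_dispersal_limit_is_dispersal_share(self):
        # c_A = 2 c_B, c << r: P(0,N) -> c_B/(c_A+c_B) = 1/3
        traits = make_traits(r_a=1.0, c_a=2e-8, r_b=1.0, c_b=1e-8)
        assert prob_all_B(1000, traits) == pytest.approx(1 / 3, abs=1e-5)
        assert prob_all_A(1000, traits) == pytest.approx(2 / 3, abs=1e-5)

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("c", [1e-2, 1.0, 1e2])
    @pytest.mark.parametrize("N", [10, 100, 1000])
    def test_matches_master_equation_endpoints(self, r, c, N):
        traits = make_traits(r_a=r, c_a=c, r_b=r, c_b=c)
        d = afd_exact(N, traits)
        assert abs(d.probabilities[0] - prob_all_B(N, traits)) < 1e-12
        assert abs(d.probabilities[-1] - prob_all_A(N, traits)) < 1e-12

    def test_asymmetric_traits_match_endpoints(self):
        traits = make_traits(r_a=1.3, c_a=0.7, r_b=0.8, c_b=2.1)
        d = afd_exact(200, traits)
        assert abs(d.probabilities[0] - prob_all_B(200, traits)) < 1e-12
        assert abs(d.probabilities[-1] - prob_all_A(200, traits)) < 1e-12

    def test_stable_at_huge_community_size(self, neutral_symmetric):
        # log-gamma evaluation must not overflow at N = 1e5
        p0 = prob_all_B(10**5, neutral_symmetric)
        assert 0.0 <= p0 <= 1.0

    def test_no_assembly_without_dispersal(self):
        traits = make_traits(r_a=1.0, c_a=0.0, r_b=1.0, c_b=0.0)
        with pytest.raises(ValueError):
            prob_all_B(10, traits)


class TestCooccurrence:
    def test_vanishes_at_very_low_dispersal(self):
        traits = make_traits(1.0, 1e-6, 1.0, 1e-6)
        assert prob_cooccurrence(1000, traits) == pytest.approx(0.0, abs=1e-3)

    def test_certain_at_very_high_dispersal(self):
        traits = make_traits(1.0, 1e6, 1.0, 1e6)
        assert prob_cooccurrence(1000, traits) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_dispersal_rate(self):
        grid = np.logspace(-4, 4, 60)
        vals = [
            prob_cooccurrence(10**5, make_traits(1.0, c, 1.0, c)) for c in grid
        ]
        assert np.all(np.diff(vals) >= -1e-12)


class TestBinomialLimit:
    def test_fair_two_recruit_case(self):
        d = afd_binomial_limit(2, 1.0, 1.0)
        assert np.allclose(d.probabilities, [0.25, 0.5, 0.25])

    def test_mean_is_dispersal_share(self):
        d = afd_binomial_limit(300, 3.0, 1.0)
        assert d.mean() == pytest.approx(300 * 0.75)

    def test_close_to_master_equation_at_high_dispersal(self):
        traits = make_traits(r_a=1.0, c_a=1e6, r_b=1.0, c_b=1e6)
        exact = afd_exact(200, traits)
        limit = afd_binomial_limit(200, 1e6, 1e6)
        assert exact.total_variation(limit) < 1e-2


class TestUniformSolution:
    @pytest.mark.parametrize("N", [1, 5, 50, 500])
    def test_matches_master_equation_at_equal_rates(self, N, neutral_symmetric):
        d = afd_exact(N, neutral_symmetric)
        u = afd_uniform_solution(N)
        assert np.max(np.abs(d.probabilities - u.probabilities)) < 1e-12

    def test_flat_and_normalized(self):
        u = afd_uniform_solution(5)
        assert np.allclose(u.probabilities, 1 / 6)
        assert u.probabilities.sum() == pytest.approx(1.0, abs=1e-15)


class TestNeutralMoments:
    def test_symmetric_mean_is_half(self):
        for n in (10, 1000):
            assert neutral_moments(n, 1.0, 1.0, 1.0).mean == pytest.approx(n / 2)

    @pytest.mark.parametrize("r,c_a,c_b,n", [(0.5, 1.0, 3.0, 77), (2.0, 0.2, 0.1, 500)])
    def test_mean_is_dispersal_share_in_every_regime(self, r, c_a, c_b, n):
        m = neutral_moments(n, r, c_a, c_b)
        assert m.mean == pytest.approx(n * c_a / (c_a + c_b), rel=1e-12)

    @pytest.mark.parametrize(
        "r,c_a,c_b,n",
        [(1.0, 1.0, 1.0, 100), (1.0, 2.0, 1.0, 250), (0.5, 0.1, 0.3, 500)],
    )
    def test_all_four_moments_match_master_equation(self, r, c_a, c_b, n):
        rec = neutral_moments(n, r, c_a, c_b)
        dp = afd_exact(n, make_traits(r, c_a, r, c_b)).moments()
        for a, b in zip(rec.raw_moments, dp.raw_moments):
            assert abs(a - b) <= 1e-10 * max(1.0, abs(b))

    def test_moment_inequalities_hold(self):
        m = neutral_moments(200, 1.0, 0.3, 2.0)
        assert m.variance >= 0
        assert m.kurtosis >= m.skewness**2 + 1 - 1e-12


class TestBimodalityCoefficients:
    def test_uniform_regime_gives_five_ninths(self):
        assert bc_symmetric_limit(1.0, 1.0) == pytest.approx(5 / 9)
        assert bc_asymmetric(1.0, 1.0, 1.0) == pytest.approx(5 / 9)

    def test_smallest_community_uniform(self):
        # uniform on {0,1,2}: skewness 0, kurtosis 3/2, BC = 2/3
        assert bc_symmetric(2, 1.0, 1.0) == pytest.approx(2 / 3)

    def test_dispersal_dominated_limit_is_one_third(self):
        assert bc_symmetric_limit(1.0, 1e6) == pytest.approx(1 / 3, abs=1e-5)
        assert bc_asymmetric(1e-9, 2.0, 3.0) == pytest.approx(1 / 3, abs=1e-5)

    def test_division_dominated_limit_is_one(self):
        assert bc_symmetric_limit(1.0, 1e-6) == pytest.approx(1.0, abs=1e-5)

    def test_finite_size_correction_fades(self):
        assert abs(bc_symmetric(10**4, 1.0, 1.0) - 5 / 9) < 1e-3

    def test_asymmetric_closed_form_matches_moment_recursion(self):
        for c_a, c_b in [(1.0, 1.0), (2.0, 1.0), (0.7, 1.9)]:
            rec = neutral_moments(10**4, 1.0, c_a, c_b).bimodality_coefficient
            assert abs(bc_asymmetric(1.0, c_a, c_b) - rec) < 1e-3

    def test_monotone_decreasing_in_dispersal(self):
        grid = np.logspace(-4, 4, 60)
        vals = [bc_symmetric_limit(1.0, c) for c in grid]
        assert np.all(np.diff(vals) < 0)

    def test_small_community_rejected(self):
        with pytest.raises(ValueError):
            bc_symmetric(1, 1.0, 1.0)


class TestSSpeciesLimits:
    def test_symmetric_monodominance(self):
        assert np.allclose(monodominance_probs([1, 1, 1]), [1 / 3, 1 / 3, 1 / 3])

    def test_two_species_reduces_to_boundary_forms(self):
        p = monodominance_probs([2.0, 1.0])
        traits = make_traits(r_a=1.0, c_a=2e-8, r_b=1.0, c_b=1e-8)
        assert p[0] == pytest.approx(prob_all_A(1000, traits), abs=1e-5)
        assert p[1] == pytest.approx(prob_all_B(1000, traits), abs=1e-5)

    def test_multinomial_means(self):
        dist = multinomial_limit([2.0, 1.0, 1.0], K=100)
        assert np.allclose(dist.mean(), [50.0, 25.0, 25.0])

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            monodominance_probs([0.0, 0.0])
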