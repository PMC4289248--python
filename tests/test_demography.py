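"""Unit and property tests for the single-step demographic kernel."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sharkpop import (
    DemographicParams,
    LitterDistribution,
    PopulationState,
    advance,
    breeding_females,
    draw_deaths,
    draw_total_births,
    first_class_mortality_prob,
    juvenile_count,
)
from sharkpop.demography import ConfigError


def state_with(params=None, **class_counts):
    p = params or DemographicParams()
    c = np.zeros(p.n_classes, dtype=np.int64)
    for key, v in class_counts.items():
        c[int(key.lstrip("a"))] = v
    return PopulationState(c)


class TestBreedingFemales:
    def test_quarter_of_adult_total(self):
        p = DemographicParams()
        c = np.zeros(26, dtype=np.int64)
        c[12:] = [4, 4, 4, 4, 4, 4, 2, 2, 2, 2, 2, 2, 2, 2]  # sums to 40
        assert breeding_females(PopulationState(c), p) == 10.0

    def test_empty_population(self):
        assert breeding_females(state_with(), DemographicParams()) == 0.0

    def test_fractional_count_allowed(self):
        st_ = state_with(a12=15, a13=15)
        assert breeding_females(st_, DemographicParams()) == 7.5

    def test_subadults_do_not_breed(self):
        st_ = state_with(a3=50, a11=50)
        assert breeding_females(st_, DemographicParams()) == 0.0


class TestTotalBirths:
    def test_no_breeders_no_births(self, rng):
        point = LitterDistribution(np.eye(19)[5])
        for mode, dist in (("poisson", None), ("empirical", point)):
            p = DemographicParams(fecundity_mode=mode, litter_dist=dist)
            assert draw_total_births(0.0, p, rng) == 0

    def test_poisson_mean_is_lambda_times_b(self, rng):
        p = DemographicParams(lambda_mean=6.1)
        n = 100_000
        draws = np.array([draw_total_births(10.0, p, rng) for _ in range(n)])
        se = np.sqrt(61.0 / n)
        assert abs(draws.mean() - 61.0) < 3 * se
        # Poisson: variance equals the mean
        var_se = 61.0 * np.sqrt(2.0 / (n - 1))  # approx SE of sample variance
        assert abs(draws.var(ddof=1) - 61.0) < 3 * var_se

    def test_degenerate_litter_distribution(self, rng):
        point = LitterDistribution(np.eye(19)[5])
        p = DemographicParams(fecundity_mode="empirical", litter_dist=point)
        assert all(draw_total_births(4.0, p, rng) == 20 for _ in range(50))

    def test_empirical_rounds_b_half_even(self, rng):
        point = LitterDistribution(np.eye(19)[5])
        p = DemographicParams(fecundity_mode="empirical", litter_dist=point)
        assert draw_total_births(2.5, p, rng) == 10  # 2.5 -> 2 females
        assert draw_total_births(3.5, p, rng) == 20  # 3.5 -> 4 females

    def test_empirical_without_distribution_is_config_error(self):
        with pytest.raises(ConfigError):
            DemographicParams(fecundity_mode="empirical")

    def test_negative_b_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_total_births(-1.0, DemographicParams(), rng)


class TestHillMortality:
    def test_zero_density_zero_mortality(self):
        assert first_class_mortality_prob(0, h=1.0, k=100.0) == 0.0

    @pytest.mark.parametrize("h", [1.0, 2.0, 5.0])
    def test_half_saturation_is_exactly_half(self, h):
        assert first_class_mortality_prob(100, h=h, k=100.0) == pytest.approx(0.5)

    def test_three_k_gives_three_quarters(self):
        assert first_class_mortality_prob(300, h=1.0, k=100.0) == pytest.approx(0.75)

    @given(
        x0=st.integers(0, 10_000),
        h=st.floats(1.0, 8.0),
        k=st.floats(0.5, 500.0),
    )
    def test_bounded_probability(self, x0, h, k):
        p = first_class_mortality_prob(x0, h, k)
        assert 0.0 <= p < 1.0

    @given(x0=st.integers(0, 2_000), h=st.floats(1.0, 6.0), k=st.floats(1.0, 300.0))
    def test_monotone_in_cohort_size(self, x0, h, k):
        assert first_class_mortality_prob(x0 + 1, h, k) >= first_class_mortality_prob(
            x0, h, k
        )

    @given(x0=st.integers(1, 2_000), h=st.floats(1.0, 6.0), k=st.floats(1.0, 300.0))
    def test_monotone_decreasing_in_k(self, x0, h, k):
        assert first_class_mortality_prob(x0, h, k * 1.5) < first_class_mortality_prob(
            x0, h, k
        )


class TestDeaths:
    def test_certain_survival(self, rng):
        assert all(draw_deaths(50, 0.0, rng) == 0 for _ in range(20))

    def test_empty_class(self, rng):
        assert draw_deaths(0, 0.7, rng) == 0

    def test_binomial_moments(self, rng):
        n = 100_000
        draws = np.array([draw_deaths(100, 0.15, rng) for _ in range(n)])
        mean, var = 15.0, 100 * 0.15 * 0.85
        assert abs(draws.mean() - mean) < 3 * np.sqrt(var / n)
        assert abs(draws.var(ddof=1) - var) < 3 * var * np.sqrt(2.0 / (n - 1))

    def test_pmf_matches_exhaustive_binomial(self, rng):
        """Chi-square test of deaths in a 4-shark class against the exact pmf."""
        n, mu, ndraw = 4, 0.3, 100_000
        draws = np.array([draw_deaths(n, mu, rng) for _ in range(ndraw)])
        observed = np.bincount(draws, minlength=n + 1)
        expected = stats.binom.pmf(np.arange(n + 1), n, mu) * ndraw
        _, pval = stats.chisquare(observed, expected)
        assert pval > 0.01


def leslie_mean_iteration(x0, lam, n_steps, x_m=12, t_max=25):
    """Independent oracle: deterministic mean-matrix iteration with mu=0, no
    density dependence.  Survival shifts every class by one (oldest removed),
    then the newborn class is lambda/4 of the post-shift adult total."""
    shift = np.zeros((t_max + 1, t_max + 1))
    for a in range(1, t_max + 1):
        shift[a, a - 1] = 1.0
    v = np.asarray(x0, dtype=float)
    out = []
    for _ in range(n_steps):
        v = shift @ v
        v[0] = (lam / 4.0) * v[x_m:].sum()
        out.append(v.copy())
    return np.array(out)


class TestAdvance:
    def test_extinction_is_absorbing(self, rng, default_params):
        s = state_with()
        for _ in range(5):
            s, rec = advance(s, default_params, rng)
            assert s.total == 0 and rec.births == 0

    def test_certain_death_above_class_zero(self, rng):
        p = DemographicParams(mu=1.0)
        s = state_with(a1=10)
        nxt, rec = advance(s, p, rng)
        assert nxt.total == 0
        assert rec.deaths[1] == 10

    def test_oldest_class_survivors_are_discarded(self, rng):
        p = DemographicParams(mu=0.0, lambda_mean=0.0)
        s = state_with(a25=40)
        nxt, _ = advance(s, p, rng)
        assert nxt.total == 0

    def test_census_index_increments(self, rng, default_params):
        s = state_with(a0=10)
        nxt, _ = advance(s, default_params, rng)
        assert nxt.census_index == s.census_index + 1

    @given(data=st.data())
    def test_conservation_per_class(self, data):
        counts = data.draw(
            st.lists(st.integers(0, 60), min_size=26, max_size=26).map(np.array)
        )
        seed = data.draw(st.integers(0, 2**31 - 1))
        params = DemographicParams(mu=data.draw(st.floats(0.0, 1.0)))
        state = PopulationState(counts)
        nxt, rec = advance(state, params, np.random.default_rng(seed))
        # survivors into class a+1 plus deaths account exactly for class a
        for a in range(25):
            assert nxt.counts[a + 1] + rec.deaths[a] == state.counts[a]
            assert 0 <= rec.deaths[a] <= state.counts[a]
        assert nxt.counts[0] == rec.births >= 0

    def test_mean_trajectory_matches_leslie_oracle(self):
        """With density dependence off (k huge) and mu=0 the ensemble mean
        must follow the deterministic mean-matrix iteration."""
        lam = 6.1
        params = DemographicParams(lambda_mean=lam, mu=0.0, k=1e9)
        x0 = np.zeros(26, dtype=np.int64)
        x0[:3] = [30, 25, 20]
        x0[12:18] = 5
        n_reps, n_steps = 2000, 20
        oracle = leslie_mean_iteration(x0, lam, n_steps)
        acc = np.zeros((n_steps, 26))
        acc2 = np.zeros((n_steps, 26))
        root = np.random.SeedSequence(777)
        for child in root.spawn(n_reps):
            rng = np.random.default_rng(child)
            s = PopulationState(x0)
            for t in range(n_steps):
                s, _ = advance(s, params, rng)
                acc[t] += s.counts
                acc2[t] += s.counts.astype(float) ** 2
        mean = acc / n_reps
        sd = np.sqrt(np.maximum(acc2 / n_reps - mean**2, 0.0))
        se = sd / np.sqrt(n_reps)
        assert np.all(np.abs(mean - oracle) <= 3 * se + 1e-9)

    def test_expected_deaths_identity(self):
        """E[M_a] = mu * x_a for a >= 1, Monte Carlo within 3 SE."""
        params = DemographicParams(mu=0.2, lambda_mean=0.0)
        s = state_with(a5=200)
        n = 20_000
        rng = np.random.default_rng(5)
        deaths = np.array([advance(s, params, rng)[1].deaths[5] for _ in range(n)])
        expect = 0.2 * 200
        se = np.sqrt(200 * 0.2 * 0.8 / n)
        assert abs(deaths.mean() - expect) < 3 * se


class TestJuvenileCount:
    def test_sums_first_three_classes(self):
        assert juvenile_count(state_with(a0=54, a1=35, a2=30)) == 119

    def test_zero_for_empty_and_adult_only_states(self):
        assert juvenile_count(state_with()) == 0
        assert juvenile_count(state_with(a12=40, a20=10)) == 0


class TestLitterDistribution:
    def test_moments(self):
        d = LitterDistribution(np.array([0.25, 0.5, 0.25]))
        assert d.mean == pytest.approx(1.0)
        assert d.variance == pytest.approx(0.5)

    def test_csv_round_trip(self, tmp_path):
        d = LitterDistribution(np.array([0.1, 0.2, 0.3, 0.4]))
        path = tmp_path / "litter.csv"
        d.to_csv(path)
        back = LitterDistribution.from_csv(path)
        assert np.allclose(back.probs, d.probs)

    def test_renormalizes_small_deviation(self, tmp_path):
        path = tmp_path / "litter.csv"
        path.write_text("litter_size,probability\n0,0.5\n1,0.5000005\n")
        d = LitterDistribution.from_csv(path)
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_large_deviation(self, tmp_path):
        path = tmp_path / "litter.csv"
        path.write_text("litter_size,probability\n0,0.5\n1,0.6\n")
        with pytest.raises(ConfigError):
            LitterDistribution.from_csv(path)

    def test_rejects_negative_probability(self):
        with pytest.raises(ConfigError):
            LitterDistribution(np.array([1.2, -0.2]))


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"mu": -0.1},
            {"mu": 1.5},
            {"k": 0.0},
            {"h": 0.5},
            {"x_m": 0},
            {"x_m": 30},
            {"breeding_coeff": 0.0},
            {"lambda_mean": -1.0},
            {"fecundity_mode": "uniform"},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises((ConfigError, ValueError)):
            DemographicParams(**kw)

    def test_state_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            PopulationState(np.array([1, -2, 3]))
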