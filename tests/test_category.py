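"""Category-level estimators: HDI, cohort simulation, >=k prevalence, conditionals."""

import itertools

import numpy as np
import pytest
from scipy import integrate

import anyprev as ap
from tests.conftest import make_fixed_draws


class TestHdi:
    def test_identical_samples_zero_width(self):
        lo, hi = ap.hdi([0.3] * 10)
        assert lo == hi == 0.3

    def test_uniform_sample_width(self):
        rng = np.random.default_rng(0)
        lo, hi = ap.hdi(rng.uniform(size=200_000))
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(1)
        lo, hi = ap.hdi(rng.standard_normal(100_000))
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_skewed_sample_shorter_than_central_interval(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(size=100_000)
        lo, hi = ap.hdi(x)
        q_lo, q_hi = np.quantile(x, [0.025, 0.975])
        assert hi - lo < q_hi - q_lo
        assert lo == pytest.approx(0.0, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ap.hdi([])


def _brute_force_at_least_k(p, omega_C, k):
    """Enumerate all 2^D outcomes of the thresholded latent MVN (independent case)."""
    D = len(p)
    assert np.allclose(omega_C, np.eye(D)), "enumeration oracle assumes independence"
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=D):
        if sum(outcome) >= k:
            prob = np.prod([p[d] if outcome[d] else 1 - p[d] for d in range(D)])
            total += prob
    return total


class TestSimulateCohort:
    def test_marginal_consistency_under_no_heterogeneity(self):
        p = np.array([0.05, 0.10, 0.30])
        draws = make_fixed_draws(ap.probit(p), 0.0, np.eye(3), np.eye(3))
        cohort = ap.simulate_cohort(draws, 200_000, seed=0)
        np.testing.assert_allclose(cohort.diagnoses.mean(axis=0), p, atol=0.005)

    def test_perfect_comorbidity_duplicates_columns(self):
        z = ap.probit(0.2)
        omega = np.array([[1.0, 1.0], [1.0, 1.0]]) + 1e-12 * np.eye(2)
        draws = make_fixed_draws([z, z], 0.0, np.eye(2), omega)
        cohort = ap.simulate_cohort(draws, 5_000, seed=1)
        np.testing.assert_array_equal(cohort.diagnoses[:, 0], cohort.diagnoses[:, 1])

    def test_one_study_per_draw_shares_study_effects(self):
        draws = make_fixed_draws([-1.5, -1.2], 0.5, np.eye(2), np.eye(2), n_draws=50)
        cohort = ap.simulate_cohort(draws, 2_000, mode="one-study-per-draw", seed=2)
        assert len(np.unique(cohort.study_index)) <= 50
        solo = ap.simulate_cohort(draws, 2_000, seed=2)
        assert len(np.unique(solo.study_index)) == 2_000

    def test_pairwise_association_matches_orthant_oracle(self):
        # correlated comorbidity: P(both) from numerical double integration
        rho = 0.45
        p = np.array([0.08, 0.15])
        z = ap.probit(p)
        omega = np.array([[1.0, rho], [rho, 1.0]])
        draws = make_fixed_draws(z, 0.0, np.eye(2), omega)
        cohort = ap.simulate_cohort(draws, 400_000, seed=3)
        both = (cohort.diagnoses[:, 0] & cohort.diagnoses[:, 1]).mean()

        def integrand(y, x):
            det = 1 - rho**2
            return np.exp(-(x**2 - 2 * rho * x * y + y**2) / (2 * det)) / (
                2 * np.pi * np.sqrt(det)
            )

        # diagnosis means latent mu + eps > 0, i.e. eps beyond -probit(p)
        oracle, _ = integrate.dblquad(integrand, -z[0], 8, lambda x: -z[1], 8,
                                      epsabs=1e-10)
        assert both == pytest.approx(oracle, abs=0.002)


class TestCategoryPrevalence:
    def test_independence_limit_matches_enumeration(self):
        p = np.array([0.015, 0.020, 0.025, 0.035, 0.040, 0.060])
        draws = make_fixed_draws(ap.probit(p), 0.0, np.eye(6), np.eye(6))
        s = ap.category_prevalence(draws, k=1, n_inner=20_000, seed=0,
                                   prediction_interval=False)
        expected = _brute_force_at_least_k(p, np.eye(6), 1)
        assert round(100 * expected, 1) == 18.0
        assert s.median == pytest.approx(expected, abs=0.004)

    def test_k_sweep_is_monotone(self):
        p = np.array([0.05, 0.10, 0.20, 0.30])
        omega = ap.exchangeable_corr(4, 0.4)
        draws = make_fixed_draws(ap.probit(p), 0.2, omega, omega, n_draws=100)
        vals = [
            ap.category_prevalence(draws, k=k, n_inner=2_000, seed=5,
                                   prediction_interval=False).median
            for k in range(1, 5)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_comonotone_disorders_collapse_to_marginal(self):
        z = ap.probit(0.12)
        omega = np.full((3, 3), 1.0) + 1e-12 * np.eye(3)
        draws = make_fixed_draws([z] * 3, 0.0, np.eye(3), omega)
        s = ap.category_prevalence(draws, k=1, n_inner=20_000, seed=6,
                                   prediction_interval=False)
        assert s.median == pytest.approx(0.12, abs=0.005)

    def test_prediction_interval_at_least_as_wide_as_hdi(self):
        p = np.array([0.02, 0.03, 0.05])
        draws = make_fixed_draws(ap.probit(p), 0.4, np.eye(3), np.eye(3), n_draws=600)
        s = ap.category_prevalence(draws, k=1, n_inner=1_000, seed=7)
        assert (s.pi_high - s.pi_low) >= (s.hdi_high - s.hdi_low)

    def test_k_out_of_range_rejected(self):
        draws = make_fixed_draws([-2.0, -1.5], 0.0, np.eye(2), np.eye(2))
        with pytest.raises(ValueError):
            ap.category_prevalence(draws, k=3)


class TestConditionalProbability:
    def test_independence_gives_marginal(self):
        p = np.array([0.03, 0.08])
        draws = make_fixed_draws(ap.probit(p), 0.0, np.eye(2), np.eye(2))
        c = ap.conditional_probability(draws, given=["d1"], target="d2", seed=0,
                                       prediction_interval=False)
        assert c.median == pytest.approx(0.08, abs=1e-6)

    def test_perfect_comorbidity_gives_certainty(self):
        z = ap.probit(0.05)
        omega = np.array([[1.0, 1.0 - 1e-9], [1.0 - 1e-9, 1.0]])
        draws = make_fixed_draws([z, z], 0.0, np.eye(2), omega)
        c = ap.conditional_probability(draws, given=[0], target=1, seed=1,
                                       prediction_interval=False)
        assert c.median == pytest.approx(1.0, abs=1e-3)

    def test_matches_bivariate_orthant_oracle(self):
        # P(z1 > 1.881, z2 > 1.881; rho=0.5) / 0.03 by double integration
        rho, p = 0.5, 0.03
        z = ap.probit(p)
        omega = np.array([[1.0, rho], [rho, 1.0]])
        draws = make_fixed_draws([z, z], 0.0, np.eye(2), omega)
        c = ap.conditional_probability(draws, given=["d1"], target="d2", seed=2,
                                       prediction_interval=False)

        def integrand(y, x):
            det = 1 - rho**2
            return np.exp(-(x**2 - 2 * rho * x * y + y**2) / (2 * det)) / (
                2 * np.pi * np.sqrt(det)
            )

        joint, _ = integrate.dblquad(integrand, -z, 9, lambda x: -z, 9, epsabs=1e-11)
        assert round(c.median, 3) == round(joint / p, 3)

    def test_mc_route_agrees_with_orthant_route(self):
        p = np.array([0.10, 0.25, 0.15])
        omega = ap.exchangeable_corr(3, 0.5)
        draws = make_fixed_draws(ap.probit(p), 0.0, np.eye(3), omega, n_draws=30)
        exact = ap.conditional_probability(draws, ["d1"], "d3", method="orthant",
                                           prediction_interval=False)
        mc = ap.conditional_probability(draws, ["d1"], "d3", method="mc",
                                        n_inner=40_000, seed=3,
                                        prediction_interval=False)
        assert mc.median == pytest.approx(exact.median, abs=0.01)

    def test_degenerate_conditioning_handled_without_nan(self):
        # near-impossible conditioning event: MC falls back to orthant integration
        p = np.array([0.0005, 0.02])
        draws = make_fixed_draws(ap.probit(p), 0.0, np.eye(2), np.eye(2), n_draws=20)
        c = ap.conditional_probability(draws, ["d1"], "d2", method="mc", n_inner=50,
                                       seed=4, prediction_interval=False)
        assert np.isfinite(c.median)

    def test_invalid_sets_rejected(self):
        draws = make_fixed_draws([-2.0, -1.5], 0.0, np.eye(2), np.eye(2))
        with pytest.raises(ValueError, match="non-empty"):
            ap.conditional_probability(draws, [], "d1")
        with pytest.raises(ValueError, match="target"):
            ap.conditional_probability(draws, ["d1"], "d1")


@pytest.fixture(scope="module")
def toy():
    panel = ap.DisorderPanel(["a", "b"])
    samples = [
        ap.AggregateSample("s1", "c0", 500, (25, None), any_count=25),
        ap.AggregateSample("s2", "c0", 400, (18, 30), any_count=44),
    ]
    data = ap.MetaDataset(panel, samples)
    z = ap.probit(np.array([0.05, 0.08]))
    draws = make_fixed_draws(z, 0.0, np.eye(2), np.eye(2), n_draws=300)
    return data, draws


class TestPerStudyPredictions:

    def test_single_measured_disorder_any_equals_per_disorder(self, toy):
        data, draws = toy
        per = ap.per_study_predictions(draws, data, mode="per-disorder", seed=0)
        any_ = ap.per_study_predictions(draws, data, mode="any-measured", seed=0)
        row_d = per[(per.sample_id == "s1") & (per.quantity == "a")].iloc[0]
        row_a = any_[any_.sample_id == "s1"].iloc[0]
        assert row_a["median"] == pytest.approx(row_d["median"], abs=0.01)

    def test_predictions_cover_unmeasured_disorders(self, toy):
        data, draws = toy
        per = ap.per_study_predictions(draws, data, mode="per-disorder", seed=0)
        row = per[(per.sample_id == "s1") & (per.quantity == "b")].iloc[0]
        assert row["observed"] is None or np.isnan(row["observed"])
        assert 0 <= row["hdi_low"] <= row["hdi_high"] <= 1

    def test_unknown_sample_rejected(self, toy):
        data, draws = toy
        stranger = ap.MetaDataset(
            data.panel,
            [ap.AggregateSample("sX", "cX", 10, (1, None), any_count=1)],
        )
        with pytest.raises(ValueError, match="no fitted cluster"):
            ap.per_study_predictions(draws, stranger)

    def test_binomial_noise_vanishes_for_huge_samples(self):
        panel = ap.DisorderPanel(["a", "b"])
        big = ap.MetaDataset(
            panel, [ap.AggregateSample("s", "c0", 1_000_000, (50_000, None),
                                       any_count=50_000)]
        )
        z = ap.probit(np.array([0.05, 0.08]))
        rng = np.random.default_rng(0)
        theta = np.tile(z, (200, 1)) + 0.01 * rng.standard_normal((200, 2))
        draws = make_fixed_draws(z, 0.0, np.eye(2), np.eye(2), n_draws=200)
        draws.mu = theta[:, None, :]
        per = ap.per_study_predictions(draws, big, seed=1, max_draws=200)
        row = per[per.quantity == "a"].iloc[0]
        band = row["hdi_high"] - row["hdi_low"]
        post = ap.hdi(ap.inv_probit(theta[:, 0]))
        assert band == pytest.approx(post[1] - post[0], rel=0.2)
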