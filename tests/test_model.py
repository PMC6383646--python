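"""Bayesian core: priors reproduce, posteriors agree with small-data oracles."""

import warnings

import numpy as np
import pytest
from scipy import stats

import anyprev as ap
from anyprev.model import SamplerConfig


def _quiet_fit(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kwargs)


@pytest.fixture(scope="module")
def prior_only_draws():
    """Fit with N = 0 samples: no likelihood, so the posterior is the prior."""
    panel = ap.DisorderPanel(["a", "b"])
    ds = ap.MetaDataset(panel, [ap.AggregateSample("s1", "c1", 0, (0, 0))])
    return _quiet_fit(
        ap.fit_model1, ds, np.eye(2),
        cfg=SamplerConfig(chains=2, iterations=1500, warmup=500, seed=3),
    )


class TestValidation:
    def test_univariate_dataset_rejected(self):
        panel = ap.DisorderPanel(["only"])
        ds = ap.MetaDataset(panel, [ap.AggregateSample("s", "s", 10, (1,), any_count=1)])
        with pytest.raises(ValueError, match="at least two"):
            ap.fit_model1(ds, np.eye(1))

    def test_invalid_omega_c_rejected(self, small_dataset):
        singular = np.full((3, 3), 1.0)  # rank one, not positive definite
        with pytest.raises(ValueError, match="positive definite"):
            ap.fit_model1(small_dataset, singular)

    def test_model2_requires_ipd(self, small_dataset):
        with pytest.raises(ValueError, match="IPD"):
            ap.fit_model2(small_dataset)

    def test_sampler_config_invariants(self):
        with pytest.raises(ValueError, match="warmup"):
            SamplerConfig(iterations=100, warmup=100)
        with pytest.raises(ValueError, match="chains"):
            SamplerConfig(chains=1)

    def test_unobserved_disorder_warns(self):
        panel = ap.DisorderPanel(["a", "b"])
        ds = ap.MetaDataset(panel, [ap.AggregateSample("s", "s", 50, (3, None), any_count=3)])
        with pytest.warns(UserWarning, match="observed in no sample"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("always", UserWarning)
                ap.fit_model1(ds, np.eye(2),
                              cfg=SamplerConfig(chains=2, iterations=60, warmup=30,
                                                seed=0))


class TestPriorReproduction:
    """With no data the sampler must reproduce its own priors exactly."""

    def test_prevalence_prior_quantiles(self, prior_only_draws):
        prev = ap.inv_probit(prior_only_draws.theta[:, 0])
        lo, mid, hi = np.percentile(prev, [2.28, 50, 97.72])  # +/- 2 SD mass
        plo, phi = ap.prior_prevalence_range(-1.88, 0.30, 2)
        assert mid == pytest.approx(ap.inv_probit(-1.88), abs=0.004)
        assert lo == pytest.approx(plo, abs=0.003)
        assert hi == pytest.approx(phi, abs=0.012)

    def test_tau_prior_is_half_normal(self, prior_only_draws):
        tau = prior_only_draws.tau.ravel()
        assert tau.min() >= 0
        ref = stats.halfnorm(scale=0.25)
        assert np.median(tau) == pytest.approx(ref.median(), abs=0.02)
        assert np.percentile(tau, 90) == pytest.approx(ref.ppf(0.9), abs=0.03)

    def test_between_study_correlation_prior_is_lkj(self, prior_only_draws):
        # for D = 2 the LKJ(2) marginal of r is 2 Beta(2, 2) - 1
        r = prior_only_draws.omega_B[:, 0, 1]
        assert abs(r.mean()) < 0.04
        assert r.std() == pytest.approx(np.sqrt(4 * 4 / (16 * 5 * 4)) * 2, abs=0.03)

    def test_all_correlation_draws_are_valid(self, prior_only_draws):
        om = prior_only_draws.omega_B
        assert np.allclose(om, np.swapaxes(om, 1, 2))
        assert np.allclose(om[:, 0, 0], 1.0) and np.allclose(om[:, 1, 1], 1.0)
        assert (np.linalg.eigvalsh(om).min(axis=1) > 0).all()

    def test_sigma_b_reconstructs_from_tau_and_omega(self, prior_only_draws):
        d = prior_only_draws
        sigma = d.tau[:, :, None] * d.omega_B * d.tau[:, None, :]
        assert np.allclose(sigma[:, 0, 1], d.tau[:, 0] * d.tau[:, 1] * d.omega_B[:, 0, 1])


class TestBinomialOracle:
    def test_large_sample_pins_posterior_at_observed_rate(self):
        # one huge sample, 3% rates: Phi(theta) must land within 0.5% of 3%
        panel = ap.DisorderPanel(["a", "b"])
        ds = ap.MetaDataset(
            panel,
            [ap.AggregateSample("s", "s", 100_000, (3_000, 3_000), any_count=5_000)],
        )
        d = _quiet_fit(
            ap.fit_model1, ds, np.eye(2), priors=ap.Priors(tau_sd=0.01),
            cfg=SamplerConfig(chains=2, iterations=1000, warmup=500, seed=4),
        )
        prev = ap.inv_probit(np.median(d.theta, axis=0))
        np.testing.assert_allclose(prev, 0.03, atol=0.005)

    def test_matches_numeric_single_study_posterior(self):
        """tau -> 0 limit: Phi(theta) posterior equals the brute-force
        single-parameter binomial posterior computed by quadrature."""
        n_obs, N = 11, 160
        panel = ap.DisorderPanel(["a", "b"])
        ds = ap.MetaDataset(panel, [ap.AggregateSample("s", "s", N, (n_obs, None))])
        priors = ap.Priors(tau_sd=1e-3)  # pin heterogeneity at zero
        d = _quiet_fit(
            ap.fit_model1, ds, np.eye(2), priors=priors,
            cfg=SamplerConfig(chains=2, iterations=1500, warmup=500, seed=5),
        )

        def post_unnorm(t):
            p = stats.norm.cdf(t)
            return (
                stats.norm.pdf(t, -1.88, 0.30) * p**n_obs * (1 - p) ** (N - n_obs)
            )

        grid = np.linspace(-4, 1, 4001)
        w = post_unnorm(grid)
        w /= np.trapezoid(w, grid)
        cdf = np.concatenate([[0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))])
        q_oracle = np.interp([0.25, 0.5, 0.75], cdf, grid)
        q_mcmc = np.percentile(d.theta[:, 0], [25, 50, 75])
        np.testing.assert_allclose(q_mcmc, q_oracle, atol=0.03)

    def test_unmeasured_disorder_posterior_is_prior_predictive(self):
        # disorder b never measured, omega_B = I: mu_b marginal must match
        # theta_b + tau_b z (checked against fresh normal draws)
        panel = ap.DisorderPanel(["a", "b"])
        ds = ap.MetaDataset(panel, [ap.AggregateSample("s", "s", 400, (20, None))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = ap.fit_model1(
                ds, np.eye(2),
                cfg=SamplerConfig(chains=2, iterations=1500, warmup=500, seed=6),
            )
        rng = np.random.default_rng(0)
        ref = d.theta[:, 1] + d.tau[:, 1] * rng.standard_normal(d.n_draws)
        mu_b = d.mu[:, 0, 1]
        assert np.median(mu_b) == pytest.approx(np.median(ref), abs=0.04)
        assert mu_b.std() == pytest.approx(ref.std(), abs=0.05)


class TestClusters:
    def test_clustered_samples_share_mu(self, small_dataset):
        d = _quiet_fit(
            ap.fit_model1, small_dataset, np.eye(3),
            cfg=SamplerConfig(chains=2, iterations=300, warmup=150, seed=7),
        )
        # two clusters (c1 shared by s1+s2, c3 alone), three disorders
        assert d.mu.shape[1:] == (2, 3)
        assert d.cluster_ids == ["c1", "c3"]


class TestConvergenceReport:
    def test_well_mixed_chains_pass(self, prior_only_draws):
        table = ap.convergence_report(prior_only_draws)
        assert bool(table["pass"].all())
        assert table.loc["theta.a", "rhat"] < 1.05

    def test_disagreeing_chains_flagged(self, prior_only_draws):
        import copy

        bad = copy.deepcopy(prior_only_draws)
        half = bad.n_draws // 2
        bad.theta[half:, 0] += 5.0  # second chain far away
        table = ap.convergence_report(bad)
        assert table.loc["theta.a", "rhat"] > 1.5
        assert not table.loc["theta.a", "pass"]

    def test_constant_parameters_excluded_from_criterion(self, prior_only_draws):
        table = ap.convergence_report(prior_only_draws)
        # omega_C was fixed (Model 1): constant, excluded, but not failing
        row = table.loc["omegaC.a.b"]
        assert row["constant"] and row["pass"] and np.isnan(row["rhat"])

    def test_single_chain_rejected(self, prior_only_draws):
        import copy

        solo = copy.deepcopy(prior_only_draws)
        solo.n_chains = 1
        with pytest.raises(ValueError, match="two chains"):
            ap.convergence_report(solo)


class TestDrawsPersistence:
    def test_csv_json_round_trip(self, prior_only_draws, tmp_path):
        csv, js = tmp_path / "d.csv", tmp_path / "d.json"
        prior_only_draws.save(csv, js)
        back = ap.PosteriorDraws.load(csv, js)
        np.testing.assert_allclose(back.theta, prior_only_draws.theta)
        np.testing.assert_allclose(back.tau, prior_only_draws.tau)
        np.testing.assert_allclose(back.omega_B, prior_only_draws.omega_B)
        np.testing.assert_allclose(back.mu, prior_only_draws.mu)
        assert back.cluster_ids == prior_only_draws.cluster_ids
        assert back.n_chains == prior_only_draws.n_chains


class TestModelFrontEnd:
    def test_fit_returns_results_with_summary(self, small_dataset):
        model = ap.PrevalenceModel(small_dataset, omega_C=np.eye(3))
        res = _quiet_fit(model.fit, chains=2, iterations=300, warmup=150, seed=8)
        summ = res.summary()
        assert list(summ.index) == ["a", "b", "c"]
        assert ((summ["prev_hdi_low"] <= summ["prevalence"])
                & (summ["prevalence"] <= summ["prev_hdi_high"])).all()
        tab = res.category_table(ks=(1, 2), n_inner=200, max_draws=100,
                                 prediction_interval=False)
        assert tab.loc[0, "median"] >= tab.loc[1, "median"]

    def test_missing_omega_c_without_ipd_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="omega_C"):
            ap.PrevalenceModel(small_dataset)
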