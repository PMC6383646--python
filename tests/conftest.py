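import numpy as np
import pytest

import anyprev as ap


@pytest.fixture(scope="session")
def case_study() -> ap.MetaDataset:
    return ap.case_study_table1()


@pytest.fixture(scope="session")
def small_dataset() -> ap.MetaDataset:
    """Tiny three-disorder aggregate dataset with one two-sample cluster."""
    panel = ap.DisorderPanel(["a", "b", "c"])
    samples = [
        ap.AggregateSample("s1", "c1", 100, (5, 3, None), any_count=7),
        ap.AggregateSample("s2", "c1", 50, (2, None, 1), any_count=3),
        ap.AggregateSample("s3", "c3", 200, (9, 4, 12), any_count=20),
    ]
    return ap.MetaDataset(panel, samples)


def make_fixed_draws(theta, tau, omega_B, omega_C, n_draws=400, n_clusters=1):
    """PosteriorDraws whose every draw equals the given parameter values.

    Collapsing posterior uncertainty this way turns the category estimators
    into plain Monte-Carlo integrals with known closed-form answers.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    D = theta.size
    tau = np.broadcast_to(np.asarray(tau, dtype=float), (D,))
    mu = np.tile(theta, (n_draws, n_clusters, 1))
    return ap.PosteriorDraws(
        theta=np.tile(theta, (n_draws, 1)),
        tau=np.tile(tau, (n_draws, 1)),
        omega_B=np.tile(np.asarray(omega_B, dtype=float), (n_draws, 1, 1)),
        omega_C=np.tile(np.asarray(omega_C, dtype=float), (n_draws, 1, 1)),
        mu=mu,
        cluster_ids=[f"c{i}" for i in range(n_clusters)],
        disorder_names=[f"d{i + 1}" for i in range(D)],
        n_chains=2,
    )
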