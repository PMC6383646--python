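"""Superordinate-category quantities computed from posterior draws.

The model's parameters live on the probit scale; category-level quantities
(probability of having at least k disorders, conditional comorbidity
probabilities, per-study predictive checks) are obtained by simulating
hypothetical participants.  For a participant drawn from a random *new* study,
the latent trait is

    ytilde ~ MVN(theta, Sigma_B + omega_C),    y_d = 1{ytilde_d > 0},

since the study effect mu* ~ MVN(theta, Sigma_B) and the within-study trait
adds MVN(0, omega_C) noise.  Per posterior draw m we estimate the quantity of
interest under parameters_m (Monte Carlo over ``n_inner`` participants, or
orthant integration where exact), then summarize the per-draw values by their
median and 95% highest-density interval.  Prediction intervals instead share
one new study across all participants of a draw, so between-study
heterogeneity widens them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import MetaDataset
from .model import PosteriorDraws

__all__ = [
    "PrevalenceSummary",
    "HypotheticalCohort",
    "hdi",
    "simulate_cohort",
    "category_prevalence",
    "conditional_probability",
    "per_study_predictions",
]


@dataclass(frozen=True)
class PrevalenceSummary:
    """Median, 95% HDI and (optionally) 95% prediction interval of a prevalence."""

    median: float
    hdi_low: float
    hdi_high: float
    pi_low: Optional[float] = None
    pi_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.hdi_low <= self.median <= self.hdi_high):
            raise ValueError("median must lie inside its HDI")

    def as_row(self) -> dict:
        return {
            "median": self.median,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "pi_low": self.pi_low,
            "pi_high": self.pi_high,
        }


@dataclass
class HypotheticalCohort:
    """Simulated binary diagnoses with per-row provenance."""

    diagnoses: np.ndarray  # (n, D) of {0, 1}
    draw_index: np.ndarray  # posterior draw each participant came from
    study_index: np.ndarray  # distinct new-study effect each participant used


def hdi(samples: Iterable[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("hdi of an empty sample")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def _chols(draws: PosteriorDraws) -> tuple[np.ndarray, np.ndarray]:
    return np.linalg.cholesky(draws.omega_B), np.linalg.cholesky(draws.omega_C)


def _select_draws(n_total: int, max_draws: Optional[int]) -> np.ndarray:
    if max_draws is None or n_total <= max_draws:
        return np.arange(n_total)
    return np.linspace(0, n_total - 1, max_draws).astype(int)


def simulate_cohort(
    draws: PosteriorDraws,
    n_participants: int,
    mode: str = "one-study-per-participant",
    seed: int = 0,
) -> HypotheticalCohort:
    """Simulate hypothetical participants from the posterior.

    ``one-study-per-participant``: each participant gets their own posterior
    draw and their own new-study effect (the category-prevalence convention).
    ``one-study-per-draw``: participants are dealt round-robin across
    posterior draws and all participants of one draw share a single new study
    (the prediction-interval convention).
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if mode not in ("one-study-per-participant", "one-study-per-draw"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    M, D = draws.theta.shape
    L_B, L_C = _chols(draws)
    m_idx = rng.integers(0, M, size=n_participants)
    if mode == "one-study-per-participant":
        study_idx = np.arange(n_participants)
        z_study = rng.standard_normal((n_participants, D))
    else:
        study_idx = m_idx  # one study per posterior draw
        z_by_draw = rng.standard_normal((M, D))
        z_study = z_by_draw[m_idx]
    z_part = rng.standard_normal((n_participants, D))
    mu_star = draws.theta[m_idx] + draws.tau[m_idx] * np.einsum(
        "nde,ne->nd", L_B[m_idx], z_study
    )
    ytilde = mu_star + np.einsum("nde,ne->nd", L_C[m_idx], z_part)
    return HypotheticalCohort(
        diagnoses=(ytilde > 0).astype(np.int8),
        draw_index=m_idx,
        study_index=study_idx,
    )


def _per_draw_prevalence(
    draws: PosteriorDraws,
    k: int,
    n_inner: int,
    rng: np.random.Generator,
    share_study: bool,
    idx: np.ndarray,
    chunk: int = 128,
) -> np.ndarray:
    """P(participant has >= k disorders | parameters_m) for each draw m in idx."""
    D = draws.D
    L_B, L_C = _chols(draws)
    out = np.empty(idx.size)
    for lo in range(0, idx.size, chunk):
        sel = idx[lo:lo + chunk]
        c = sel.size
        if share_study:
            z_study = rng.standard_normal((c, 1, D))
        else:
            z_study = rng.standard_normal((c, n_inner, D))
        z_part = rng.standard_normal((c, n_inner, D))
        mu_star = draws.theta[sel, None, :] + draws.tau[sel, None, :] * np.einsum(
            "mde,mne->mnd", L_B[sel], z_study
        )
        ytilde = mu_star + np.einsum("mde,mne->mnd", L_C[sel], z_part)
        n_dis = (ytilde > 0).sum(axis=2)
        out[lo:lo + c] = (n_dis >= k).mean(axis=1)
    return out


def category_prevalence(
    draws: PosteriorDraws,
    k: int = 1,
    n_inner: int = 1000,
    seed: int = 0,
    max_draws: Optional[int] = 5000,
    prediction_interval: bool = True,
) -> PrevalenceSummary:
    """Prevalence of having at least ``k`` of the D disorders.

    Per posterior draw, the probability is estimated by Monte Carlo over
    ``n_inner`` hypothetical participants, each from their own new study; the
    summary is the median and 95% HDI across draws.  The prediction interval
    repeats the computation with one shared new study per draw, describing
    the category prevalence expected in a single new study.
    """
    if not 1 <= k <= draws.D:
        raise ValueError(f"k must be in [1, {draws.D}]")
    rng = np.random.default_rng(seed)
    idx = _select_draws(draws.n_draws, max_draws)
    pi = _per_draw_prevalence(draws, k, n_inner, rng, False, idx)
    lo, hi = hdi(pi)
    pi_lo = pi_hi = None
    if prediction_interval:
        pi_new = _per_draw_prevalence(draws, k, n_inner, rng, True, idx)
        pi_lo, pi_hi = hdi(pi_new)
    return PrevalenceSummary(float(np.median(pi)), lo, hi, pi_lo, pi_hi)


def _orthant_prob(mean: np.ndarray, cov: np.ndarray) -> float:
    """P(X_j > 0 for all j) for X ~ MVN(mean, cov)."""
    if mean.size == 1:
        return float(stats.norm.cdf(mean[0] / np.sqrt(cov[0, 0])))
    # by symmetry P(N(mean, cov) > 0) = P(N(0, cov) < mean)
    return float(
        stats.multivariate_normal(mean=np.zeros(mean.size), cov=cov,
                                  allow_singular=True).cdf(mean)
    )


def conditional_probability(
    draws: PosteriorDraws,
    given: Sequence[int | str],
    target: int | str,
    n_inner: int = 1000,
    seed: int = 0,
    max_draws: Optional[int] = 2000,
    method: str = "auto",
    prediction_interval: bool = True,
) -> PrevalenceSummary:
    """P(target disorder | all disorders in ``given``) for a random new study's participant.

    Disorders may be named or indexed.  Per posterior draw the probability is
    the ratio P(target and given) / P(given) under the marginal latent
    distribution MVN(theta, Sigma_B + omega_C); small conditioning sets use
    numerical orthant integration, larger ones Monte Carlo (with the orthant
    fallback whenever the denominator is degenerate, so the result is never
    silently undefined).  The prediction interval conditions on a single new
    study per draw (covariance omega_C around its mu*).
    """

    def _resolve(d) -> int:
        return draws.disorder_names.index(d) if isinstance(d, str) else int(d)

    g = [_resolve(d) for d in given]
    t = _resolve(target)
    if not g:
        raise ValueError("conditioning set must be non-empty")
    if t in g:
        raise ValueError("target must not be part of the conditioning set")
    if len(set(g)) != len(g):
        raise ValueError("duplicate disorders in conditioning set")
    if method not in ("auto", "orthant", "mc"):
        raise ValueError(f"unknown method {method!r}")
    use_orthant = method == "orthant" or (method == "auto" and len(g) + 1 <= 4)
    rng = np.random.default_rng(seed)
    idx = _select_draws(draws.n_draws, max_draws)
    both = np.array(g + [t])
    onlyg = np.array(g)

    Sigma_B = draws.tau[:, :, None] * draws.omega_B * draws.tau[:, None, :]
    marg_cov = Sigma_B + draws.omega_C

    def draw_value(m: int, cov: np.ndarray, mean: np.ndarray) -> float:
        num = _orthant_prob(mean[both], cov[np.ix_(both, both)])
        den = _orthant_prob(mean[onlyg], cov[np.ix_(onlyg, onlyg)])
        return num / den if den > 0 else 0.0

    values = np.empty(idx.size)
    if use_orthant:
        for j, m in enumerate(idx):
            values[j] = draw_value(m, marg_cov[m], draws.theta[m])
    else:
        L_B, L_C = _chols(draws)
        for j, m in enumerate(idx):
            n = n_inner
            val = None
            for _ in range(4):  # double n until the denominator is populated
                z1 = rng.standard_normal((n, draws.D))
                z2 = rng.standard_normal((n, draws.D))
                y = (
                    draws.theta[m]
                    + draws.tau[m] * (z1 @ L_B[m].T)
                    + z2 @ L_C[m].T
                ) > 0
                den = y[:, onlyg].all(axis=1)
                if den.sum() > 0:
                    val = float(y[den][:, t].mean())
                    break
                n *= 2
            if val is None:  # orthant fallback, never NaN
                val = draw_value(m, marg_cov[m], draws.theta[m])
            values[j] = val
    lo, hi = hdi(values)
    pi_lo = pi_hi = None
    if prediction_interval:
        # one new study per posterior draw: condition within that study
        L_B = np.linalg.cholesky(draws.omega_B)
        z = rng.standard_normal((idx.size, draws.D))
        mu_star = draws.theta[idx] + draws.tau[idx] * np.einsum(
            "mde,me->md", L_B[idx], z
        )
        pvals = np.empty(idx.size)
        for j, m in enumerate(idx):
            num = _orthant_prob(mu_star[j][both], draws.omega_C[m][np.ix_(both, both)])
            den = _orthant_prob(mu_star[j][onlyg], draws.omega_C[m][np.ix_(onlyg, onlyg)])
            pvals[j] = num / den if den > 0 else 0.0
        pi_lo, pi_hi = hdi(pvals)
    med = float(np.median(values))
    return PrevalenceSummary(med, min(lo, med), max(hi, med), pi_lo, pi_hi)


def per_study_predictions(
    draws: PosteriorDraws,
    data: MetaDataset,
    mode: str = "per-disorder",
    seed: int = 0,
    max_draws: Optional[int] = 1000,
) -> pd.DataFrame:
    """Posterior-predictive prevalence for every sample (the Figure 2/3 check).

    For each sample, ``N_s`` participants are simulated per posterior draw
    from that sample's cluster-level ``mu`` draws and the comorbidity matrix.
    ``per-disorder`` reports each disorder's simulated prevalence (including
    disorders the sample never measured — predictions for them); ``any-measured``
    reports the prevalence of having at least one of the disorders the sample
    actually measured, the sample's own operationalization of the category.
    """
    if mode not in ("per-disorder", "any-measured"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    idx = _select_draws(draws.n_draws, max_draws)
    cindex = {cid: i for i, cid in enumerate(draws.cluster_ids)}
    L_C = np.linalg.cholesky(draws.omega_C)
    rows = []
    for s in data.samples:
        if s.cluster_id not in cindex:
            raise ValueError(f"sample {s.sample_id} has no fitted cluster")
        c = cindex[s.cluster_id]
        n = max(s.N, 1)
        mu = draws.mu[idx, c, :]  # (M, D)
        # simulate counts in draw-chunks to bound memory
        chunk = max(1, int(2_000_000 / max(n, 1)))
        if mode == "per-disorder":
            prev = np.empty((idx.size, draws.D))
        else:
            prev = np.empty(idx.size)
            measured = np.where(s.measured_mask)[0]
        for lo in range(0, idx.size, chunk):
            sel = slice(lo, min(lo + chunk, idx.size))
            c_sz = prev[sel].shape[0]
            z = rng.standard_normal((c_sz, n, draws.D))
            y = (
                mu[sel][:, None, :] + np.einsum("mde,mne->mnd", L_C[idx[sel]], z)
            ) > 0
            if mode == "per-disorder":
                prev[sel] = y.mean(axis=1)
            else:
                prev[sel] = y[:, :, measured].any(axis=2).mean(axis=1)
        if mode == "per-disorder":
            for d, name in enumerate(data.panel.names):
                lo_, hi_ = hdi(prev[:, d])
                obs = s.counts[d]
                rows.append({
                    "sample_id": s.sample_id,
                    "quantity": name,
                    "observed": None if obs is None else obs / s.N,
                    "median": float(np.median(prev[:, d])),
                    "hdi_low": lo_,
                    "hdi_high": hi_,
                })
        else:
            lo_, hi_ = hdi(prev)
            rows.append({
                "sample_id": s.sample_id,
                "quantity": "any_measured",
                "observed": None if s.any_count is None else s.any_count / s.N,
                "median": float(np.median(prev)),
                "hdi_low": lo_,
                "hdi_high": hi_,
            })
    return pd.DataFrame(rows)
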