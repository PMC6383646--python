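"""Hierarchical Bayesian multivariate prevalence model.

The model estimates, for a panel of D disorders, the probit-scale mean
prevalence ``theta_d``, the between-study SD ``tau_d``, the between-study
correlation ``omega_B`` of study-level effects, and (with IPD) the latent
within-study comorbidity correlation ``omega_C``:

* between studies: ``mu_{s,*} ~ MVN(theta, Sigma_B)`` with
  ``Sigma_B[d,d'] = tau_d omega_B[d,d'] tau_d'``; samples from the same
  parent study (equal ``cluster_id``) share one ``mu`` vector;
* aggregate likelihood: ``n_{s,d} ~ Binomial(N_s, Phi(mu_{s,d}))``
  independently across measured disorders given ``mu``;
* IPD likelihood (Model 2): the per-participant binary diagnoses are
  dichotomizations at zero of a latent trait
  ``ytilde_{s,*,i} ~ MVN(mu_{s,*}, omega_C)`` with unit variances, replacing
  the aggregate binomial for those samples; latent traits of unmeasured
  disorders are integrated out.

Priors: ``theta_d ~ N(-1.88, 0.30^2)`` (population prevalences of roughly
0.6%-10% probable within 2 SD), ``tau_d ~ half-N(0.25)``, and LKJ(2) on the
Cholesky factors of both correlation matrices.

Model 1 (aggregate only) treats ``omega_C`` as known and carries it through
unchanged; Model 2 estimates it from the IPD.  Sampling is by the package's
own NUTS kernel; Model 2 augments it with a truncated-normal Gibbs sweep over
the latent traits between transitions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.linalg import solve_triangular

from ._nuts import sample_chain
from ._transforms import (
    _constrain_batch,
    chol_corr_with_grad,
)
from .data import MetaDataset

__all__ = [
    "Priors",
    "SamplerConfig",
    "PosteriorDraws",
    "fit_model1",
    "fit_model2",
    "convergence_report",
    "PrevalenceModel",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _truncnorm_onesided(mean, scale, alpha, positive, rng):
    """Draw from N(mean, scale^2) truncated to >0 (positive) or <0 (not).

    ``alpha = -mean/scale`` is the standardized threshold.  Inverse-CDF
    sampling in the well-conditioned tail direction; the rare extreme
    thresholds fall back to scipy's rejection sampler.
    """
    u = rng.uniform(size=mean.shape)
    out = np.empty_like(mean)
    ok = np.abs(alpha) < 6.0
    a = alpha[ok]
    if positive:
        # z in (a, inf): z = ndtri_sf( sf(a) * (1-u) ) via symmetry
        sf_a = special.ndtr(-a)
        z = -special.ndtri(sf_a * (1.0 - u[ok]))
    else:
        cdf_a = special.ndtr(a)
        z = special.ndtri(cdf_a * u[ok])
    out[ok] = mean[ok] + scale * z
    if not ok.all():
        bad = ~ok
        lo = alpha[bad] if positive else -np.inf
        hi = np.inf if positive else alpha[bad]
        out[bad] = stats.truncnorm.rvs(lo, hi, loc=mean[bad], scale=scale,
                                       random_state=rng)
    return out


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the mildly informative default priors."""

    theta_mean: float = -1.88
    theta_sd: float = 0.30
    tau_sd: float = 0.25
    lkj_shape: float = 2.0

    def __post_init__(self) -> None:
        if self.theta_sd <= 0 or self.tau_sd <= 0 or self.lkj_shape <= 0:
            raise ValueError("prior scales and LKJ shape must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC protocol: per-chain totals, warmup, chain count, seed."""

    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    seed: int = 0
    max_depth: int = 8
    target_accept: float = 0.8
    dense_mass: bool = False

    def __post_init__(self) -> None:
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")
        if self.chains < 2:
            raise ValueError("at least two chains are required for diagnostics")

    @property
    def draws_per_chain(self) -> int:
        return self.iterations - self.warmup


def _check_correlation(mat: np.ndarray, D: int, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (D, D):
        raise ValueError(f"{name} must be {D}x{D}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have a unit diagonal")
    if np.linalg.eigvalsh(mat).min() <= 0:
        raise ValueError(f"{name} must be positive definite")
    return mat


@dataclass
class PosteriorDraws:
    """Pooled post-warmup draws of all model parameters, with chain metadata."""

    theta: np.ndarray  # (M, D)
    tau: np.ndarray  # (M, D)
    omega_B: np.ndarray  # (M, D, D)
    omega_C: np.ndarray  # (M, D, D)
    mu: np.ndarray  # (M, C, D)
    cluster_ids: list[str]
    disorder_names: list[str]
    n_chains: int
    n_divergent: int = 0
    accept_stat: float = float("nan")
    diagnostics: Optional[pd.DataFrame] = None
    converged: Optional[bool] = None

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    @property
    def D(self) -> int:
        return self.theta.shape[1]

    def by_chain(self, arr: np.ndarray) -> np.ndarray:
        """Reshape a pooled (M, ...) array to (chains, draws_per_chain, ...)."""
        m = arr.shape[0] // self.n_chains
        return arr.reshape((self.n_chains, m) + arr.shape[1:])

    def to_frame(self) -> pd.DataFrame:
        """Columnar layout: one row per draw, labeled parameter columns."""
        cols: dict[str, np.ndarray] = {}
        names = self.disorder_names
        for d, nm in enumerate(names):
            cols[f"theta.{nm}"] = self.theta[:, d]
        for d, nm in enumerate(names):
            cols[f"tau.{nm}"] = self.tau[:, d]
        for a in range(self.D):
            for b in range(a + 1, self.D):
                cols[f"omegaB.{names[a]}.{names[b]}"] = self.omega_B[:, a, b]
        for a in range(self.D):
            for b in range(a + 1, self.D):
                cols[f"omegaC.{names[a]}.{names[b]}"] = self.omega_C[:, a, b]
        for c, cid in enumerate(self.cluster_ids):
            for d, nm in enumerate(names):
                cols[f"mu.{cid}.{nm}"] = self.mu[:, c, d]
        return pd.DataFrame(cols)

    def save(self, csv_path: str | Path, json_path: Optional[str | Path] = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            meta = {
                "disorders": self.disorder_names,
                "clusters": self.cluster_ids,
                "n_chains": self.n_chains,
                "n_divergent": int(self.n_divergent),
                "accept_stat": float(self.accept_stat),
                "converged": self.converged,
                "diagnostics": (
                    None
                    if self.diagnostics is None
                    else self.diagnostics.reset_index()
                    .rename(columns={"index": "parameter"})
                    .to_dict(orient="records")
                ),
            }
            Path(json_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, csv_path: str | Path, json_path: str | Path) -> "PosteriorDraws":
        df = pd.read_csv(csv_path)
        meta = json.loads(Path(json_path).read_text())
        names = meta["disorders"]
        clusters = meta["clusters"]
        D, C, M = len(names), len(clusters), len(df)
        theta = df[[f"theta.{n}" for n in names]].to_numpy()
        tau = df[[f"tau.{n}" for n in names]].to_numpy()

        def corr(prefix: str) -> np.ndarray:
            out = np.repeat(np.eye(D)[None], M, axis=0)
            for a in range(D):
                for b in range(a + 1, D):
                    v = df[f"{prefix}.{names[a]}.{names[b]}"].to_numpy()
                    out[:, a, b] = out[:, b, a] = v
            return out

        mu = np.empty((M, C, D))
        for c, cid in enumerate(clusters):
            for d, n in enumerate(names):
                mu[:, c, d] = df[f"mu.{cid}.{n}"].to_numpy()
        return cls(
            theta=theta, tau=tau, omega_B=corr("omegaB"), omega_C=corr("omegaC"),
            mu=mu, cluster_ids=clusters, disorder_names=list(names),
            n_chains=int(meta["n_chains"]), n_divergent=int(meta["n_divergent"]),
            accept_stat=float(meta["accept_stat"]), converged=meta.get("converged"),
        )


# ---------------------------------------------------------------------------
# posterior densities


class _AggregatePosterior:
    """Unconstrained-space posterior of Model 1 (aggregate data only).

    Study-level effects use a non-centered parameterization
    (``mu_c = theta + diag(tau) L_B z_c``) by default, which suits weakly
    informative aggregate counts; clusters named in ``centered_clusters``
    parameterize ``mu_c`` directly (centered), which suits clusters whose
    likelihood pins ``mu`` tightly — e.g. IPD blocks with many participants.
    """

    def __init__(self, data: MetaDataset, omega_C: np.ndarray, priors: Priors,
                 aggregate_samples: Optional[list[str]] = None,
                 centered_clusters: Optional[set[str]] = None):
        data.panel.require_multivariate()
        self.priors = priors
        self.D = len(data.panel)
        self.clusters = data.cluster_ids
        self.C = len(self.clusters)
        cindex = {cid: i for i, cid in enumerate(self.clusters)}
        self.sample_cluster = {s.sample_id: cindex[s.cluster_id] for s in data.samples}
        obs_c, obs_d, obs_n, obs_N = [], [], [], []
        include = set(
            s.sample_id for s in data.samples
        ) if aggregate_samples is None else set(aggregate_samples)
        observed_any = np.zeros(self.D, dtype=bool)
        for s in data.samples:
            for d, cnt in enumerate(s.counts):
                if cnt is not None:
                    observed_any[d] = True
            if s.sample_id not in include:
                continue
            for d, cnt in enumerate(s.counts):
                if cnt is None or s.N == 0:
                    continue
                obs_c.append(cindex[s.cluster_id])
                obs_d.append(d)
                obs_n.append(cnt)
                obs_N.append(s.N)
        self.obs_c = np.array(obs_c, dtype=int)
        self.obs_d = np.array(obs_d, dtype=int)
        self.obs_n = np.array(obs_n, dtype=float)
        self.obs_N = np.array(obs_N, dtype=float)
        for d, seen in enumerate(observed_any):
            if not seen:
                warnings.warn(
                    f"disorder '{data.panel.names[d]}' observed in no sample; "
                    "its posterior will reproduce the prior"
                )
        self.omega_C = _check_correlation(omega_C, self.D, "omega_C")
        centered_clusters = centered_clusters or set()
        self.centered = np.array([cid in centered_clusters for cid in self.clusters])
        self.m = self.D * (self.D - 1) // 2
        self.dim = 2 * self.D + self.m + self.C * self.D
        self._zoff = 2 * self.D + self.m

    # layout: [theta(D), log tau(D), y_B(m), Z(C*D)]
    def split(self, x: np.ndarray):
        D, m = self.D, self.m
        return (
            x[:D],
            x[D:2 * D],
            x[2 * D:2 * D + m],
            x[self._zoff:self._zoff + self.C * D].reshape(self.C, D),
        )

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        D, m = self.D, self.m
        x = np.empty(self.dim)
        x[:D] = self.priors.theta_mean + 0.3 * rng.standard_normal(D)
        x[D:2 * D] = np.log(0.5 * self.priors.tau_sd) + 0.2 * rng.standard_normal(D)
        x[2 * D:2 * D + m] = 0.1 * rng.standard_normal(m)
        W = 0.2 * rng.standard_normal((self.C, D))
        W[self.centered] = x[:D] + 0.2 * rng.standard_normal(
            (int(self.centered.sum()), D)
        )
        x[self._zoff:] = W.ravel()
        return x

    def _binomial_part(self, mu: np.ndarray):
        """Log-likelihood and d(loglik)/d(mu) accumulated per (cluster, disorder)."""
        G = np.zeros((self.C, self.D))
        if self.obs_c.size == 0:
            return 0.0, G
        mu_obs = mu[self.obs_c, self.obs_d]
        log_phi = -0.5 * mu_obs**2 - _LOG_SQRT_2PI
        log_cdf = special.log_ndtr(mu_obs)
        log_sf = special.log_ndtr(-mu_obs)
        ll = float(np.sum(self.obs_n * log_cdf + (self.obs_N - self.obs_n) * log_sf))
        g = self.obs_n * np.exp(log_phi - log_cdf) - (
            self.obs_N - self.obs_n
        ) * np.exp(log_phi - log_sf)
        np.add.at(G, (self.obs_c, self.obs_d), g)
        return ll, G

    def _extra_loglik(self, mu, L_C):
        """Hook for the IPD likelihood; Model 1 contributes nothing."""
        return 0.0, None, None

    def logp_grad(self, x: np.ndarray):
        pr = self.priors
        if not np.all(np.isfinite(x)):
            return -np.inf, np.zeros_like(x)
        theta, lam, yB, W = self.split(x)
        # exp overflow / numerically degenerate tau: negligible posterior mass,
        # rejected outright so downstream linear algebra stays finite
        if np.any(lam > 10.0) or np.any(lam < -30.0):
            return -np.inf, np.zeros_like(x)
        tau = np.exp(lam)
        L_B, dL_B, lkj_lp, lkj_g = chol_corr_with_grad(yB, self.D, pr.lkj_shape)
        L_Sig = tau[:, None] * L_B
        cen = self.centered
        Z = W[~cen]  # non-centered standard-normal effects
        mu = np.empty((self.C, self.D))
        mu[~cen] = theta[None, :] + Z @ L_Sig.T
        mu[cen] = W[cen]

        ll, G = self._binomial_part(mu)
        extra_ll, extra_G, dyC = self._extra_loglik(mu, self._L_C(x))
        if extra_G is not None:
            G = G + extra_G
        ll += extra_ll

        logp = (
            ll
            - 0.5 * float(np.sum(((theta - pr.theta_mean) / pr.theta_sd) ** 2))
            - 0.5 * float(np.sum((tau / pr.tau_sd) ** 2))
            + float(np.sum(lam))  # log-Jacobian of tau = exp(lam)
            + lkj_lp
            - 0.5 * float(np.sum(Z**2))
        )

        grad = np.empty_like(x)
        D, m = self.D, self.m
        dtheta = G[~cen].sum(axis=0) - (theta - pr.theta_mean) / pr.theta_sd**2
        dtau = (G[~cen] * (Z @ L_B.T)).sum(axis=0) - tau / pr.tau_sd**2
        G_LB = tau[:, None] * (G[~cen].T @ Z)
        dW = np.empty_like(W)
        dW[~cen] = G[~cen] @ L_Sig - Z

        if cen.any():
            # MVN(theta, Sigma_B) prior density of the centered mu_c
            if np.any(np.diag(L_Sig) < 1e-12):
                return -np.inf, np.zeros_like(x)
            n_cen = int(cen.sum())
            R = mu[cen] - theta[None, :]
            U = solve_triangular(L_Sig, R.T, lower=True).T
            Wsol = solve_triangular(L_Sig.T, U.T, lower=False).T  # Sigma^-1 r_c
            logp += -n_cen * float(np.sum(np.log(np.diag(L_Sig)))) \
                - 0.5 * float(np.sum(U**2))
            dW[cen] = G[cen] - Wsol
            dtheta += Wsol.sum(axis=0)
            Sig_inv = solve_triangular(
                L_Sig.T, solve_triangular(L_Sig, np.eye(D), lower=True), lower=False
            )
            G_Sig = 0.5 * (Wsol.T @ Wsol - n_cen * Sig_inv)
            G_LSig = 2.0 * np.tril(G_Sig @ L_Sig)
            dtau += (G_LSig * L_B).sum(axis=1)
            G_LB += tau[:, None] * G_LSig

        grad[:D] = dtheta
        grad[D:2 * D] = dtau * tau + 1.0
        grad[2 * D:2 * D + m] = np.einsum("kde,de->k", dL_B, G_LB) + lkj_g
        grad[self._zoff:self._zoff + self.C * D] = dW.ravel()
        self._finish_grad(x, grad, dyC)
        return logp, grad

    def _L_C(self, x):
        return None

    def _finish_grad(self, x, grad, dyC):
        return

    def unpack(self, draws: np.ndarray) -> dict[str, np.ndarray]:
        """Constrain a (M, dim) array of raw draws."""
        D, m, C = self.D, self.m, self.C
        theta = draws[:, :D]
        tau = np.exp(draws[:, D:2 * D])
        L_B, _ = _constrain_batch(draws[:, 2 * D:2 * D + m], D)
        omega_B = L_B @ np.swapaxes(L_B, -1, -2)
        Wall = draws[:, self._zoff:self._zoff + C * D].reshape(-1, C, D)
        L_Sig = tau[:, :, None] * L_B
        mu = theta[:, None, :] + np.einsum("mef,mcf->mce", L_Sig, Wall)
        mu[:, self.centered, :] = Wall[:, self.centered, :]
        omega_C = np.repeat(self.omega_C[None], draws.shape[0], axis=0)
        return {"theta": theta, "tau": tau, "omega_B": omega_B,
                "omega_C": omega_C, "mu": mu}


class _IPDPosterior(_AggregatePosterior):
    """Model 2: aggregate likelihood plus latent multivariate-probit IPD blocks.

    The latent traits are not part of the NUTS state; they are resampled by a
    truncated-normal Gibbs sweep between transitions (data augmentation) and
    the NUTS kernel targets the conditional posterior given them.
    """

    def __init__(self, data: MetaDataset, priors: Priors):
        if not data.ipd:
            raise ValueError("Model 2 requires at least one IPD block")
        ipd_ids = [b.sample_id for b in data.ipd]
        aggregate_only = [s.sample_id for s in data.samples if s.sample_id not in ipd_ids]
        ipd_clusters = {
            s.cluster_id for s in data.samples if s.sample_id in ipd_ids
        }
        # IPD samples drop out of the binomial part: their likelihood is the
        # latent MVN, everything else enters as aggregate counts.  Clusters
        # with IPD use the centered parameterization (their mu is data-pinned).
        super().__init__(
            data, omega_C=np.eye(len(data.panel)), priors=priors,
            aggregate_samples=aggregate_only, centered_clusters=ipd_clusters,
        )
        self.blocks = []
        for b in data.ipd:
            M = np.where(b.measured_mask)[0]
            y = b.diagnoses[:, M].astype(bool)
            self.blocks.append({
                "cluster": self.sample_cluster[b.sample_id],
                "measured": M,
                "y": y,
                "latent": np.where(y, 0.5, -0.5).astype(float),  # Gibbs state
            })
        self.dim += self.m
        self._yc_off = 2 * self.D + self.m
        self._zoff = self._yc_off + self.m

    # layout: [theta(D), log tau(D), y_B(m), y_C(m), Z(C*D)]
    def initial(self, rng: np.random.Generator) -> np.ndarray:
        x = super().initial(rng)  # fills everything except the y_C slots
        x[self._yc_off:self._yc_off + self.m] = 0.1 * rng.standard_normal(self.m)
        return x

    def _L_C(self, x):
        yC = x[self._yc_off:self._yc_off + self.m]
        L_C, dL_C, lkj_lp, lkj_g = chol_corr_with_grad(yC, self.D, self.priors.lkj_shape)
        self._cache_C = (L_C, dL_C, lkj_lp, lkj_g)
        return L_C

    def _extra_loglik(self, mu, L_C):
        omega = L_C @ L_C.T
        ll = self._cache_C[2]  # LKJ prior + Jacobian for y_C
        G = np.zeros((self.C, self.D))
        G_om = np.zeros((self.D, self.D))
        for blk in self.blocks:
            M = blk["measured"]
            c = blk["cluster"]
            sub = omega[np.ix_(M, M)]
            sign, logdet = np.linalg.slogdet(sub)
            if sign <= 0 or logdet < -40:  # numerically singular: reject state
                return -np.inf, None, np.zeros(self.m)
            try:
                P = np.linalg.inv(sub)
            except np.linalg.LinAlgError:
                return -np.inf, None, np.zeros(self.m)
            resid = blk["latent"] - mu[c, M][None, :]
            n = resid.shape[0]
            S = resid.T @ resid
            ll += -0.5 * n * logdet - 0.5 * float(np.sum(P * S))
            G[c, M] += P @ resid.sum(axis=0)
            H = 0.5 * (P @ S @ P - n * P)
            G_om[np.ix_(M, M)] += H
        G_LC = 2.0 * (G_om @ L_C)
        dyC = np.einsum("kde,de->k", self._cache_C[1], G_LC) + self._cache_C[3]
        return ll, G, dyC

    def _finish_grad(self, x, grad, dyC):
        grad[self._yc_off:self._yc_off + self.m] = dyC

    gibbs_sweeps: int = 2

    def gibbs_update(self, x: np.ndarray, rng: np.random.Generator) -> None:
        """Truncated-normal Gibbs sweeps over all latent traits."""
        theta, lam, yB, Z = self.split(x)
        tau = np.exp(lam)
        from ._transforms import chol_corr_constrain

        L_B = chol_corr_constrain(yB, self.D)
        L_C = chol_corr_constrain(x[self._yc_off:self._yc_off + self.m], self.D)
        omega = L_C @ L_C.T
        mu = theta[None, :] + Z @ (tau[:, None] * L_B).T
        mu[self.centered] = Z[self.centered]
        for blk in self.blocks:
            M = blk["measured"]
            mu_M = mu[blk["cluster"], M]
            P = np.linalg.inv(omega[np.ix_(M, M)])
            lat = blk["latent"]
            resid = lat - mu_M[None, :]
            for _ in range(self.gibbs_sweeps):
                for j in range(len(M)):
                    s = 1.0 / np.sqrt(P[j, j])
                    b = resid @ P[:, j] - P[j, j] * resid[:, j]
                    mean = mu_M[j] - b / P[j, j]
                    pos = blk["y"][:, j]
                    draw = np.empty(lat.shape[0])
                    alpha = -mean / s  # standardized threshold
                    if pos.any():
                        draw[pos] = _truncnorm_onesided(mean[pos], s, alpha[pos],
                                                        True, rng)
                    if (~pos).any():
                        draw[~pos] = _truncnorm_onesided(mean[~pos], s, alpha[~pos],
                                                         False, rng)
                    lat[:, j] = draw
                    resid[:, j] = draw - mu_M[j]

    def unpack(self, draws: np.ndarray) -> dict[str, np.ndarray]:
        out = super().unpack(draws)
        L_C, _ = _constrain_batch(draws[:, self._yc_off:self._yc_off + self.m], self.D)
        out["omega_C"] = L_C @ np.swapaxes(L_C, -1, -2)
        return out


# ---------------------------------------------------------------------------
# fitting and diagnostics


def _run(posterior, data: MetaDataset, cfg: SamplerConfig) -> PosteriorDraws:
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    all_draws = []
    n_div = 0
    accepts = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        res = sample_chain(
            posterior,
            n_warmup=cfg.warmup,
            n_draws=cfg.draws_per_chain,
            rng=rng,
            max_depth=cfg.max_depth,
            target_accept=cfg.target_accept,
            dense_mass=cfg.dense_mass,
        )
        all_draws.append(res.draws)
        n_div += res.n_divergent
        accepts.append(res.accept_stat)
    raw = np.concatenate(all_draws, axis=0)
    parts = posterior.unpack(raw)
    draws = PosteriorDraws(
        theta=parts["theta"], tau=parts["tau"], omega_B=parts["omega_B"],
        omega_C=parts["omega_C"], mu=parts["mu"],
        cluster_ids=list(posterior.clusters),
        disorder_names=list(data.panel.names),
        n_chains=cfg.chains, n_divergent=n_div,
        accept_stat=float(np.mean(accepts)),
    )
    table = convergence_report(draws)
    draws.diagnostics = table
    draws.converged = bool(table["pass"].all())
    if not draws.converged:
        bad = table[~table["pass"]]
        warnings.warn(
            "sampler did not meet convergence thresholds "
            f"(R-hat <= 1.05, ESS >= 200) for {len(bad)} parameter(s); "
            "inspect draws.diagnostics",
            RuntimeWarning,
        )
    return draws


def fit_model1(
    data: MetaDataset,
    omega_C_known: np.ndarray,
    priors: Priors = Priors(),
    cfg: SamplerConfig = SamplerConfig(),
) -> PosteriorDraws:
    """Fit the aggregate-only model with a known comorbidity matrix."""
    post = _AggregatePosterior(data, omega_C_known, priors)
    if post.obs_c.size == 0 and not any(s.N > 0 for s in data.samples):
        pass  # prior-only run with N=0 samples is legal
    elif post.obs_c.size == 0:
        raise ValueError("no observed disorder counts to fit")
    return _run(post, data, cfg)


def fit_model2(
    data: MetaDataset,
    priors: Priors = Priors(),
    cfg: SamplerConfig = SamplerConfig(),
) -> PosteriorDraws:
    """Fit the combined aggregate + IPD model, estimating omega_C."""
    post = _IPDPosterior(data, priors)
    return _run(post, data, cfg)


def convergence_report(draws: PosteriorDraws) -> pd.DataFrame:
    """Split-R-hat and effective sample size for every reported parameter.

    Parameters that are constant across draws (e.g. the known ``omega_C`` of
    Model 1) are excluded from the pass criterion, which requires
    R-hat <= 1.05 and bulk ESS >= 200 everywhere else.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("diagnostics require at least two chains")
    frame = draws.to_frame()
    rows = []
    for name, col in frame.items():
        arr = draws.by_chain(col.to_numpy())
        if np.allclose(arr, arr.flat[0]):
            rows.append((name, np.nan, np.nan, True, True))
            continue
        rhat = float(az.rhat(arr))
        ess = float(az.ess(arr))
        ok = (rhat <= 1.05) and (ess >= 200)
        rows.append((name, rhat, ess, ok, False))
    table = pd.DataFrame(
        rows, columns=["parameter", "rhat", "ess", "pass", "constant"]
    ).set_index("parameter")
    return table


class PrevalenceModel:
    """Multivariate superordinate-category prevalence model.

    statsmodels-style front end: construct from a :class:`MetaDataset`, call
    :meth:`fit`, get a :class:`~anyprev.results.PrevalenceResults` carrying
    the posterior draws, diagnostics and the category-level estimators.

    Parameters
    ----------
    data : MetaDataset
    omega_C : known comorbidity correlation matrix (required when the dataset
        has no IPD; ignored when IPD are present unless ``use_ipd=False``)
    priors : prior hyperparameters
    use_ipd : fit the latent-correlation model when IPD blocks exist
    """

    def __init__(
        self,
        data: MetaDataset,
        omega_C: Optional[np.ndarray] = None,
        priors: Priors = Priors(),
        use_ipd: bool = True,
    ):
        data.panel.require_multivariate()
        self.data = data
        self.priors = priors
        self.use_ipd = use_ipd and bool(data.ipd)
        if not self.use_ipd and omega_C is None:
            raise ValueError(
                "without IPD the comorbidity matrix omega_C must be supplied"
            )
        self.omega_C = None if self.use_ipd else _check_correlation(
            np.asarray(omega_C, dtype=float), len(data.panel), "omega_C"
        )

    def fit(
        self,
        chains: int = 4,
        iterations: int = 5000,
        warmup: int = 2500,
        seed: int = 0,
        **kwargs,
    ):
        from .results import PrevalenceResults

        cfg = SamplerConfig(
            chains=chains, iterations=iterations, warmup=warmup, seed=seed, **kwargs
        )
        if self.use_ipd:
            draws = fit_model2(self.data, self.priors, cfg)
        else:
            draws = fit_model1(self.data, self.omega_C, self.priors, cfg)
        return PrevalenceResults(self, draws)
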