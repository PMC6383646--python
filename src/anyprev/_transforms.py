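"""Link functions and unconstrained parameterizations used by the sampler.

Correlation matrices are parameterized through the canonical-partial-
correlation construction of their Cholesky factor: m = D(D-1)/2 unconstrained
reals ``y`` map through ``z = tanh(y)`` to a valid lower-triangular factor
``L`` with unit-norm rows.  The LKJ(eta) density is evaluated directly on
``L`` and combined with the log-Jacobian of the map so the sampler works on
an unconstrained space.  Derivatives of the construction are obtained by
complex-step differentiation, which is exact to machine precision for this
analytic map.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "probit",
    "inv_probit",
    "prior_prevalence_range",
    "implied_study_range",
    "chol_corr_constrain",
    "chol_corr_unconstrain",
    "chol_corr_with_grad",
]


def probit(p):
    """Probit transform Phi^{-1}(p); defined for p strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probit requires 0 < p < 1")
    out = special.ndtri(p)
    return float(out) if out.ndim == 0 else out


def inv_probit(z):
    """Standard normal CDF Phi(z)."""
    out = special.ndtr(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def prior_prevalence_range(theta_mean: float, theta_sd: float, k: float = 2.0):
    """Prevalence band implied by a probit-scale N(theta_mean, theta_sd^2) prior.

    Returns (Phi(mean - k sd), Phi(mean + k sd)) — the range of population
    prevalences considered probable within k prior standard deviations.
    """
    if theta_sd < 0:
        raise ValueError("theta_sd must be nonnegative")
    return (
        inv_probit(theta_mean - k * theta_sd),
        inv_probit(theta_mean + k * theta_sd),
    )


def implied_study_range(mean_prev: float, tau: float, k: float = 2.0):
    """Band of "true" study-specific prevalences implied by heterogeneity tau.

    For a disorder with mean prevalence ``mean_prev`` and between-study
    probit-scale SD ``tau``, returns the prevalences at +/- k tau around
    probit(mean_prev).
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    z = probit(mean_prev)
    return inv_probit(z - k * tau), inv_probit(z + k * tau)


def _tri_indices(D: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(D, k=-1)


def _constrain_batch(y: np.ndarray, D: int) -> tuple[np.ndarray, np.ndarray]:
    """Map (..., m) unconstrained values to (..., D, D) Cholesky factors.

    Also returns the log-Jacobian of the map, shape (...,).  Works for real
    and complex inputs (the latter for complex-step derivatives).
    """
    y = np.asarray(y)
    batch = y.shape[:-1]
    z = np.tanh(y)
    L = np.zeros(batch + (D, D), dtype=y.dtype)
    L[..., 0, 0] = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        logjac = np.sum(np.log(1.0 - z**2), axis=-1)
    k = 0
    for i in range(1, D):
        norm = np.zeros(batch, dtype=y.dtype)
        for j in range(i):
            rem = np.sqrt(1.0 - norm)
            L[..., i, j] = z[..., k] * rem
            logjac = logjac + 0.5 * np.log(1.0 - norm)
            norm = norm + L[..., i, j] ** 2
            k += 1
        L[..., i, i] = np.sqrt(1.0 - norm)
    return L, logjac


def chol_corr_constrain(y: np.ndarray, D: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from m = D(D-1)/2 reals."""
    L, _ = _constrain_batch(np.asarray(y, dtype=float), D)
    return L


def chol_corr_unconstrain(omega: np.ndarray) -> np.ndarray:
    """Inverse map: correlation matrix -> unconstrained vector."""
    omega = np.asarray(omega, dtype=float)
    D = omega.shape[0]
    L = np.linalg.cholesky(omega)
    y = []
    for i in range(1, D):
        norm = 0.0
        for j in range(i):
            rem = np.sqrt(1.0 - norm)
            zij = L[i, j] / rem
            y.append(np.arctanh(np.clip(zij, -1 + 1e-12, 1 - 1e-12)))
            norm += L[i, j] ** 2
    return np.array(y)


def _lkj_chol_logpdf(L_diag, eta: float, D: int):
    """Unnormalized LKJ(eta) log density on a Cholesky-of-correlation factor."""
    # exponent (D - i + 2 eta - 3) on the i-th diagonal element, rows 0-indexed
    i = np.arange(1, D)
    expo = D - i + 2.0 * eta - 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sum(expo * np.log(L_diag[..., 1:]), axis=-1)


def chol_corr_with_grad(y: np.ndarray, D: int, eta: float):
    """Constrain ``y`` and differentiate everything the sampler needs.

    Returns ``(L, dL, logp, dlogp)`` where ``dL[k]`` is the derivative of L
    with respect to ``y[k]`` and ``logp`` is the LKJ(eta) log density plus the
    transform's log-Jacobian (so that sampling y with this target draws the
    correlation matrix from LKJ(eta)).
    """
    y = np.asarray(y, dtype=float)
    m = y.size
    h = 1e-200
    Y = np.tile(y.astype(complex), (m + 1, 1))
    Y[np.arange(1, m + 1), np.arange(m)] += 1j * h
    Lc, logjac_c = _constrain_batch(Y, D)
    diag = np.diagonal(Lc, axis1=-2, axis2=-1)
    logp_c = logjac_c + _lkj_chol_logpdf(diag, eta, D)
    L = Lc[0].real
    dL = Lc[1:].imag / h
    logp = float(logp_c[0].real)
    dlogp = logp_c[1:].imag / h
    return L, dL, logp, dlogp
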