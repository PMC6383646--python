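"""A self-contained No-U-Turn sampler with warmup adaptation.

The kernel is multinomial NUTS with a diagonal mass matrix: leapfrog
integration of Hamiltonian dynamics, doubling trajectories until a U-turn,
and multinomial sampling of the proposal among visited states.  Warmup adapts
the step size by dual averaging toward a target acceptance statistic and the
diagonal mass matrix from posterior variances estimated in an adaptation
window.  A posterior may additionally expose a ``gibbs_update`` hook, invoked
between transitions; this yields a Metropolis-within-Gibbs scheme used for
latent-variable (data-augmentation) models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Protocol

import numpy as np

__all__ = ["Posterior", "sample_chain", "ChainResult"]


class Posterior(Protocol):
    dim: int

    def logp_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]: ...

    def initial(self, rng: np.random.Generator) -> np.ndarray: ...

    # optional: def gibbs_update(self, x, rng) -> None


@dataclass
class ChainResult:
    draws: np.ndarray  # (n_draws, dim) unconstrained
    accept_stat: float
    n_divergent: int
    step_size: float


_DIVERGENCE = 1000.0  # energy error treated as a divergence


class _Mass:
    """Euclidean metric: momenta ~ N(0, Sigma^-1) for a covariance estimate Sigma."""

    def __init__(self, dim: int):
        self.dim = dim
        self.diag: Optional[np.ndarray] = np.ones(dim)
        self.sigma: Optional[np.ndarray] = None
        self._chol: Optional[np.ndarray] = None

    def set_diag(self, var: np.ndarray) -> None:
        self.diag = np.clip(var, 1e-10, None)
        self.sigma = self._chol = None

    def set_dense(self, sigma: np.ndarray) -> None:
        jitter = 1e-8 * float(np.max(np.diag(sigma)))
        self.sigma = sigma + jitter * np.eye(self.dim)
        self._chol = np.linalg.cholesky(self.sigma)
        self.diag = None

    def velocity(self, p: np.ndarray) -> np.ndarray:
        if self.diag is not None:
            return self.diag * p
        return self.sigma @ p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(np.dot(p, self.velocity(p)))

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.dim)
        if self.diag is not None:
            return z / np.sqrt(self.diag)
        from scipy.linalg import solve_triangular

        return solve_triangular(self._chol.T, z, lower=False)


def _leapfrog(logp_grad, x, p, grad, eps, mass):
    p = p + 0.5 * eps * grad
    x = x + eps * mass.velocity(p)
    logp, grad = logp_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _kinetic(p, mass):
    return mass.kinetic(p)


class _Tree:
    """State of one NUTS subtree (multinomial variant)."""

    __slots__ = (
        "x_minus", "p_minus", "grad_minus", "x_plus", "p_plus", "grad_plus",
        "x_prop", "logp_prop", "grad_prop", "log_weight", "sum_p",
        "turning", "diverging", "sum_accept", "n_leapfrog",
    )


def _build_tree(logp_grad, depth, x, p, grad, direction, eps, mass, h0, rng):
    if depth == 0:
        x1, p1, logp1, grad1 = _leapfrog(logp_grad, x, p, grad, direction * eps, mass)
        h1 = -logp1 + _kinetic(p1, mass)
        t = _Tree()
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.grad_minus = t.grad_plus = t.grad_prop = grad1
        t.logp_prop = logp1
        delta = h0 - h1  # log weight of the new state
        t.log_weight = delta if np.isfinite(delta) else -np.inf
        t.sum_p = p1.copy()
        t.diverging = (not np.isfinite(h1)) or (h1 - h0 > _DIVERGENCE)
        t.turning = False
        t.sum_accept = min(1.0, float(np.exp(min(delta, 0.0))))
        t.n_leapfrog = 1
        return t

    first = _build_tree(logp_grad, depth - 1, x, p, grad, direction, eps, mass, h0, rng)
    if first.diverging or first.turning:
        return first
    if direction == 1:
        second = _build_tree(
            logp_grad, depth - 1, first.x_plus, first.p_plus, first.grad_plus,
            direction, eps, mass, h0, rng,
        )
        first.x_plus = second.x_plus
        first.p_plus = second.p_plus
        first.grad_plus = second.grad_plus
    else:
        second = _build_tree(
            logp_grad, depth - 1, first.x_minus, first.p_minus, first.grad_minus,
            direction, eps, mass, h0, rng,
        )
        first.x_minus = second.x_minus
        first.p_minus = second.p_minus
        first.grad_minus = second.grad_minus

    total = np.logaddexp(first.log_weight, second.log_weight)
    if np.isfinite(second.log_weight) and np.log(rng.uniform()) < second.log_weight - total:
        first.x_prop = second.x_prop
        first.logp_prop = second.logp_prop
        first.grad_prop = second.grad_prop
    first.log_weight = total
    first.sum_p = first.sum_p + second.sum_p
    first.sum_accept += second.sum_accept
    first.n_leapfrog += second.n_leapfrog
    first.diverging = second.diverging
    first.turning = second.turning or _uturn(
        first.x_plus, first.x_minus, first.p_plus, first.p_minus, mass
    )
    return first


def _uturn(x_plus, x_minus, p_plus, p_minus, mass):
    dx = x_plus - x_minus
    return (np.dot(dx, mass.velocity(p_minus)) < 0) or (
        np.dot(dx, mass.velocity(p_plus)) < 0
    )


def _nuts_step(logp_grad, x, logp, grad, eps, mass, rng, max_depth):
    p0 = mass.sample_momentum(rng)
    h0 = -logp + _kinetic(p0, mass)

    t = _Tree()
    t.x_minus = t.x_plus = t.x_prop = x
    t.p_minus = t.p_plus = p0
    t.grad_minus = t.grad_plus = t.grad_prop = grad
    t.logp_prop = logp
    t.log_weight = 0.0
    t.sum_p = p0.copy()
    t.turning = t.diverging = False

    sum_accept = 0.0
    n_leapfrog = 0
    divergent = False
    for depth in range(max_depth):
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_grad, depth, t.x_plus, t.p_plus, t.grad_plus,
                              1, eps, mass, h0, rng)
            t.x_plus, t.p_plus, t.grad_plus = sub.x_plus, sub.p_plus, sub.grad_plus
        else:
            sub = _build_tree(logp_grad, depth, t.x_minus, t.p_minus, t.grad_minus,
                              -1, eps, mass, h0, rng)
            t.x_minus, t.p_minus, t.grad_minus = sub.x_minus, sub.p_minus, sub.grad_minus
        sum_accept += sub.sum_accept
        n_leapfrog += sub.n_leapfrog
        if sub.diverging:
            divergent = True
            break
        # biased progressive sampling: favour the new subtree
        if np.isfinite(sub.log_weight) and np.log(rng.uniform()) < sub.log_weight - t.log_weight:
            t.x_prop, t.logp_prop, t.grad_prop = sub.x_prop, sub.logp_prop, sub.grad_prop
        t.log_weight = np.logaddexp(t.log_weight, sub.log_weight)
        t.sum_p = t.sum_p + sub.sum_p
        if sub.turning or _uturn(t.x_plus, t.x_minus, t.p_plus, t.p_minus, mass):
            break
    accept_stat = sum_accept / max(n_leapfrog, 1)
    return t.x_prop, t.logp_prop, t.grad_prop, accept_stat, divergent


def _find_initial_step(logp_grad, x, logp, grad, mass, rng):
    eps = 1.0
    p0 = mass.sample_momentum(rng)
    h0 = -logp + _kinetic(p0, mass)
    _, p1, logp1, _ = _leapfrog(logp_grad, x, p0, grad, eps, mass)
    h1 = -logp1 + _kinetic(p1, mass) if np.isfinite(logp1) else np.inf
    delta = h0 - h1
    direction = 1.0 if delta > np.log(0.8) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(logp_grad, x, p0, grad, eps, mass)
        h1 = -logp1 + _kinetic(p1, mass) if np.isfinite(logp1) else np.inf
        delta = h0 - h1
        if direction == 1.0 and not (delta > np.log(0.8)):
            break
        if direction == -1.0 and not (delta < np.log(0.8)):
            break
    return eps


def sample_chain(
    posterior: Posterior,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_depth: int = 8,
    target_accept: float = 0.8,
    dense_mass: bool = False,
    init: Optional[np.ndarray] = None,
    draw_hook: Optional[Callable[[np.ndarray], None]] = None,
) -> ChainResult:
    """Run one adaptive NUTS chain and return post-warmup unconstrained draws."""
    x = posterior.initial(rng) if init is None else np.array(init, dtype=float)
    gibbs = getattr(posterior, "gibbs_update", None)
    if gibbs is not None:
        gibbs(x, rng)
    logp, grad = posterior.logp_grad(x)
    if not np.isfinite(logp):
        raise RuntimeError("initial point has non-finite log density")

    dim = x.size
    mass = _Mass(dim)
    # a dense metric can capture posterior correlation between parameters but
    # needs a long warmup to estimate well; diagonal is the default
    dense = dense_mass and dim <= 400
    eps = _find_initial_step(posterior.logp_grad, x, logp, grad, mass, rng)

    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_it = 0

    # mass adaptation window: [win_lo, win_hi) of warmup
    win_lo, win_hi = int(0.15 * n_warmup), int(0.9 * n_warmup)
    count = 0
    mean = np.zeros(dim)
    m2 = np.zeros(dim)
    xprod = np.zeros((dim, dim)) if dense else None

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    accept_sum = 0.0

    for it in range(n_warmup + n_draws):
        if gibbs is not None:
            gibbs(x, rng)
            logp, grad = posterior.logp_grad(x)
        x, logp, grad, accept, div = _nuts_step(
            posterior.logp_grad, x, logp, grad, eps, mass, rng, max_depth
        )
        if it < n_warmup:
            da_it += 1
            frac = 1.0 / (da_it + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - accept)
            log_eps = mu - np.sqrt(da_it) / gamma * h_bar
            w = da_it ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if win_lo <= it < win_hi:
                count += 1
                delta = x - mean
                mean += delta / count
                m2 += delta * (x - mean)
                if dense:
                    xprod += np.outer(delta, x - mean)
            if it == win_hi - 1 and count > 10:
                var = m2 / (count - 1)
                shrink = count / (count + 5.0)
                if dense:
                    cov = xprod / (count - 1)
                    cov = shrink * cov + (1.0 - shrink) * np.diag(
                        np.clip(var, 1e-8, None)
                    )
                    mass.set_dense(cov)
                else:
                    mass.set_diag(shrink * var + (1.0 - shrink) * 1e-3)
                eps = _find_initial_step(posterior.logp_grad, x, logp, grad, mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar = 0.0, 0.0
                da_it = 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x
            accept_sum += accept
            n_divergent += int(div)
            if draw_hook is not None:
                draw_hook(x)

    return ChainResult(
        draws=draws,
        accept_stat=accept_sum / max(n_draws, 1),
        n_divergent=n_divergent,
        step_size=eps,
    )
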