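"""Univariate logit-scale random-effects meta-analysis of "any disorder" estimates.

These are the comparator estimators the multivariate model is judged against:

* ``FRE`` — REML random-effects pooling of logit-transformed any-disorder
  prevalences, ignoring how many disorders each study measured;
* ``FRE-H`` — the same after dropping studies measuring fewer than half of the
  panel (:func:`filter_half`);
* ``FRE-A`` — the same restricted to studies measuring the full panel;
* ``FRE-M`` / ``FRE-MH`` — REML meta-regression with the number of measured
  disorders as predictor, extrapolated to a study measuring all D disorders.

The REML machinery is implemented here directly (profiled restricted
log-likelihood, maximized numerically over the between-study variance) rather
than delegated to a meta-analysis package, since the estimators themselves are
objects of study.  Inference uses inverse-variance weights and Wald-z 95%
intervals, matching the standard defaults of the usual tooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .data import MetaDataset

__all__ = [
    "EffectRow",
    "MetaResult",
    "logit_effects",
    "reml_pool",
    "reml_metareg",
    "filter_half",
    "LogitRandomEffects",
]

#: Rough logit -> probit scale conversion used for reporting tau on both scales.
LOGIT_TO_PROBIT = 1.6


@dataclass(frozen=True)
class EffectRow:
    """One study's logit-transformed any-disorder effect."""

    sample_id: str
    yi: float  # logit-transformed prevalence
    vi: float  # sampling variance of yi
    x: int  # number of disorders measured

    def __post_init__(self) -> None:
        if not self.vi > 0:
            raise ValueError(f"{self.sample_id}: sampling variance must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled (or predicted) logit effect with Wald-z interval and heterogeneity."""

    pooled_logit: float
    ci_low: float
    ci_high: float
    tau_logit: float
    k_samples: int
    slope: Optional[float] = None
    slope_p: Optional[float] = None

    @property
    def pooled_prev(self) -> float:
        return float(special.expit(self.pooled_logit))

    @property
    def ci_prev_low(self) -> float:
        return float(special.expit(self.ci_low))

    @property
    def ci_prev_high(self) -> float:
        return float(special.expit(self.ci_high))

    @property
    def tau_probit_approx(self) -> float:
        return self.tau_logit / LOGIT_TO_PROBIT

    def summary(self) -> str:
        lines = [
            f"k = {self.k_samples}",
            f"prevalence = {100 * self.pooled_prev:.1f}% "
            f"[{100 * self.ci_prev_low:.1f}, {100 * self.ci_prev_high:.1f}]",
            f"tau (logit) = {self.tau_logit:.2f}, "
            f"tau (approx. probit) = {self.tau_probit_approx:.2f}",
        ]
        if self.slope is not None:
            lines.append(f"slope = {self.slope:.3f} (p = {self.slope_p:.4g})")
        return "\n".join(lines)


def logit_effects(data: MetaDataset) -> list[EffectRow]:
    """Logit effects for every sample reporting an any-disorder count.

    ``p = any_count / N`` with ``yi = logit(p)`` and ``vi = 1/(N p) +
    1/(N (1 - p))``.  Samples with p exactly 0 or 1 get the standard
    only-zero-cells continuity correction: 0.5 added to both cells (so 1 to N).
    """
    rows = []
    for s in data.samples:
        if s.any_count is None:
            continue
        x, n = float(s.any_count), float(s.N)
        if x in (0.0, n):
            x, n = x + 0.5, n + 1.0
        yi = math.log(x / (n - x))
        vi = 1.0 / x + 1.0 / (n - x)
        rows.append(EffectRow(s.sample_id, yi, vi, s.n_measured))
    if not rows:
        raise ValueError("no samples with an any-disorder count")
    return rows


def filter_half(data: MetaDataset, min_measured: Optional[int] = None) -> MetaDataset:
    """Retain samples measuring at least ``min_measured`` disorders (default D/2 rounded up)."""
    if min_measured is None:
        min_measured = math.ceil(len(data.panel) / 2)
    keep = [s.sample_id for s in data.samples if s.n_measured >= min_measured]
    return data.subset(keep)


def _restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    XtWX = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(XtWX, X.T @ (w * y))
    resid = y - X @ beta
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid**2))


def _reml_fit(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """REML tau^2 by direct maximization; returns (tau2, beta, cov_beta)."""
    if len(y) <= X.shape[1]:
        raise ValueError("need more studies than fixed-effect coefficients")
    upper = max(10.0 * float(np.var(y)) + float(np.max(v)), 1e-4)
    res = optimize.minimize_scalar(
        lambda t2: -_restricted_loglik(t2, y, v, X),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    # tau^2 is floored at zero: snap when the profile peaks at the boundary
    if _restricted_loglik(0.0, y, v, X) >= _restricted_loglik(tau2, y, v, X):
        tau2 = 0.0
    w = 1.0 / (v + tau2)
    XtWX = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(XtWX)
    beta = cov @ (X.T @ (w * y))
    return tau2, beta, cov


def reml_pool(rows: Sequence[EffectRow]) -> MetaResult:
    """Intercept-only REML random-effects pooling with a Wald-z 95% CI."""
    if len(rows) < 2:
        raise ValueError("pooling requires at least two studies")
    y = np.array([r.yi for r in rows])
    v = np.array([r.vi for r in rows])
    X = np.ones((len(rows), 1))
    tau2, beta, cov = _reml_fit(y, v, X)
    est, se = float(beta[0]), math.sqrt(float(cov[0, 0]))
    z = stats.norm.ppf(0.975)
    return MetaResult(
        pooled_logit=est,
        ci_low=est - z * se,
        ci_high=est + z * se,
        tau_logit=math.sqrt(tau2),
        k_samples=len(rows),
    )


def reml_metareg(rows: Sequence[EffectRow], predict_at: float) -> MetaResult:
    """REML meta-regression on the number of measured disorders.

    Fits intercept + slope and reports the fitted value (with Wald-z 95% CI)
    at ``predict_at`` disorders — i.e. the extrapolated prevalence of a study
    measuring that many disorders — plus the Wald p-value of the slope.
    """
    if len(rows) < 3:
        raise ValueError("meta-regression requires at least three studies")
    x = np.array([r.x for r in rows], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("number of measured disorders is constant; slope not identified")
    y = np.array([r.yi for r in rows])
    v = np.array([r.vi for r in rows])
    X = np.column_stack([np.ones_like(x), x])
    tau2, beta, cov = _reml_fit(y, v, X)
    c = np.array([1.0, float(predict_at)])
    est = float(c @ beta)
    se = math.sqrt(float(c @ cov @ c))
    slope = float(beta[1])
    slope_se = math.sqrt(float(cov[1, 1]))
    slope_p = 2.0 * stats.norm.sf(abs(slope / slope_se))
    z = stats.norm.ppf(0.975)
    return MetaResult(
        pooled_logit=est,
        ci_low=est - z * se,
        ci_high=est + z * se,
        tau_logit=math.sqrt(tau2),
        k_samples=len(rows),
        slope=slope,
        slope_p=float(slope_p),
    )


class LogitRandomEffects:
    """statsmodels-style front end over :func:`reml_pool` / :func:`reml_metareg`.

    Parameters
    ----------
    rows : effect rows, e.g. from :func:`logit_effects`
    moderator : if True, include the number of measured disorders as predictor
    predict_at : where to evaluate the meta-regression line (default: max x)
    """

    def __init__(self, rows: Sequence[EffectRow], moderator: bool = False,
                 predict_at: Optional[float] = None):
        self.rows = list(rows)
        self.moderator = moderator
        self.predict_at = predict_at

    @classmethod
    def from_dataset(cls, data: MetaDataset, moderator: bool = False,
                     predict_at: Optional[float] = None) -> "LogitRandomEffects":
        if moderator and predict_at is None:
            predict_at = len(data.panel)
        return cls(logit_effects(data), moderator=moderator, predict_at=predict_at)

    def fit(self) -> MetaResult:
        if self.moderator:
            at = self.predict_at
            if at is None:
                at = max(r.x for r in self.rows)
            return reml_metareg(self.rows, at)
        return reml_pool(self.rows)
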