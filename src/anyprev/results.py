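"""Results object returned by :meth:`anyprev.model.PrevalenceModel.fit`."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import category as _cat
from ._transforms import inv_probit
from .model import PosteriorDraws, PrevalenceModel, convergence_report

__all__ = ["PrevalenceResults"]


class PrevalenceResults:
    """Posterior draws plus the estimators built on them.

    Carries the fitted :class:`PosteriorDraws` and exposes per-disorder
    summaries, convergence diagnostics, and the superordinate-category
    operations (category prevalence, conditional comorbidity, per-study
    posterior-predictive checks, cohort simulation).
    """

    def __init__(self, model: PrevalenceModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    # -- summaries ---------------------------------------------------------

    @property
    def converged(self) -> Optional[bool]:
        return self.draws.converged

    @property
    def diagnostics(self) -> pd.DataFrame:
        if self.draws.diagnostics is None:
            self.draws.diagnostics = convergence_report(self.draws)
        return self.draws.diagnostics

    def summary(self) -> pd.DataFrame:
        """Per-disorder posterior medians and 95% HDIs.

        ``prevalence`` is the population mean prevalence Phi(theta_d);
        ``tau`` the between-study probit-scale SD.
        """
        rows = []
        prev = inv_probit(self.draws.theta)
        for d, name in enumerate(self.draws.disorder_names):
            p_lo, p_hi = _cat.hdi(prev[:, d])
            t_lo, t_hi = _cat.hdi(self.draws.tau[:, d])
            rows.append({
                "disorder": name,
                "prevalence": float(np.median(prev[:, d])),
                "prev_hdi_low": p_lo,
                "prev_hdi_high": p_hi,
                "tau": float(np.median(self.draws.tau[:, d])),
                "tau_hdi_low": t_lo,
                "tau_hdi_high": t_hi,
            })
        return pd.DataFrame(rows).set_index("disorder")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        s = self.summary()
        conv = {True: "converged", False: "NOT converged", None: "diagnostics pending"}
        return (
            f"<PrevalenceResults: {self.draws.n_draws} draws x "
            f"{self.draws.n_chains} chains, {conv[self.converged]}>\n"
            + s.to_string(float_format=lambda v: f"{v:.3f}")
        )

    # -- category-level estimators ----------------------------------------

    def category_prevalence(self, k: int = 1, n_inner: int = 1000, seed: int = 0,
                            **kwargs) -> _cat.PrevalenceSummary:
        return _cat.category_prevalence(self.draws, k=k, n_inner=n_inner,
                                        seed=seed, **kwargs)

    def category_table(self, ks: Sequence[int] = (1, 2, 3, 4), n_inner: int = 1000,
                       seed: int = 0, **kwargs) -> pd.DataFrame:
        """Prevalence of >= k disorders for several k, as a tidy table."""
        rows = []
        for k in ks:
            s = self.category_prevalence(k=k, n_inner=n_inner, seed=seed + k, **kwargs)
            rows.append({"quantity": "category_prevalence", "k": k, **s.as_row()})
        return pd.DataFrame(rows)

    def category_report(self, ks: Sequence[int] = (1, 2, 3, 4), **kwargs) -> str:
        """Plain-text report of P(>= k disorders) with HDIs and prediction intervals."""
        tab = self.category_table(ks=ks, **kwargs)
        lines = ["Probability of having at least k disorders", ""]
        header = "k    prevalence [95% HDI]      95% PI"
        lines.append(header)
        for _, r in tab.iterrows():
            lines.append(
                f"{int(r['k'])}+   {100 * r['median']:4.0f}% "
                f"({100 * r['hdi_low']:.0f}%, {100 * r['hdi_high']:.0f}%)"
                + (
                    f"      ({100 * r['pi_low']:.0f}%, {100 * r['pi_high']:.0f}%)"
                    if r["pi_low"] is not None and not np.isnan(r["pi_low"])
                    else ""
                )
            )
        return "\n".join(lines)

    def conditional_probability(self, given, target, **kwargs) -> _cat.PrevalenceSummary:
        return _cat.conditional_probability(self.draws, given, target, **kwargs)

    def per_study_predictions(self, mode: str = "per-disorder", **kwargs) -> pd.DataFrame:
        return _cat.per_study_predictions(self.draws, self.model.data, mode=mode, **kwargs)

    def simulate_cohort(self, n_participants: int, mode: str = "one-study-per-participant",
                        seed: int = 0) -> _cat.HypotheticalCohort:
        return _cat.simulate_cohort(self.draws, n_participants, mode=mode, seed=seed)

    def save(self, csv_path, json_path=None) -> None:
        self.draws.save(csv_path, json_path)
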