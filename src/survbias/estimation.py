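"""Logistic-regression estimation and replicate pooling.

The analysis model mirrors the study design being simulated: disease status
regressed on age (continuous years), sex, and carrier status (0/1), with
statin use optionally added as a covariate.  The carrier coefficient's
exponential is the adjusted odds ratio of interest.  Replicate ORs are
pooled by their arithmetic mean with a 95% Monte-Carlo half-width
1.96·SD/√R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["EstimationError", "FitResult", "PooledEstimate", "fit_logistic", "pool_replicates"]

_ALLOWED_COVARIATES = ("age", "sex", "carrier", "statin")


class EstimationError(RuntimeError):
    """Logistic fit failed (non-convergence, separation, empty cells)."""


@dataclass(frozen=True)
class FitResult:
    """One logistic fit: per-covariate estimates plus dataset sizes."""

    params: pd.DataFrame = field(repr=False)  # name, coef, se, or, ci_low, ci_high, p
    n_analyzed: int
    n_cases: int

    def row(self, name: str) -> pd.Series:
        match = self.params[self.params["name"] == name]
        if match.empty:
            raise KeyError(f"no covariate named {name!r} in fit")
        return match.iloc[0]

    def odds_ratio(self, name: str = "carrier") -> float:
        return float(self.row(name)["or"])


@dataclass(frozen=True)
class PooledEstimate:
    """Replicate odds ratios pooled over a simulation condition."""

    condition: str
    ors: tuple[float, ...]
    pooled_or: float
    mc_halfwidth: float

    @property
    def replicates(self) -> int:
        return len(self.ors)


def fit_logistic(
    data: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "carrier"),
    outcome: str = "event",
) -> FitResult:
    """Maximum-likelihood logistic fit of ``outcome ~ covariates``.

    ``data`` holds one row per analyzed individual.  Age enters as
    continuous years; sex, carrier and statin as 0/1 indicators.  Newton
    iterations are capped at 100 with a 1e-8 relative tolerance; failures
    to converge, perfect separation and all-or-nothing carrier case counts
    raise :class:`EstimationError` with diagnostics attached.
    """
    bad = [c for c in covariates if c not in _ALLOWED_COVARIATES]
    if bad:
        raise ValueError(f"unsupported covariates {bad}; allowed: {_ALLOWED_COVARIATES}")
    y = data[outcome].to_numpy(dtype=float)
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == len(y):
        raise EstimationError(f"degenerate outcome: {n_cases} cases out of {len(y)} rows")
    if "carrier" in covariates:
        carrier_cases = int(((data["carrier"] == 1) & (data[outcome] == 1)).sum())
        if carrier_cases == 0 or carrier_cases == n_cases:
            raise EstimationError(
                f"carrier/case cross-tabulation degenerate ({carrier_cases} carrier "
                f"cases of {n_cases}); the carrier OR is not identifiable"
            )
    X = sm.add_constant(data[list(covariates)].to_numpy(dtype=float), prepend=True)
    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except Exception as exc:  # separation, singular Hessian, ...
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise EstimationError(f"logistic fit did not converge: {res.mle_retvals}")
    names = ["intercept", *covariates]
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    ci = res.conf_int(alpha=0.05)
    params = pd.DataFrame(
        {
            "name": names,
            "coef": coef,
            "se": se,
            "or": np.exp(coef),
            "ci_low": np.exp(np.asarray(ci)[:, 0]),
            "ci_high": np.exp(np.asarray(ci)[:, 1]),
            "p": np.asarray(res.pvalues, dtype=float),
        }
    )
    return FitResult(params=params, n_analyzed=len(y), n_cases=n_cases)


def pool_replicates(
    fits: Sequence[FitResult], covariate: str = "carrier", condition: str = ""
) -> PooledEstimate:
    """Pool replicate odds ratios: mean OR and 1.96·SD/√R half-width."""
    if len(fits) < 2:
        raise ValueError(f"need at least 2 replicates to pool, got {len(fits)}")
    ors = np.array([f.odds_ratio(covariate) for f in fits], dtype=float)
    halfwidth = 1.96 * ors.std(ddof=1) / np.sqrt(len(ors))
    return PooledEstimate(
        condition=condition,
        ors=tuple(ors),
        pooled_or=float(ors.mean()),
        mc_halfwidth=float(halfwidth),
    )
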