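"""Closed-form expected values for every simulated condition.

The simulator's generative process has a deterministic expectation: for each
age × sex × genotype (× treatment) stratum the expected mass of surviving
cases is

    mass × p × (1 − f_genotype)

and of non-cases ``mass × (1 − p)``, where ``p`` is the stratum event
probability and ``f_genotype`` the genotype's case-fatality rate.  Fitting
the same logistic analysis model to these fractional expected counts gives
the exact large-sample limit of the simulated adjusted odds ratio — the
analytic twin used for calibration, fast prediction over parameter grids,
and equivalence testing of the stochastic engine.

A cruder closed form is also exposed: survival exclusion multiplies the
carrier odds by (1 − f_c)/(1 − f_n), so

    OR_observed ≈ OR_unbiased × (1 − f_c)/(1 − f_n)

which is exact for the crude 2×2 odds ratio and approximate for the
adjusted one.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .cohort_sim import solve_fatality_rates
from .demography import SEX_FEMALE, SEX_MALE, DemographyTable
from .risk_model import BaselineIncidenceTable, RiskConfig, carrier_multiplier

__all__ = [
    "expected_cells",
    "expected_or",
    "expected_or_statin",
    "attenuation_factor",
    "effective_multiplier",
]

_SEX_OF = {"F": SEX_FEMALE, "M": SEX_MALE}


def expected_cells(
    demog: DemographyTable,
    incidence: BaselineIncidenceTable,
    cfg: RiskConfig,
    F: float = 0.0,
    d: float = 0.0,
    convention: str = "relative",
) -> pd.DataFrame:
    """Expected surviving-case and non-case mass per stratum.

    Strata are (age, sex, carrier, statin); the statin dimension collapses
    to a single untreated stratum when ``cfg.statin_fraction`` is 0 or 1.
    Masses are population fractions (they sum to 1 before exclusion).
    """
    rates = solve_fatality_rates(F, d, cfg.q, convention) if (F > 0 or d > 0) else None

    ages, sexes, masses = [], [], []
    for _, band in demog.bands.iterrows():
        width = int(band["age_hi"] - band["age_lo"])
        for a in range(int(band["age_lo"]), int(band["age_hi"])):
            ages.append(a)
            sexes.append(_SEX_OF[band["sex"]])
            masses.append(band["proportion"] / width)
    base = pd.DataFrame({"age": ages, "sex": sexes, "mass": masses})
    base["p0"] = incidence.p0(base["age"].to_numpy(), base["sex"].to_numpy())

    s = cfg.statin_fraction
    statin_levels = [(0, 1.0 - s)] if s == 0.0 else [(1, 1.0)] if s == 1.0 else [(0, 1.0 - s), (1, s)]

    rows = []
    for carrier, gmass in ((0, 1.0 - cfg.q), (1, cfg.q)):
        f = 0.0 if rates is None else (rates.f_carrier if carrier else rates.f_noncarrier)
        for statin, smass in statin_levels:
            m = float(carrier_multiplier(cfg, statin)) if carrier else 1.0
            p = np.minimum(base["p0"].to_numpy() * m, 1.0 - 1e-12)
            mass = base["mass"].to_numpy() * gmass * smass
            rows.append(
                pd.DataFrame(
                    {
                        "age": base["age"],
                        "sex": base["sex"],
                        "carrier": carrier,
                        "statin": statin,
                        "case_mass": mass * p * (1.0 - f),
                        "noncase_mass": mass * (1.0 - p),
                    }
                )
            )
    cells = pd.concat(rows, ignore_index=True)
    if (cells[["case_mass", "noncase_mass"]].to_numpy() < 0).any():
        raise AssertionError("negative expected mass")
    return cells


def _fit_expected(cells: pd.DataFrame, covariates: tuple[str, ...]) -> float:
    """Adjusted carrier OR from a weighted logistic fit to expected counts.

    Each stratum contributes a binomial observation with success fraction
    case/(case+noncase) and weight equal to its surviving mass, which is the
    weighted-proportions form of logistic regression on fractional counts.
    """
    total = cells["case_mass"] + cells["noncase_mass"]
    keep = total > 0
    cells, total = cells[keep], total[keep]
    frac = cells["case_mass"] / total
    X = sm.add_constant(cells[list(covariates)].to_numpy(dtype=float), prepend=True)
    with warnings.catch_warnings():
        # near the rare-disease limit every expected fraction is ~0 and the
        # separation heuristic fires; the weighted point estimate is still exact
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = sm.GLM(
            frac.to_numpy(), X, family=sm.families.Binomial(), var_weights=total.to_numpy()
        ).fit(tol=1e-10)
    return float(np.exp(res.params[1 + covariates.index("carrier")]))


def expected_or(
    demog: DemographyTable,
    incidence: BaselineIncidenceTable,
    cfg: RiskConfig,
    F: float = 0.0,
    d: float = 0.0,
    convention: str = "relative",
    adjust_for_statin: bool = False,
) -> float:
    """Expected adjusted carrier odds ratio for one simulation condition.

    Covers both bias mechanisms (and their combination): fatal-case
    exclusion via (F, d) and statin effect modification via cfg's
    statin_fraction/statin_efficacy.
    """
    cells = expected_cells(demog, incidence, cfg, F=F, d=d, convention=convention)
    covariates: tuple[str, ...] = ("age", "sex", "carrier")
    if adjust_for_statin and 0.0 < cfg.statin_fraction < 1.0:
        covariates += ("statin",)
    return _fit_expected(cells, covariates)


def expected_or_statin(
    demog: DemographyTable,
    incidence: BaselineIncidenceTable,
    cfg: RiskConfig,
    adjust_for_statin: bool = False,
) -> float:
    """Expected carrier OR under statin effect modification only (F=d=0)."""
    return expected_or(demog, incidence, cfg, F=0.0, d=0.0, adjust_for_statin=adjust_for_statin)


def attenuation_factor(F: float, d: float, q: float, convention: str = "relative") -> float:
    """First-order survival-bias attenuation (1−f_c)/(1−f_n) of the odds ratio."""
    if F == 0.0 or d == 0.0:
        return 1.0
    rates = solve_fatality_rates(F, d, q, convention)
    return (1.0 - rates.f_carrier) / (1.0 - rates.f_noncarrier)


def effective_multiplier(cfg: RiskConfig) -> float:
    """Marginal carrier risk multiplier under partial statin coverage.

    Carriers are a mixture of treated and untreated, so the population-level
    multiplier is exactly 1 + (RR−1)(1 − s·e).
    """
    return 1.0 + (cfg.rr - 1.0) * (1.0 - cfg.statin_fraction * cfg.statin_efficacy)
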