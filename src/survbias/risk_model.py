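"""Per-individual cardiovascular event probabilities.

The risk surface is a per-sex cumulative incidence curve p0(age, sex) — the
probability of a first CVD event between age 40 and the attained age —
modified multiplicatively by genotype and by treatment:

    p = p0(age, sex) * m,    m = 1                                noncarrier
                             m = 1 + (RR - 1) * (1 - e * statin)  carrier

where RR is the carrier risk ratio, ``e`` the fraction of the carrier
*excess* risk eliminated by statin treatment, and ``statin`` a 0/1
indicator.  Statins act only on the carrier excess term; noncarrier risk is
unchanged, which takes the clinical observation that noncarriers derive
less benefit from statins to its limiting case.

Because no exact published incidence table is reproduced here, the packaged
curve is a smooth logistic-in-age template whose overall scale is fixed once
by :func:`calibrate_baseline`: a single global factor k is chosen so that
the *unbiased* (no exclusion, no treatment) adjusted carrier odds ratio for
RR = 1.5 hits a chosen anchor (default 1.55).  The OR/RR gap is purely a
function of how common the outcome is, so one scalar pins it down; every
other simulated quantity is then out-of-sample.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .demography import SEX_FEMALE, SEX_MALE, DemographyTable, load_demography

__all__ = [
    "IncidenceError",
    "BaselineIncidenceTable",
    "RiskConfig",
    "load_incidence",
    "assign_genotype",
    "assign_statin",
    "carrier_multiplier",
    "individual_risk",
    "calibrate_baseline",
    "default_calibrated_incidence",
]

logger = logging.getLogger(__name__)

_RISK_CAP = 1.0 - 1e-12


class IncidenceError(ValueError):
    """Invalid baseline incidence table."""


@dataclass(frozen=True)
class BaselineIncidenceTable:
    """Cumulative CVD incidence p0(sex, age) for integer ages.

    Invariants: 0 <= p0 < 1, p0 non-decreasing in age within each sex, and
    p0 = 0 at the youngest covered age (risk accumulates from there).
    """

    table: pd.DataFrame = field(repr=False)  # columns sex, age, p0
    scale: float = 1.0  # calibration factor applied to the source values

    def __post_init__(self) -> None:
        df = self.table
        for col in ("sex", "age", "p0"):
            if col not in df.columns:
                raise IncidenceError(f"incidence table is missing column {col!r}")
        if ((df["p0"] < 0) | (df["p0"] >= 1)).any():
            raise IncidenceError("p0 values must lie in [0, 1)")
        ages = np.sort(df["age"].unique())
        lookup = np.empty((2, len(ages)))
        for sex_label, code in (("F", SEX_FEMALE), ("M", SEX_MALE)):
            g = df[df["sex"] == sex_label].sort_values("age")
            if len(g) != len(ages) or not np.array_equal(g["age"].to_numpy(), ages):
                raise IncidenceError(f"sex {sex_label} must cover every age exactly once")
            p = g["p0"].to_numpy(dtype=float)
            if (np.diff(p) < 0).any():
                raise IncidenceError(f"p0 must be non-decreasing in age for sex {sex_label}")
            if p[0] != 0.0:
                raise IncidenceError(f"p0 at the youngest age must be 0 for sex {sex_label}")
            lookup[code] = p
        if (np.diff(ages) != 1).any():
            raise IncidenceError("ages must be contiguous integers")
        object.__setattr__(self, "_ages", ages)
        object.__setattr__(self, "_lookup", lookup)

    @property
    def age_min(self) -> int:
        return int(self._ages[0])

    @property
    def age_max(self) -> int:
        """Inclusive upper end of the covered age range."""
        return int(self._ages[-1])

    def p0(self, ages: np.ndarray, sexes: np.ndarray) -> np.ndarray:
        """Vectorized lookup of baseline cumulative incidence."""
        ages = np.asarray(ages)
        if ((ages < self.age_min) | (ages > self.age_max)).any():
            raise IncidenceError(
                f"age outside incidence table range [{self.age_min}, {self.age_max}]"
            )
        return self._lookup[np.asarray(sexes), ages - self.age_min]

    def scaled(self, k: float) -> "BaselineIncidenceTable":
        """Return a copy with every p0 multiplied by ``k``."""
        df = self.table.copy()
        df["p0"] = df["p0"] * k
        return BaselineIncidenceTable(df, scale=self.scale * k)


@dataclass(frozen=True)
class RiskConfig:
    """Genotype and treatment parameters of the risk model.

    q : population carrier frequency (KIF6 719Arg carriers: 0.59)
    rr : carrier-vs-noncarrier risk ratio in the untreated (reference grid: 1.25, 1.5)
    statin_fraction : fraction of the population on statins, independent of genotype
    statin_efficacy : fraction of the carrier excess risk eliminated by treatment
    """

    q: float = 0.59
    rr: float = 1.5
    statin_fraction: float = 0.0
    statin_efficacy: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"carrier frequency q must be in (0, 1), got {self.q}")
        if self.rr <= 0:
            raise ValueError(f"risk ratio must be positive, got {self.rr}")
        if not 0.0 <= self.statin_fraction <= 1.0:
            raise ValueError(f"statin fraction must be in [0, 1], got {self.statin_fraction}")
        if not 0.0 <= self.statin_efficacy <= 1.0:
            raise ValueError(f"statin efficacy must be in [0, 1], got {self.statin_efficacy}")


def load_incidence(source: str | Path = "framingham_template") -> BaselineIncidenceTable:
    """Load an incidence table from a packaged name or a CSV (sex, age, p0)."""
    if isinstance(source, str) and source == "framingham_template":
        ref = resources.files("survbias._data") / "framingham_template.csv"
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)
    return BaselineIncidenceTable(df)


def assign_genotype(n: int, q: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(q) carrier indicators (genotype ⟂ age, sex)."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"carrier frequency q must be strictly inside (0, 1), got {q}")
    return (rng.random(n) < q).astype(np.int64)


def assign_statin(n: int, s: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(s) statin-use indicators."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"statin fraction must be in [0, 1], got {s}")
    if s == 0.0:
        return np.zeros(n, dtype=np.int64)
    if s == 1.0:
        return np.ones(n, dtype=np.int64)
    return (rng.random(n) < s).astype(np.int64)


def carrier_multiplier(cfg: RiskConfig, statin: np.ndarray | int) -> np.ndarray:
    """Risk multiplier applied to carriers: 1 + (RR−1)(1 − e·statin)."""
    return 1.0 + (cfg.rr - 1.0) * (1.0 - cfg.statin_efficacy * np.asarray(statin))


def individual_risk(
    ages: np.ndarray,
    sexes: np.ndarray,
    carrier: np.ndarray,
    statin: np.ndarray | int,
    incidence: BaselineIncidenceTable,
    cfg: RiskConfig,
) -> np.ndarray:
    """Event probability per individual.

    Noncarriers get the baseline p0(age, sex) regardless of treatment;
    carriers get p0 times ``carrier_multiplier``.  Results are clipped to
    [0, 1−1e-12]; with a sanely calibrated baseline no clipping occurs, and
    any clipping events are counted and logged as a warning.
    """
    p0 = incidence.p0(ages, sexes)
    m = np.where(carrier == 1, carrier_multiplier(cfg, statin), 1.0)
    risk = p0 * m
    n_clipped = int(np.count_nonzero(risk > _RISK_CAP))
    if n_clipped:
        logger.warning("individual_risk clipped %d probabilities to %.12f", n_clipped, _RISK_CAP)
        risk = np.minimum(risk, _RISK_CAP)
    return risk


def calibrate_baseline(
    template: BaselineIncidenceTable,
    target: float = 1.55,
    demog: DemographyTable | None = None,
    rr: float = 1.5,
    tol: float = 1e-4,
) -> tuple[BaselineIncidenceTable, float]:
    """Scale the incidence template so the unbiased carrier OR hits ``target``.

    Bisects a single global factor k so that the analytic expected adjusted
    odds ratio (no fatal-case exclusion, no statin use) for carrier risk
    ratio ``rr`` equals ``target``.  The expected OR is continuous and
    strictly increasing in k (more common outcomes inflate the OR above the
    RR), so the root is unique; k is capped so that max(p0)·rr stays below 1.

    Returns ``(calibrated_table, k)``.
    """
    from .oracle import expected_or  # deferred: oracle depends on this module

    if demog is None:
        demog = load_demography("canada2006")
    if target < rr:
        raise ValueError(
            f"target OR {target} below the risk ratio {rr}: unreachable, the "
            "odds ratio can only exceed the risk ratio for a non-rare outcome"
        )
    cfg = RiskConfig(rr=rr, statin_fraction=0.0)
    max_p0 = float(template.table["p0"].max())
    k_max = (1.0 - 1e-9) / (rr * max_p0)

    def gap(k: float) -> float:
        return expected_or(demog, template.scaled(k), cfg) - target

    lo = 1e-9
    if gap(k_max) < 0:
        raise IncidenceError(
            f"target OR {target} not reachable: even at the maximal scale "
            f"k={k_max:.4f} the expected OR falls short"
        )
    k = brentq(gap, lo, k_max, xtol=1e-10, rtol=1e-12)
    calibrated = template.scaled(k)
    achieved = expected_or(demog, calibrated, cfg)
    if abs(achieved - target) > tol:
        raise IncidenceError(
            f"calibration did not converge: achieved {achieved:.6f} vs target {target}"
        )
    return calibrated, k


@functools.lru_cache(maxsize=4)
def _default_calibrated(target: float, rr: float) -> tuple[BaselineIncidenceTable, float]:
    return calibrate_baseline(load_incidence(), target=target, rr=rr)


def default_calibrated_incidence(target: float = 1.55, rr: float = 1.5) -> BaselineIncidenceTable:
    """Packaged template calibrated to the default anchor (memoized)."""
    return _default_calibrated(target, rr)[0]
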