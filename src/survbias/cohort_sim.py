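"""Event simulation, genotype-specific case fatality, and exclusion.

A cross-sectional case-control study can only recruit survivors: cases who
died of their event are available neither as cases nor as controls.  This
module draws events against per-individual risks, resolves carrier- and
noncarrier-specific case-fatality rates under the constraint that the
population-weighted overall fatality stays fixed, and removes fatal cases
from the analysis dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FATALITY_CONVENTIONS",
    "FatalityRates",
    "Cohort",
    "simulate_events",
    "solve_fatality_rates",
    "apply_survival_filter",
]

FATALITY_CONVENTIONS = ("relative", "mean_relative")


@dataclass(frozen=True)
class FatalityRates:
    """Case-fatality probabilities by genotype.

    ``f_carrier`` applies to carrier cases, ``f_noncarrier`` to noncarrier
    cases; carriers never fare better (f_noncarrier <= f_carrier), and the
    population-weighted mean q·f_carrier + (1−q)·f_noncarrier equals the
    configured overall fatality rate.
    """

    f_carrier: float
    f_noncarrier: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_noncarrier <= self.f_carrier < 1.0:
            raise ValueError(
                f"need 0 <= f_noncarrier <= f_carrier < 1, got "
                f"({self.f_carrier}, {self.f_noncarrier})"
            )

    def overall(self, q: float) -> float:
        """Population-weighted mean fatality at carrier frequency q."""
        return q * self.f_carrier + (1.0 - q) * self.f_noncarrier


@dataclass
class Cohort:
    """Columnar per-individual simulation record.

    Invariants: ``fatal`` implies ``event``; ``included`` is exactly
    ``1 - fatal`` (every survivor, case or not, is analyzable); risks lie
    in [0, 1].
    """

    age: np.ndarray
    sex: np.ndarray
    carrier: np.ndarray
    statin: np.ndarray
    risk: np.ndarray
    event: np.ndarray | None = None
    fatal: np.ndarray | None = None
    included: np.ndarray | None = None
    n_clipped: int = field(default=0, compare=False)

    @property
    def n(self) -> int:
        return len(self.age)

    def analysis_frame(self) -> pd.DataFrame:
        """Rows entering the logistic regression (included == 1)."""
        if self.event is None or self.included is None:
            raise ValueError("events/fatalities not yet simulated")
        df = self.to_frame()
        return df[df["included"] == 1].reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "age": self.age,
            "sex": self.sex,
            "carrier": self.carrier,
            "statin": self.statin,
            "risk": self.risk,
        }
        for name in ("event", "fatal", "included"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


def simulate_events(risks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one event indicator per individual: event iff U < risk."""
    risks = np.asarray(risks, dtype=float)
    if ((risks < 0) | (risks > 1)).any():
        raise ValueError("risks must lie in [0, 1]")
    return (rng.random(len(risks)) < risks).astype(np.int64)


def solve_fatality_rates(
    F: float, d: float, q: float, convention: str = "relative"
) -> FatalityRates:
    """Resolve genotype-specific fatality rates from (F, d, q).

    ``F`` is the overall case-fatality rate, held fixed as the differential
    ``d`` varies; ``q`` is the population carrier frequency used to weight
    the two genotype rates (q·f_c + (1−q)·f_n = F).

    Conventions for the differential:

    - ``"relative"`` (default): the noncarrier rate is d lower than the
      carrier rate in relative terms, f_n = (1−d)·f_c, giving
      f_c = F / (q + (1−q)(1−d)).
    - ``"mean_relative"``: the rates straddle F with a gap of d·F,
      f_c = F(1 + (1−q)d), f_n = F(1 − q·d).

    Raises ``ValueError`` when the implied carrier rate reaches 1.
    """
    if not 0.0 <= F < 1.0:
        raise ValueError(f"overall fatality F must be in [0, 1), got {F}")
    if not 0.0 <= d < 1.0:
        raise ValueError(f"fatality differential d must be in [0, 1), got {d}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"carrier frequency q must be in (0, 1), got {q}")
    if convention == "relative":
        f_c = F / (q + (1.0 - q) * (1.0 - d))
        f_n = (1.0 - d) * f_c
    elif convention == "mean_relative":
        f_c = F * (1.0 + (1.0 - q) * d)
        f_n = F * (1.0 - q * d)
    else:
        raise ValueError(f"unknown fatality convention {convention!r}")
    if f_c >= 1.0:
        raise ValueError(
            f"infeasible combination: carrier fatality {f_c:.4f} >= 1 "
            f"for F={F}, d={d}, q={q} ({convention})"
        )
    return FatalityRates(f_carrier=f_c, f_noncarrier=f_n)


def apply_survival_filter(
    cohort: Cohort, rates: FatalityRates, rng: np.random.Generator
) -> Cohort:
    """Mark fatal cases and exclude them from the analysis set.

    Each case independently dies with its genotype's fatality probability;
    non-cases are never fatal.  Sets ``fatal`` and ``included = 1 - fatal``
    in place and returns the cohort.
    """
    if cohort.event is None:
        raise ValueError("events must be simulated before the survival filter")
    f = np.where(cohort.carrier == 1, rates.f_carrier, rates.f_noncarrier)
    fatal = ((cohort.event == 1) & (rng.random(cohort.n) < f)).astype(np.int64)
    cohort.fatal = fatal
    cohort.included = 1 - fatal
    return cohort
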