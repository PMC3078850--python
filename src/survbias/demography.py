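"""Population age/sex structure for simulated cohorts.

A :class:`DemographyTable` holds the fraction of the population in each
age-band × sex cell.  The packaged default ``"canada2006"`` approximates the
age and sex distribution of Canadian adults aged 40–89 (5-year bands); it is
an approximation committed as data and can be replaced by any user CSV with
columns ``age_lo, age_hi, sex, proportion``.

Only ages 40+ are modelled: the baseline risk surface is cumulative disease
incidence from age 40, so younger individuals carry zero risk and would only
dilute the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SEX_FEMALE",
    "SEX_MALE",
    "DemographyError",
    "DemographyTable",
    "load_demography",
    "sample_population",
]

#: integer sex codes used throughout the package (and in design matrices)
SEX_FEMALE = 0
SEX_MALE = 1

_SEX_CODES = {"F": SEX_FEMALE, "M": SEX_MALE}
_REQUIRED_COLUMNS = ("age_lo", "age_hi", "sex", "proportion")
_PACKAGED = {"canada2006": "canada2006.csv"}


class DemographyError(ValueError):
    """Invalid demography table (bad columns, proportions or bands)."""


@dataclass(frozen=True)
class DemographyTable:
    """Age-band × sex population proportions.

    Parameters
    ----------
    bands
        One row per cell with columns ``age_lo`` (inclusive), ``age_hi``
        (exclusive), ``sex`` (``"F"``/``"M"``) and ``proportion``.
        Proportions must be non-negative and sum to 1 within 1e-9; bands
        must not overlap within a sex and both sexes must be present.
    """

    bands: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _validate(self.bands)

    @property
    def age_min(self) -> int:
        return int(self.bands["age_lo"].min())

    @property
    def age_max(self) -> int:
        """Exclusive upper bound of the covered age range."""
        return int(self.bands["age_hi"].max())

    def proportions(self) -> np.ndarray:
        return self.bands["proportion"].to_numpy(dtype=float)


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DemographyError(f"demography table is missing columns {missing}")
    if df.empty:
        raise DemographyError("demography table has no rows")
    bad_sex = df.loc[~df["sex"].isin(_SEX_CODES), "sex"]
    if len(bad_sex):
        raise DemographyError(
            f"sex must be one of {sorted(_SEX_CODES)}; got {bad_sex.iloc[0]!r} "
            f"in row {bad_sex.index[0]}"
        )
    neg = df.index[df["proportion"] < 0]
    if len(neg):
        raise DemographyError(f"negative proportion in row {neg[0]}")
    bad_band = df.index[df["age_hi"] <= df["age_lo"]]
    if len(bad_band):
        raise DemographyError(f"empty or inverted age band in row {bad_band[0]}")
    total = df["proportion"].sum()
    if abs(total - 1.0) > 1e-9:
        raise DemographyError(
            f"proportions sum to {total:.8f}, not 1 (renormalize via load_demography)"
        )
    for sex, grp in df.groupby("sex"):
        g = grp.sort_values("age_lo")
        bad = np.flatnonzero(g["age_lo"].values[1:] < g["age_hi"].values[:-1])
        if len(bad):
            raise DemographyError(
                f"overlapping age bands for sex {sex} at row {g.index[bad[0] + 1]}"
            )
    if df["sex"].nunique() != 2:
        raise DemographyError("both sexes must be present")


def load_demography(source: str | Path) -> DemographyTable:
    """Load and validate a demography table.

    ``source`` is either a registered packaged name (``"canada2006"``) or a
    path to a CSV with columns ``age_lo, age_hi, sex, proportion``.
    Proportions that sum to 1 within 1e-6 are renormalized exactly;
    larger deviations raise :class:`DemographyError`.
    """
    if isinstance(source, str) and source in _PACKAGED:
        ref = resources.files("survbias._data") / _PACKAGED[source]
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DemographyError(f"demography file {source} is missing columns {missing}")
    total = df["proportion"].sum()
    if abs(total - 1.0) > 1e-6:
        raise DemographyError(
            f"proportions in {source} sum to {total:.6f}; deviation from 1 "
            "exceeds the 1e-6 renormalization tolerance"
        )
    df = df.copy()
    df["proportion"] = df["proportion"] / total
    return DemographyTable(df.reset_index(drop=True))


def sample_population(
    demog: DemographyTable, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` individuals from the demography table.

    Each individual is assigned a band×sex cell by a single categorical draw
    over the table's proportions, then an integer age uniform within the
    band.  Returns ``(ages, sexes)`` with sexes coded 0=female, 1=male.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = demog.bands
    idx = rng.choice(len(df), size=n, p=demog.proportions())
    lo = df["age_lo"].to_numpy(dtype=np.int64)[idx]
    width = (df["age_hi"] - df["age_lo"]).to_numpy(dtype=np.int64)[idx]
    ages = lo + rng.integers(0, width)
    sexes = df["sex"].map(_SEX_CODES).to_numpy(dtype=np.int64)[idx]
    return ages, sexes
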