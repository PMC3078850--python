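"""Configuration-driven simulation conditions and experiment grids.

Each condition runs R independent replicates of an n-individual cohort
through the full pipeline — demography → genotype (→ statin) → risk →
events → survival filter → logistic fit — and pools the replicate carrier
odds ratios.  Three canned grids trace the attenuation curves of interest:

* fatality-differential grid: F × RR × d (survival bias),
* statin-use grid: s × RR with full efficacy, fit with and without the
  statin covariate (adjustment futility),
* statin-efficacy grid: e × s at RR = 1.5 (partial effect elimination).

Reproducibility: replicate r of a condition uses seed ``base_seed + r``,
and each stochastic stage (population, genotype, statin, events, fatality)
draws from its own named substream of that seed, so switching one stage on
or off never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort_sim, demography, estimation, oracle, risk_model

__all__ = [
    "ScenarioConfig",
    "ConditionResult",
    "ExperimentResult",
    "simulate_cohort",
    "run_condition",
    "run_figure1_grid",
    "run_figure2_grid",
    "run_figure3_grid",
]

logger = logging.getLogger(__name__)

_STAGES = {"population": 0, "genotype": 1, "statin": 2, "events": 3, "fatality": 4}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGES[stage]]))


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation condition.

    Defaults are the reference study conditions: cohorts of 1,000,000
    drawn 10 times, 59% carriers, and no bias mechanism active.
    """

    n: int = 1_000_000
    replicates: int = 10
    base_seed: int = 0
    q: float = 0.59
    rr: float = 1.5
    fatality: float = 0.0          # overall case-fatality rate F
    fatality_diff: float = 0.0     # genotype differential d
    statin_fraction: float = 0.0   # s
    statin_efficacy: float = 1.0   # e
    adjust_for_statin: bool = False
    fatality_convention: str = "relative"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.fatality_convention not in cohort_sim.FATALITY_CONVENTIONS:
            raise ValueError(f"unknown fatality convention {self.fatality_convention!r}")
        # range checks shared with the risk model
        self.risk_config()
        if self.fatality > 0 or self.fatality_diff > 0:
            cohort_sim.solve_fatality_rates(
                self.fatality, self.fatality_diff, self.q, self.fatality_convention
            )

    def risk_config(self) -> risk_model.RiskConfig:
        return risk_model.RiskConfig(
            q=self.q,
            rr=self.rr,
            statin_fraction=self.statin_fraction,
            statin_efficacy=self.statin_efficacy,
        )

    def label(self) -> str:
        return (
            f"n={self.n} R={self.replicates} q={self.q} RR={self.rr} "
            f"F={self.fatality} d={self.fatality_diff} s={self.statin_fraction} "
            f"e={self.statin_efficacy}"
        )

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class ConditionResult:
    """Pooled estimate plus per-replicate fits for one condition."""

    config: ScenarioConfig
    pooled: estimation.PooledEstimate
    fits: tuple[estimation.FitResult, ...]
    pooled_with_statin: estimation.PooledEstimate | None = None
    oracle_or: float | None = None

    @property
    def mean_cases(self) -> float:
        return float(np.mean([f.n_cases for f in self.fits]))


@dataclass(frozen=True)
class ExperimentResult:
    """Grid of conditions: per-replicate and pooled tables."""

    name: str
    per_replicate: pd.DataFrame = field(repr=False)
    pooled: pd.DataFrame = field(repr=False)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_replicate.to_csv(out / f"results_{self.name}.csv", index=False)
        self.pooled.to_csv(out / f"pooled_{self.name}.csv", index=False)
        oracle_cols = [c for c in self.pooled.columns if c in (*_GRID_PARAMS, "oracle_or")]
        self.pooled[oracle_cols].rename(columns={"oracle_or": "expected_or"}).to_csv(
            out / f"oracle_{self.name}.csv", index=False
        )


def simulate_cohort(
    cfg: ScenarioConfig,
    seed: int,
    demog: demography.DemographyTable,
    incidence: risk_model.BaselineIncidenceTable,
) -> cohort_sim.Cohort:
    """Generate one replicate cohort (events drawn, fatal cases flagged)."""
    rcfg = cfg.risk_config()
    ages, sexes = demography.sample_population(demog, cfg.n, _stage_rng(seed, "population"))
    carrier = risk_model.assign_genotype(cfg.n, cfg.q, _stage_rng(seed, "genotype"))
    statin = risk_model.assign_statin(cfg.n, cfg.statin_fraction, _stage_rng(seed, "statin"))
    risk = risk_model.individual_risk(ages, sexes, carrier, statin, incidence, rcfg)
    cohort = cohort_sim.Cohort(age=ages, sex=sexes, carrier=carrier, statin=statin, risk=risk)
    cohort.event = cohort_sim.simulate_events(risk, _stage_rng(seed, "events"))
    if cfg.fatality > 0 or cfg.fatality_diff > 0:
        rates = cohort_sim.solve_fatality_rates(
            cfg.fatality, cfg.fatality_diff, cfg.q, cfg.fatality_convention
        )
        cohort_sim.apply_survival_filter(cohort, rates, _stage_rng(seed, "fatality"))
    else:
        cohort.fatal = np.zeros(cfg.n, dtype=np.int64)
        cohort.included = np.ones(cfg.n, dtype=np.int64)
    return cohort


def run_condition(
    cfg: ScenarioConfig,
    demog: demography.DemographyTable | None = None,
    incidence: risk_model.BaselineIncidenceTable | None = None,
    with_oracle: bool = False,
) -> ConditionResult:
    """Run all replicates of one condition and pool the carrier ORs.

    When ``cfg.adjust_for_statin`` is set (and 0 < s < 1), each replicate is
    fit twice — with and without the statin covariate — and both pooled
    estimates are returned.
    """
    if demog is None:
        demog = demography.load_demography("canada2006")
    if incidence is None:
        incidence = risk_model.default_calibrated_incidence()
    fit_statin = cfg.adjust_for_statin and 0.0 < cfg.statin_fraction < 1.0
    fits, fits_statin = [], []
    t0 = time.perf_counter()
    for r in range(cfg.replicates):
        cohort = simulate_cohort(cfg, cfg.base_seed + r, demog, incidence)
        data = cohort.analysis_frame()
        try:
            fits.append(estimation.fit_logistic(data, ("age", "sex", "carrier")))
            if fit_statin:
                fits_statin.append(
                    estimation.fit_logistic(data, ("age", "sex", "carrier", "statin"))
                )
        except estimation.EstimationError as exc:
            raise estimation.EstimationError(f"[{cfg.label()} rep {r}] {exc}") from exc
        logger.info(
            "condition %s rep %d: %d cases analyzed", cfg.label(), r, fits[-1].n_cases
        )
    pooled = estimation.pool_replicates(fits, condition=cfg.label())
    pooled_statin = (
        estimation.pool_replicates(fits_statin, condition=cfg.label() + " +statin-cov")
        if fit_statin
        else None
    )
    oracle_value = (
        oracle.expected_or(
            demog,
            incidence,
            cfg.risk_config(),
            F=cfg.fatality,
            d=cfg.fatality_diff,
            convention=cfg.fatality_convention,
        )
        if with_oracle
        else None
    )
    logger.info(
        "condition %s: pooled OR %.4f ± %.4f (%.1f s)",
        cfg.label(),
        pooled.pooled_or,
        pooled.mc_halfwidth,
        time.perf_counter() - t0,
    )
    return ConditionResult(
        config=cfg,
        pooled=pooled,
        fits=tuple(fits),
        pooled_with_statin=pooled_statin,
        oracle_or=oracle_value,
    )


_GRID_PARAMS = ("rr", "fatality", "fatality_diff", "statin_fraction", "statin_efficacy")


def _run_grid(
    name: str,
    configs: Iterable[ScenarioConfig],
    demog: demography.DemographyTable | None,
    incidence: risk_model.BaselineIncidenceTable | None,
    out_dir: str | Path | None = None,
    plot: bool = False,
) -> ExperimentResult:
    if demog is None:
        demog = demography.load_demography("canada2006")
    if incidence is None:
        incidence = risk_model.default_calibrated_incidence()
    rep_rows, pooled_rows = [], []
    for cfg in configs:
        res = run_condition(cfg, demog, incidence, with_oracle=True)
        base = {p: getattr(cfg, p) for p in _GRID_PARAMS}
        for r, fit in enumerate(res.fits):
            rep_rows.append(
                base
                | {
                    "replicate": r,
                    "carrier_or": fit.odds_ratio("carrier"),
                    "carrier_se": float(fit.row("carrier")["se"]),
                    "n_cases": fit.n_cases,
                }
            )
        row = base | {
            "pooled_or": res.pooled.pooled_or,
            "mc_halfwidth": res.pooled.mc_halfwidth,
            "oracle_or": res.oracle_or,
            "mean_cases": res.mean_cases,
        }
        if res.pooled_with_statin is not None:
            row["pooled_or_statin_adj"] = res.pooled_with_statin.pooled_or
        pooled_rows.append(row)
    result = ExperimentResult(
        name=name,
        per_replicate=pd.DataFrame(rep_rows),
        pooled=pd.DataFrame(pooled_rows),
    )
    if out_dir is not None:
        result.write(out_dir)
        if plot:
            _plot_grid(result, Path(out_dir))
    return result


def run_figure1_grid(
    demog: demography.DemographyTable | None = None,
    incidence: risk_model.BaselineIncidenceTable | None = None,
    base: ScenarioConfig = ScenarioConfig(),
    F_values: Sequence[float] = (0.33, 0.415, 0.50),
    rr_values: Sequence[float] = (1.25, 1.50),
    d_values: Sequence[float] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25),
    out_dir: str | Path | None = None,
    plot: bool = False,
) -> ExperimentResult:
    """Survival-bias grid: overall fatality × risk ratio × differential."""
    configs = [
        base.replace(rr=rr, fatality=F, fatality_diff=d)
        for rr in rr_values
        for F in F_values
        for d in d_values
    ]
    return _run_grid("figure1", configs, demog, incidence, out_dir, plot)


def run_figure2_grid(
    demog: demography.DemographyTable | None = None,
    incidence: risk_model.BaselineIncidenceTable | None = None,
    base: ScenarioConfig = ScenarioConfig(),
    s_values: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    rr_values: Sequence[float] = (1.25, 1.50),
    out_dir: str | Path | None = None,
    plot: bool = False,
) -> ExperimentResult:
    """Statin-use grid at full efficacy, fit with and without the statin covariate."""
    configs = [
        base.replace(
            rr=rr,
            statin_fraction=s,
            statin_efficacy=1.0,
            fatality=0.0,
            fatality_diff=0.0,
            adjust_for_statin=True,
        )
        for rr in rr_values
        for s in s_values
    ]
    return _run_grid("figure2", configs, demog, incidence, out_dir, plot)


def run_figure3_grid(
    demog: demography.DemographyTable | None = None,
    incidence: risk_model.BaselineIncidenceTable | None = None,
    base: ScenarioConfig = ScenarioConfig(),
    e_values: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    s_values: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    out_dir: str | Path | None = None,
    plot: bool = False,
) -> ExperimentResult:
    """Partial-efficacy grid at RR=1.5: statin eliminates a fraction e of excess risk."""
    configs = [
        base.replace(rr=1.5, statin_fraction=s, statin_efficacy=e)
        for e in e_values
        for s in s_values
    ]
    return _run_grid("figure3", configs, demog, incidence, out_dir, plot)


def _plot_grid(result: ExperimentResult, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.pooled
    fig, ax = plt.subplots(figsize=(6, 4))
    if result.name == "figure1":
        xcol, title = "fatality_diff", "Fatality differential between genotypes"
        groups = ["rr", "fatality"]
    elif result.name == "figure2":
        xcol, title = "statin_fraction", "Fraction of population on statins"
        groups = ["rr"]
    else:
        xcol, title = "statin_fraction", "Fraction of population on statins"
        groups = ["statin_efficacy"]
    for key, g in df.groupby(groups):
        key = key if isinstance(key, tuple) else (key,)
        lbl = ", ".join(f"{k}={v:g}" for k, v in zip(groups, key))
        g = g.sort_values(xcol)
        ax.errorbar(g[xcol], g["pooled_or"], yerr=g["mc_halfwidth"], label=lbl, marker="o")
        ax.plot(g[xcol], g["oracle_or"], ls="--", color="grey", lw=0.8)
    ax.set_xlabel(title)
    ax.set_ylabel("Carrier odds ratio (adjusted)")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / f"{result.name}.png", dpi=150)
    plt.close(fig)
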