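# survbias

Monte-Carlo simulation of two mechanisms that can make a real genetic risk
factor look null in cross-sectional case-control studies:

1. **Survival bias** — case-control studies recruit survivors. If carriers
   of a risk allele are more likely to die of their event than noncarriers,
   fatal cases are preferentially missing from the case pool and the
   observed odds ratio is attenuated.
2. **Drug effect-modification** — if a common treatment (statins) removes
   part or all of the carriers' *excess* risk, the population-level
   genotype odds ratio is diluted in proportion to treatment coverage, and
   adding treatment as a regression covariate does **not** repair it.

The worked scenario throughout is the KIF6 Trp719Arg polymorphism and
cardiovascular disease (CVD): carrier frequency q = 0.59, carrier risk
ratio RR = 1.25 or 1.50, cohorts drawn from a Canadian-style adult age/sex
distribution with Framingham-style cumulative incidence by age and sex.
It is intended for epidemiologists and statistical geneticists who want to
quantify how large these biases can plausibly be for a variant of interest.

## Model

Each simulated individual i gets an event probability

```
p_i = p0(age_i, sex_i) · m_i
m_i = 1                                   noncarrier
m_i = 1 + (RR − 1)(1 − e · statin_i)      carrier
```

where `p0` is cumulative CVD incidence from age 40 to the attained age,
`e` is the fraction of carrier excess risk eliminated by statin treatment
and `statin_i ~ Bernoulli(s)` independent of genotype. Events are drawn by
uniform comparison (`event_i = 1 iff u_i < p_i`). Each case then dies with
its genotype's case-fatality probability, solved from the overall fatality
rate F and the genotype differential d under the constraint

```
q·f_c + (1−q)·f_n = F,    f_n = (1−d)·f_c
```

so the *overall* fatality never changes as the differential grows. Fatal
cases are excluded — they can be recruited neither as cases nor as
controls — and the survivors are analyzed by logistic regression of
disease on age, sex and carrier status. Ten replicates of 1,000,000 are
pooled (mean OR, half-width 1.96·SD/√10).

Because the odds ratio exceeds the risk ratio for a non-rare outcome, the
incidence scale is fixed once by calibration: a single factor k is chosen
so the unbiased RR = 1.5 odds ratio equals the 1.55 reference anchor.
Every other quantity (the RR = 1.25 anchor ≈ 1.27, every attenuation
curve) is then out-of-sample. An analytic oracle — the same logistic model
fit to exact expected stratum counts — predicts every condition without
simulation and is what the stochastic engine is verified against.

## Worked example

```python
from survbias import (ScenarioConfig, RiskConfig, load_demography,
                      default_calibrated_incidence, run_condition, expected_or)

demog = load_demography("canada2006")
incidence = default_calibrated_incidence()   # calibrated so OR(RR=1.5) = 1.55

cfg = ScenarioConfig(n=100_000, replicates=5, base_seed=20,
                     rr=1.25, fatality=0.415, fatality_diff=0.20)
res = run_condition(cfg, demog, incidence)
print(res.pooled.pooled_or, res.pooled.mc_halfwidth)
# 1.1342 0.0491
print(expected_or(demog, incidence, RiskConfig(rr=1.25), F=0.415, d=0.20))
# 1.0898
```

A variant that truly carries 25% higher risk (unbiased OR ≈ 1.27) is
observed at OR ≈ 1.09–1.13 once 41.5% of cases are fatal and carrier cases
die 20% more often than noncarrier cases — the simulated estimate (with
Monte-Carlo half-width ≈ 0.05 at this reduced scale) brackets the analytic
expectation 1.09. The `examples/` scripts walk through the survival-bias
curve, the statin-dilution curve with the futile covariate adjustment, and
the analytic oracle grid; each prints the numbers it computes and one line
on what they mean.

The command-line interface exposes the same pipeline
(`survbias simulate`, `figure1`, `figure2`, `figure3`, `oracle`,
`calibrate`; see `survbias --help`).

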