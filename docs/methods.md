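# Methods

## Generative model

One simulated population is a cross-section of adults aged 40–89 with no
time dynamics: a single draw of (age, sex), genotype, treatment, disease
event and — for cases — survival, followed by one analysis mimicking how a
cross-sectional case-control study would use the surviving population.

**Demography.** Individuals are drawn from an age-band × sex proportion
table by one categorical draw per individual, with integer age uniform
within the 5-year band. The packaged `canada2006` table approximates the
adult (40–89) Canadian age/sex distribution; it is committed as data and
replaceable by any CSV with the same columns. The table is restricted to
ages 40+ because the risk surface is cumulative incidence *from age 40*:
younger individuals would carry exactly zero risk and only dilute the
cohort. The population structure has little leverage on the biases being
studied — it enters only through the prevalence-weighting of strata — and
this insensitivity is one of the things the oracle/simulation equivalence
tests exercise.

**Baseline risk.** `p0(age, sex)` is the probability of a first
cardiovascular event between age 40 and the attained age. The packaged
template is a smooth logistic-in-age curve per sex (male plateau above
female, both zero at 40, non-decreasing), i.e. a Framingham-like shape
rather than any published table. Its overall scale is deliberately left
free and fixed by calibration (below), which makes every downstream result
insensitive to the template's exact provenance.

**Genotype and treatment.** Carrier status is Bernoulli(q = 0.59) and
statin use Bernoulli(s), both independent of age, sex and each other.
Treatment acts *only* on the carrier excess risk: a treated carrier's
multiplier is 1 + (RR−1)(1−e), a noncarrier's risk never changes. This is
the limiting form of the clinical observation that noncarriers derive less
benefit from statins; setting e < 1 relaxes it continuously.

**Events and case fatality.** Events are drawn by uniform comparison
(`u < p`). Each case then dies with its genotype's case-fatality
probability. The pair (f_c, f_n) is solved from the overall rate F and the
differential d so that the population-weighted overall fatality is exactly
F for every d — the attenuation curves therefore isolate the *differential*
from the *level*. Two conventions for d are supported:

- `relative` (default): f_n = (1−d)·f_c, so f_c = F / (q + (1−q)(1−d));
- `mean_relative`: f_c = F(1+(1−q)d), f_n = F(1−q·d), a symmetric spread
  around F.

At F = 50%, d = 25% the default gives (55.7%, 41.8%) and the alternative
(55.1%, 42.6%); both round to the familiar 55%/43% illustration, and both
reproduce the reference attenuation series within its Monte-Carlo
tolerance. The weighted mean uses the *population* carrier frequency q
(0.59/0.41), not the case distribution.

**Exclusion and analysis.** Fatal cases are removed entirely (a dead
individual can be recruited neither as a case nor as a control). Survivors
are analyzed by maximum-likelihood logistic regression of disease on age
(continuous years), sex and carrier status (0/1), optionally plus statin
use. Age is modelled linearly on the log-odds scale even though the
generating surface is not logistic-linear — this mild misspecification is
part of the study design being simulated. Replicate carrier odds ratios
are pooled by their arithmetic mean (the OR scale is where the precision
claim lives; the difference from log-scale pooling is < 1e-4 at these
magnitudes) with 95% half-width 1.96·SD/√R.

## Calibration

The odds ratio exceeds the risk ratio whenever the outcome is not rare, by
an amount governed by the prevalence structure. One scalar k multiplies
the whole incidence template and is solved by root-finding (Brent, exact
to 1e-10) so that the analytic no-bias, no-treatment OR at RR = 1.5 equals
1.55. With the packaged template k ≈ 0.2813, giving an overall event
prevalence of ≈ 2.7% and ≈ 27,000 cases per million-person replicate. The
RR = 1.25 no-bias OR is then a genuine out-of-sample check (≈ 1.27,
against published printings of 1.29 and 1.27 for the same quantity). The
calibration is deterministic and recomputed at run time (< 1 s, memoized
in-process); the factor is recorded on the returned table and can be
exported via `survbias calibrate`.

## Analytic oracle

The expectation of the whole generative process is available in closed
form: for each age × sex × genotype (× treatment) stratum, expected
surviving-case mass `mass·p·(1−f_genotype)` and non-case mass
`mass·(1−p)`. Fitting the *same* logistic model to these fractional counts
(weighted-proportions GLM, IRLS to 1e-10) gives the exact large-sample
limit of the simulated adjusted OR, so oracle-vs-simulation equivalence
exercises the full pipeline including covariate adjustment. Two cruder
closed forms are exposed for intuition and checked against the exact
oracle: survival exclusion multiplies the carrier odds by
(1−f_c)/(1−f_n), and partial statin coverage acts like an effective
multiplier 1 + (RR−1)(1−s·e).

## Reproducibility

Replicate r of a condition uses seed `base_seed + r`; within a replicate,
every stochastic stage (population, genotype, statin, events, fatality)
draws from its own named substream (`SeedSequence([seed, stage_id])`).
Toggling one mechanism therefore never perturbs the draws of another,
which keeps ceteris-paribus comparisons across grid cells clean — e.g. the
partial-efficacy grid's e = 1 column is bit-identical to the statin grid
at the same seeds. Reruns with the same configuration are byte-identical
down to the output CSVs.

## Numerical choices and edge cases

- Logistic fits: Newton, tolerance 1e-8, 100 iterations cap;
  non-convergence, separation and empty carrier-case cells raise typed
  errors carrying the condition label.
- Individual risks are clipped at 1−1e-12 with a logged count; under the
  calibrated default (max p·RR ≈ 0.66) clipping never occurs, and the
  tests assert so.
- Demography files are renormalized when proportions sum to 1 within
  1e-6; larger deviations are rejected naming the offender.
- Fatality solving rejects parameter combinations whose implied carrier
  rate reaches 1 (e.g. high F with large d and small q).
- The oracle drops strata of zero surviving mass before fitting and
  silences the separation heuristic near the rare-disease limit, where
  every expected fraction tends to zero but the weighted point estimate
  remains exact.

## Design choices where the design was open

- **Differential convention.** The relative form f_n = (1−d)·f_c is the
  default because the reference description of the 55/43 example is a
  relative statement ("25% less"); the mean-relative form matches the
  rounded example slightly better and is available as a switch. The
  question cannot be settled from the printed numbers alone.
- **Null behaviour under differential fatality.** With RR = 1 but d > 0
  the model *correctly* produces a spurious protective OR ≈
  (1−f_c)/(1−f_n) < 1 — survival bias does not need a real effect to act
  on. The "null gives OR = 1" property therefore holds only at d = 0, and
  that is how it is tested.
- **Proportionality scale.** The statement that the odds reduction is
  proportional to the eliminated excess fraction holds tightly on the
  excess-odds scale — (OR(s,e)−1)/(OR(0)−1) is within ~0.02 of 1−s·e —
  but not on the log-OR scale, where the curvature of log(1+Δ(1−x))
  reaches ~0.03. The property test asserts the excess-odds form.
- **Adjusted vs crude invariance.** With d = 0, exclusion is
  genotype-blind and the crude OR is exactly invariant to F; the
  *adjusted* OR moves by a few 1e-4 because shrinking the case mass
  reweights the misspecified age term. Tests allow 0.005, an order of
  magnitude below Monte-Carlo noise.

## Problem sizes

Full scale is 10 replicates of 1,000,000 individuals per condition
(≈ 7 s per condition here), used by `scripts/acceptance.py` and by the
Monte-Carlo precision check, whose claim — pooled-OR half-width ≤ 0.02 —
is specific to that scale (observed ≈ 0.011). The test suite's
simulation-heavy checks run a documented reduced mode, n = 100,000 with 5
replicates, which preserves every monotonicity and equivalence property
and reproduces the full-scale odds ratios within about ±0.08; each such
check is paired with the deterministic oracle at ±0.04.

## What the generator does and does not emulate

The synthetic population reproduces the features the bias mechanisms
depend on — realistic adult age/sex structure, age- and sex-graded
cumulative risk, a common risk genotype independent of demography, and
treatment assigned independently of genotype. It does **not** model
genotype–sex or genotype–age dependence, confounding between treatment and
risk factors, competing mortality, time-to-event structure, post-event
treatment initiation, or measurement error in genotype or diagnosis.
Passing tests therefore demonstrate the internal mathematics of the two
bias mechanisms, not the magnitude of bias in any particular real study;
in real data the mechanisms can also interact (the combined mode is
supported and oracle-verified, but no published reference values exist
for it).

## Known limitations

- The incidence template and demography are plausible stand-ins, not
  published tables; the calibration step removes most, but not all,
  sensitivity to their shapes (the age-profile of prevalence still has a
  second-order effect on the adjusted OR).
- Fatality is a single post-event Bernoulli — no survival-time modelling,
  so "fatality" conflates death at event with death before recruitment.
- Genotype is binary carrier/noncarrier; per-genotype (additive) effects
  are out of scope.
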