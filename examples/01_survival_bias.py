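"""Survival bias: how excluding fatal cases attenuates a genetic odds ratio.

Simulates a cross-sectional case-control study of a common risk variant
(59% carrier frequency, 25% higher event risk for carriers) in which 41.5%
of incident cases are fatal and therefore never recruited.  As the
case-fatality gap between carriers and noncarriers widens, the observed
carrier odds ratio shrinks away from its unbiased value of about 1.27 —
even though the underlying biology never changes.
"""

from survbias import (
    RiskConfig,
    ScenarioConfig,
    default_calibrated_incidence,
    expected_or,
    load_demography,
    run_condition,
    solve_fatality_rates,
)

demog = load_demography("canada2006")
incidence = default_calibrated_incidence()  # anchored so OR(RR=1.5)=1.55

print("carrier RR = 1.25, overall case fatality = 41.5%")
print(f"{'diff':>6} {'f_carrier':>10} {'f_noncarr':>10} {'sim OR':>8} {'±':>7} {'expected':>9}")
for d in (0.0, 0.10, 0.20, 0.25):
    rates = solve_fatality_rates(F=0.415, d=d, q=0.59)
    cfg = ScenarioConfig(
        n=100_000, replicates=5, base_seed=20, rr=1.25, fatality=0.415, fatality_diff=d
    )
    res = run_condition(cfg, demog, incidence)
    exp = expected_or(demog, incidence, RiskConfig(rr=1.25), F=0.415, d=d)
    print(
        f"{d:6.2f} {rates.f_carrier:10.4f} {rates.f_noncarrier:10.4f} "
        f"{res.pooled.pooled_or:8.4f} {res.pooled.mc_halfwidth:7.4f} {exp:9.4f}"
    )

print(
    "\nEach row holds the *overall* fatality fixed at 41.5% while shifting it"
    "\nbetween genotypes; a 25% relative differential drags the observed OR"
    "\nfrom ~1.27 down to ~1.05, mimicking a null association."
)
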