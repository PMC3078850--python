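"""Drug effect-modification: statins hide a genotype from case-control studies.

Carriers of the risk allele (59% of the population) have 50% higher event
risk — unless they take a statin, which (in this scenario) removes the
entire excess.  As statin coverage grows, the population-level carrier
odds ratio slides from ~1.55 toward 1, and adding statin use as a
regression covariate does NOT bring it back: the drug interacts with the
genotype rather than shifting everyone's log odds.
"""

from survbias import ScenarioConfig, default_calibrated_incidence, load_demography, run_condition

demog = load_demography("canada2006")
incidence = default_calibrated_incidence()

print("carrier RR = 1.5 untreated, 1.0 on statin (full efficacy)")
print(f"{'statin %':>9} {'OR (crude adj)':>15} {'OR (+statin cov)':>17}")
for s in (0.0, 0.2, 0.4, 0.6, 0.9):
    cfg = ScenarioConfig(
        n=100_000,
        replicates=5,
        base_seed=40,
        rr=1.5,
        statin_fraction=s,
        statin_efficacy=1.0,
        adjust_for_statin=True,
    )
    res = run_condition(cfg, demog, incidence)
    with_cov = res.pooled_with_statin.pooled_or if res.pooled_with_statin else float("nan")
    print(f"{s:9.0%} {res.pooled.pooled_or:15.4f} {with_cov:17.4f}")

print(
    "\nBoth columns agree cell by cell: statistical adjustment for treatment"
    "\ncannot undo effect-measure modification. At 90% coverage the variant"
    "\nlooks essentially unassociated with disease."
)
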