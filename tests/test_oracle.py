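import numpy as np
import pytest

from survbias.oracle import (
    attenuation_factor,
    effective_multiplier,
    expected_cells,
    expected_or,
    expected_or_statin,
)
from survbias.risk_model import RiskConfig


class TestExpectedCells:
    def test_mass_conservation_without_exclusion(self, demog, incidence):
        cells = expected_cells(demog, incidence, RiskConfig(rr=1.5))
        total = (cells["case_mass"] + cells["noncase_mass"]).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_exclusion_removes_expected_fatal_mass(self, demog, incidence):
        F, d = 0.5, 0.25
        cells = expected_cells(demog, incidence, RiskConfig(rr=1.5), F=F, d=d)
        surviving = (cells["case_mass"] + cells["noncase_mass"]).sum()
        # overall fatality F applies to the event mass, which is genotype-weighted
        assert surviving < 1.0
        assert (cells[["case_mass", "noncase_mass"]] >= 0).all().all()

    def test_statin_strata_present_only_under_partial_use(self, demog, incidence):
        no_statin = expected_cells(demog, incidence, RiskConfig(rr=1.5))
        assert set(no_statin["statin"]) == {0}
        mixed = expected_cells(demog, incidence, RiskConfig(rr=1.5, statin_fraction=0.3))
        assert set(mixed["statin"]) == {0, 1}


class TestSurvivalBiasOracle:
    def test_no_differential_is_invariant_to_fatality_level(self, demog, incidence):
        """With d=0 exclusion hits genotypes equally and the OR is untouched.

        The crude OR is exactly invariant; the age/sex-adjusted OR moves by
        a few 1e-4 because shrinking the case mass reweights the (linear-in-
        age) analysis model, an order of magnitude below Monte-Carlo noise.
        """
        base = expected_or(demog, incidence, RiskConfig(rr=1.5))
        for F in (0.33, 0.415, 0.50):
            assert expected_or(demog, incidence, RiskConfig(rr=1.5), F=F, d=0.0) == (
                pytest.approx(base, abs=0.005)
            )

    def test_null_genotype_effect_gives_unit_or(self, demog, incidence):
        """With RR=1 and no fatality differential the OR is exactly null;
        statin use is also inert since there is no excess risk to remove."""
        for F, s in ((0.0, 0.0), (0.5, 0.0), (0.0, 0.4)):
            cfg = RiskConfig(rr=1.0, statin_fraction=s)
            assert expected_or(demog, incidence, cfg, F=F, d=0.0) == (
                pytest.approx(1.0, abs=1e-6)
            )

    def test_fatality_differential_alone_fakes_protection(self, demog, incidence):
        """Even a null genotype (RR=1) appears protective when its cases are
        preferentially removed: OR ≈ (1−f_c)/(1−f_n) < 1."""
        got = expected_or(demog, incidence, RiskConfig(rr=1.0), F=0.5, d=0.25)
        assert got < 0.9
        assert got == pytest.approx(attenuation_factor(0.5, 0.25, 0.59), abs=0.1)

    def test_strictly_decreasing_in_differential(self, demog, incidence):
        ors = [
            expected_or(demog, incidence, RiskConfig(rr=1.25), F=0.415, d=d)
            for d in (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)
        ]
        assert all(a > b for a, b in zip(ors, ors[1:]))

    def test_attenuation_approximation_tracks_exact(self, demog, incidence):
        """OR_obs ≈ OR_unbiased · (1−f_c)/(1−f_n) to first order."""
        cfg = RiskConfig(rr=1.25)
        base = expected_or(demog, incidence, cfg)
        for d in (0.10, 0.20, 0.25):
            exact = expected_or(demog, incidence, cfg, F=0.415, d=d)
            approx = base * attenuation_factor(0.415, d, cfg.q)
            assert exact == pytest.approx(approx, abs=0.01)

    def test_fatality_series_reference_values(self, demog, incidence):
        """RR=1.25, F=41.5%: published attenuation series 1.18/1.11/1.08."""
        cfg = RiskConfig(rr=1.25)
        for d, ref in ((0.10, 1.18), (0.20, 1.11), (0.25, 1.08)):
            assert expected_or(demog, incidence, cfg, F=0.415, d=d) == (
                pytest.approx(ref, abs=0.04)
            )


class TestStatinOracle:
    def test_zero_use_matches_unbiased(self, demog, incidence):
        cfg = RiskConfig(rr=1.5, statin_fraction=0.0)
        assert expected_or_statin(demog, incidence, cfg) == pytest.approx(
            expected_or(demog, incidence, cfg), abs=1e-12
        )

    def test_strictly_decreasing_in_coverage_times_efficacy(self, demog, incidence):
        points = [(0.0, 1.0), (0.2, 0.5), (0.2, 1.0), (0.5, 0.8), (0.6, 1.0), (0.9, 1.0)]
        ors = [
            expected_or_statin(
                demog, incidence, RiskConfig(rr=1.5, statin_fraction=s, statin_efficacy=e)
            )
            for s, e in sorted(points, key=lambda p: p[0] * p[1])
        ]
        assert all(a > b for a, b in zip(ors, ors[1:]))

    def test_effective_multiplier_approximation(self, demog, incidence):
        """Marginal carrier multiplier 1+(RR−1)(1−s·e) predicts the OR."""
        for s, e in ((0.4, 1.0), (0.6, 0.5)):
            cfg = RiskConfig(rr=1.5, statin_fraction=s, statin_efficacy=e)
            m = effective_multiplier(cfg)
            proxy = expected_or(demog, incidence, RiskConfig(rr=m))
            assert expected_or_statin(demog, incidence, cfg) == pytest.approx(proxy, abs=0.005)

    def test_statin_series_reference_values(self, demog, incidence):
        for rr, series in (
            (1.5, {0.2: 1.43, 0.4: 1.33, 0.6: 1.21}),
            (1.25, {0.0: 1.27, 0.2: 1.21, 0.4: 1.17, 0.6: 1.12}),
        ):
            for s, ref in series.items():
                cfg = RiskConfig(rr=rr, statin_fraction=s)
                assert expected_or_statin(demog, incidence, cfg) == (
                    pytest.approx(ref, abs=0.04)
                ), f"rr={rr} s={s}"

    def test_excess_odds_proportional_to_eliminated_fraction(self, demog, incidence):
        """The carrier excess odds shrink in proportion to s·e.

        The carrier multiplier is exactly 1+(RR−1)(1−s·e), so on the excess
        scale (OR−1)/(OR₀−1) tracks 1−s·e closely; the log-OR itself is
        visibly convex in s·e, so proportionality is asserted on the excess
        scale.
        """
        base = expected_or(demog, incidence, RiskConfig(rr=1.5)) - 1.0
        for se in (0.2, 0.4, 0.5, 0.6, 0.8, 0.9):
            cfg = RiskConfig(rr=1.5, statin_fraction=se, statin_efficacy=1.0)
            excess = expected_or_statin(demog, incidence, cfg) - 1.0
            assert excess / base == pytest.approx(1.0 - se, abs=0.02)

    def test_adjusting_for_statin_does_not_restore_or(self, demog, incidence):
        cfg = RiskConfig(rr=1.5, statin_fraction=0.4)
        unadj = expected_or_statin(demog, incidence, cfg, adjust_for_statin=False)
        adj = expected_or_statin(demog, incidence, cfg, adjust_for_statin=True)
        assert adj == pytest.approx(unadj, abs=0.01)
        # far below the no-statin OR either way
        assert adj < expected_or(demog, incidence, RiskConfig(rr=1.5)) - 0.1


class TestLimits:
    def test_rare_disease_limit_reaches_effective_rr(self, demog, template):
        tiny = template.scaled(1e-4)
        cfg = RiskConfig(rr=1.5, statin_fraction=0.4)
        assert expected_or_statin(demog, tiny, cfg) == pytest.approx(
            effective_multiplier(cfg), abs=1e-3
        )

    def test_or_exceeds_rr_for_common_outcome(self, demog, incidence):
        for rr in (1.25, 1.5):
            assert expected_or(demog, incidence, RiskConfig(rr=rr)) > rr
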