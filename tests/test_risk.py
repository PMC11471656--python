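"""Risk rules: spec'd cut-offs, tie handling, monotonicity, report compilation."""

import numpy as np
import pytest

from dissectflow.metrics import (ConditionSummary, DeformationReport,
                                 DwellResult, PhaseExtremum)
from dissectflow.risk import (RiskThresholds, assess_aneurysm_risk,
                              assess_condition, assess_extension_risk,
                              assess_high_shear_platelet,
                              assess_low_shear_thrombosis,
                              assess_occlusion_risk, compile_risk_report)

LEVEL_RANK = {"low": 0, "moderate": 1, "high": 2}
T = 0.86


def make_summary(regime="normotension", wall="normal", *,
                 pct_below_10=0.0, dwell_above_2600=0.0, dwell_above_4000=0.0,
                 flap_tip_wss_sys=(0.4, 2.0), wssg_max=1.0,
                 delta_p_min=-500.0, flap_excursion=0.0, throat=2.1):
    def dw(thr, direction, dwell):
        return DwellResult(thr, direction, dwell,
                           float(np.floor(100 * dwell / T * 10 + 0.5) / 10),
                           T, site="probe")

    dwell = [
        dw(2600.0, "above", dwell_above_2600),
        dw(4000.0, "above", dwell_above_4000),
        dw(100.0, "below", 0.5), dw(50.0, "below", 0.4),
        dw(10.0, "below", pct_below_10 / 100.0 * T),
        dw(5.0, "below", 0.0),
    ]
    ext = {k: PhaseExtremum(1.0, "site", 0.0)
           for k in ("V_max", "V_min", "SR_max", "SR_min", "P_max", "P_min")}
    return ConditionSummary(
        regime=regime, wall_tag=wall, period=T, systole_end=0.3,
        phases={"systole": dict(ext), "diastole": dict(ext)},
        dwell=dwell,
        deformation=DeformationReport(0.1, "site", (0.05, 0.08), ("a", "b")),
        flap_tip_wss={"systole": flap_tip_wss_sys,
                      "diastole": (0.1, 0.5)},
        wssg_max=PhaseExtremum(wssg_max, "wall_lower@x=15mm (C2)", 0.0),
        delta_p_min={"systole": PhaseExtremum(delta_p_min, "mid", 0.0),
                     "diastole": PhaseExtremum(delta_p_min / 2, "mid", 0.0)},
        flap_max_excursion=flap_excursion,
        throat_width=throat,
    )


class TestThrombosis:
    @pytest.mark.parametrize("pct,level", [
        (41.3, "high"),     # sustained stasis ~40% of the cycle
        (0.0, "low"),
        (15.0, "moderate"),  # boundary inclusive toward higher risk
        (35.0, "high"),
        (14.9, "low"),
    ])
    def test_levels(self, pct, level):
        e = assess_low_shear_thrombosis(make_summary(pct_below_10=pct))
        assert e.level == level
        assert e.evidence["percent_below_threshold"] == pytest.approx(pct, abs=0.1)

    def test_monotone_in_stasis_percent(self):
        ranks = [LEVEL_RANK[assess_low_shear_thrombosis(
            make_summary(pct_below_10=p)).level] for p in np.linspace(0, 99, 34)]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))

    def test_threshold_override_changes_outcome(self):
        s = make_summary(pct_below_10=20.0)
        assert assess_low_shear_thrombosis(s).level == "moderate"
        strict = RiskThresholds(stasis_percent_high=20.0)
        assert assess_low_shear_thrombosis(s, strict).level == "high"


class TestPlatelet:
    def test_mild_exposure_is_moderate(self):
        # e.g. 14.9% of the cycle above 2,600 1/s
        e = assess_high_shear_platelet(make_summary(dwell_above_2600=0.13))
        assert e.level == "moderate"
        assert e.evidence["percent_above_mild"] == pytest.approx(14.9, abs=0.2)

    def test_no_flow_is_low(self):
        assert assess_high_shear_platelet(make_summary()).level == "low"

    def test_any_time_above_4000_is_high(self):
        e = assess_high_shear_platelet(
            make_summary(dwell_above_2600=0.2, dwell_above_4000=0.01))
        assert e.level == "high"


class TestExtension:
    @pytest.mark.parametrize("wss,level", [
        ((1.7, 2.2), "low"),   # within the physiologic band
        ((5.0, 10.0), "high"),  # > 2x band upper bound
        ((2.0, 4.5), "low"),    # boundary inclusive
        ((2.0, 6.0), "moderate"),
    ])
    def test_levels(self, wss, level):
        e = assess_extension_risk(make_summary(flap_tip_wss_sys=wss))
        assert e.level == level


class TestAneurysm:
    def test_positive_wssg_maximum_is_elevated_with_locus(self):
        e = assess_aneurysm_risk(make_summary(wssg_max=10.48))
        assert e.level == "moderate"
        assert "C2" in e.evidence["predicted_dilatation_locus"]

    def test_zero_gradient_still_exceeds_permissive_cutoff(self):
        e = assess_aneurysm_risk(make_summary(wssg_max=0.0))
        assert e.level == "moderate"
        assert e.note  # the permissiveness caveat is surfaced

    def test_strongly_negative_gradient_is_low(self):
        assert assess_aneurysm_risk(make_summary(wssg_max=-1.0)).level == "low"


class TestOcclusion:
    def test_gradient_without_motion_is_moderate(self):
        e = assess_occlusion_risk(make_summary(flap_excursion=0.0,
                                               delta_p_min=-8203.8))
        assert e.level == "moderate"

    def test_no_gradient_no_motion_is_low(self):
        assert assess_occlusion_risk(
            make_summary(flap_excursion=0.0, delta_p_min=0.0)).level == "low"

    def test_large_excursion_is_high(self):
        e = assess_occlusion_risk(make_summary(flap_excursion=0.6 * 2.1))
        assert e.level == "high"

    def test_monotone_in_excursion(self):
        ranks = [LEVEL_RANK[assess_occlusion_risk(
            make_summary(flap_excursion=x, delta_p_min=-100.0)).level]
            for x in np.linspace(0.0, 2.0, 21)]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))


class TestReport:
    def _six(self):
        return [make_summary(r, w, pct_below_10=p)
                for p, (r, w) in enumerate(
                    (r, w) for r in ("hypotension", "normotension", "hypertension")
                    for w in ("normal", "atherosclerotic"))]

    def test_six_conditions_yield_six_assessments(self):
        report = compile_risk_report(self._six())
        assert len(report) == 6
        assert all(len(a.entries) == 5 for a in report)

    def test_single_condition(self):
        report = compile_risk_report([make_summary()])
        assert len(report) == 1

    def test_ordering_invariant_under_permutation(self):
        six = self._six()
        a = compile_risk_report(six)
        b = compile_risk_report(list(reversed(six)))
        assert [(x.regime, x.wall_tag) for x in a] == \
            [(x.regime, x.wall_tag) for x in b]
        assert [x.regime for x in a[:2]] == ["hypotension", "hypotension"]

    def test_every_entry_cites_evidence(self):
        for a in compile_risk_report(self._six()):
            for e in a.entries:
                assert e.evidence

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compile_risk_report([])
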