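"""Categorical risk rules applied to a condition summary.

Five assessments, each citing the numeric evidence it fired on:

* low-shear thrombosis  - fraction of the cycle the false-lumen terminus
  spends below 10 1/s (sustained stasis activates clotting factors);
* high-shear platelet activation - dwell above 2,600 1/s (vWF unfolding)
  and 4,000 1/s (maximal unfolding) at the true-lumen throat;
* dissection extension  - systolic WSS at the terminal flap segment against
  the 2.5-4.5 Pa physiologic band of medium arteries;
* aneurysm formation    - max systolic WSSG over the dissection wall against
  the -0.32 Pa/mm literature threshold (reported with a caveat: the cut-off
  is permissive, the *locus* of max WSSG is the informative output);
* functional occlusion  - flap excursion against a fraction of the throat
  width, else the presence of a true/false-lumen pressure gradient.

Every rule is monotone (worse evidence never lowers the level) and reads its
cut-offs from :class:`RiskThresholds` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .metrics import ConditionSummary

__all__ = [
    "RiskThresholds",
    "RiskEntry",
    "RiskAssessment",
    "assess_low_shear_thrombosis",
    "assess_high_shear_platelet",
    "assess_extension_risk",
    "assess_aneurysm_risk",
    "assess_occlusion_risk",
    "assess_condition",
    "compile_risk_report",
]

LEVELS = ("low", "moderate", "high")
_REGIME_ORDER = {"hypotension": 0, "normotension": 1, "hypertension": 2}
_WALL_ORDER = {"normal": 0, "atherosclerotic": 1}


@dataclass(frozen=True)
class RiskThresholds:
    sr_platelet_mild: float = 2600.0  # 1/s
    sr_platelet_high: float = 4000.0  # 1/s
    sr_stasis_high: float = 10.0  # 1/s
    sr_stasis_watch: float = 50.0  # 1/s
    physiologic_wss_band: tuple[float, float] = (2.5, 4.5)  # Pa, systolic
    wssg_aneurysm: float = -0.32  # Pa/mm
    stasis_percent_high: float = 35.0  # % of cycle below sr_stasis_high
    stasis_percent_moderate: float = 15.0
    occlusion_displacement_fraction: float = 0.5  # of true-lumen throat width

    def __post_init__(self) -> None:
        if not self.sr_platelet_mild < self.sr_platelet_high:
            raise ValueError("mild platelet threshold must be below high")
        lo, hi = self.physiologic_wss_band
        if not lo < hi:
            raise ValueError("WSS band must be ordered")
        for p in (self.stasis_percent_high, self.stasis_percent_moderate):
            if not 0.0 < p < 100.0:
                raise ValueError("stasis percents must lie in (0,100)")


@dataclass
class RiskEntry:
    name: str
    level: str  # low | moderate | high
    evidence: dict[str, object]
    rule: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if not self.evidence:
            raise ValueError("every risk entry must cite numeric evidence")


@dataclass
class RiskAssessment:
    regime: str
    wall_tag: str
    entries: list[RiskEntry]

    def __getitem__(self, name: str) -> RiskEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


class MissingEvidenceError(KeyError):
    pass


def assess_low_shear_thrombosis(summary: ConditionSummary,
                                thresholds: RiskThresholds | None = None
                                ) -> RiskEntry:
    thr = thresholds or RiskThresholds()
    try:
        d = summary.dwell_for(thr.sr_stasis_high, "below")
    except KeyError as e:
        raise MissingEvidenceError(
            f"no dwell result below {thr.sr_stasis_high} 1/s") from e
    pct = d.percent_of_cycle
    if pct >= thr.stasis_percent_high:
        level = "high"
    elif pct >= thr.stasis_percent_moderate:
        level = "moderate"
    else:
        level = "low"
    return RiskEntry(
        name="thrombosis_low_shear",
        level=level,
        evidence={"percent_below_threshold": pct, "dwell_s": d.dwell_time,
                  "threshold_s-1": thr.sr_stasis_high, "site": d.site},
        rule=(f"high if % of cycle below {thr.sr_stasis_high:g}/s >= "
              f"{thr.stasis_percent_high:g}%, moderate if >= "
              f"{thr.stasis_percent_moderate:g}% (boundaries inclusive)"),
    )


def assess_high_shear_platelet(summary: ConditionSummary,
                               thresholds: RiskThresholds | None = None
                               ) -> RiskEntry:
    thr = thresholds or RiskThresholds()
    try:
        mild = summary.dwell_for(thr.sr_platelet_mild, "above")
        hard = summary.dwell_for(thr.sr_platelet_high, "above")
    except KeyError as e:
        raise MissingEvidenceError("missing high-shear dwell results") from e
    if hard.dwell_time > 0.0:
        level = "high"
    elif mild.dwell_time > 0.0:
        level = "moderate"
    else:
        level = "low"
    return RiskEntry(
        name="platelet_high_shear",
        level=level,
        evidence={"percent_above_mild": mild.percent_of_cycle,
                  "dwell_above_mild_s": mild.dwell_time,
                  "dwell_above_high_s": hard.dwell_time,
                  "mild_threshold_s-1": thr.sr_platelet_mild,
                  "high_threshold_s-1": thr.sr_platelet_high,
                  "site": mild.site},
        rule=(f"high if any time above {thr.sr_platelet_high:g}/s; moderate "
              f"if any time above {thr.sr_platelet_mild:g}/s"),
    )


def assess_extension_risk(summary: ConditionSummary,
                          thresholds: RiskThresholds | None = None
                          ) -> RiskEntry:
    thr = thresholds or RiskThresholds()
    if "systole" not in summary.flap_tip_wss:
        raise MissingEvidenceError("no flap-tip WSS available (no dissection?)")
    lo, hi = summary.flap_tip_wss["systole"]
    band_hi = thr.physiologic_wss_band[1]
    if hi <= band_hi:
        level = "low"
    elif hi > 2.0 * band_hi:
        level = "high"
    else:
        level = "moderate"
    return RiskEntry(
        name="dissection_extension",
        level=level,
        evidence={"flap_tip_wss_systole_pa": (lo, hi),
                  "physiologic_band_pa": thr.physiologic_wss_band,
                  "site": "terminal flap segment"},
        rule=(f"low if systolic flap-tip WSS <= {band_hi:g} Pa (band upper "
              f"bound, inclusive); high if > {2*band_hi:g} Pa; else moderate"),
    )


def assess_aneurysm_risk(summary: ConditionSummary,
                         thresholds: RiskThresholds | None = None
                         ) -> RiskEntry:
    thr = thresholds or RiskThresholds()
    g = summary.wssg_max
    if g.site == "n/a":
        raise MissingEvidenceError("no WSSG series available")
    elevated = g.value > thr.wssg_aneurysm
    return RiskEntry(
        name="aneurysm_formation",
        level="moderate" if elevated else "low",
        evidence={"max_systolic_wssg_pa_per_mm": g.value,
                  "threshold_pa_per_mm": thr.wssg_aneurysm,
                  "predicted_dilatation_locus": g.site},
        rule=(f"elevated when max systolic WSSG over the dissection wall "
              f"exceeds {thr.wssg_aneurysm:g} Pa/mm"),
        note=("the literature cut-off is permissive (most positive WSSG maxima"
              " exceed it); the max-WSSG locus is the informative output"),
    )


def assess_occlusion_risk(summary: ConditionSummary,
                          thresholds: RiskThresholds | None = None
                          ) -> RiskEntry:
    thr = thresholds or RiskThresholds()
    exc = summary.flap_max_excursion  # mm
    dp = summary.delta_p_min
    if not dp:
        raise MissingEvidenceError("no pressure-difference extremum available")
    dp_min = min(dp["systole"].value, dp["diastole"].value)
    cut = thr.occlusion_displacement_fraction * summary.throat_width
    if exc >= cut:
        level = "high"
    elif abs(dp_min) > 1.0:  # a nontrivial trans-flap gradient exists
        level = "moderate"
    else:
        level = "low"
    return RiskEntry(
        name="functional_occlusion",
        level=level,
        evidence={"flap_max_excursion_mm": exc,
                  "excursion_cutoff_mm": cut,
                  "delta_p_min_pa": dp_min,
                  "site": dp["systole"].site},
        rule=(f"high if flap excursion >= "
              f"{thr.occlusion_displacement_fraction:g} x throat width; "
              "moderate if a true/false-lumen pressure gradient exists"),
    )


def assess_condition(summary: ConditionSummary,
                     thresholds: RiskThresholds | None = None
                     ) -> RiskAssessment:
    thr = thresholds or RiskThresholds()
    entries = [
        assess_low_shear_thrombosis(summary, thr),
        assess_high_shear_platelet(summary, thr),
    ]
    try:
        entries.append(assess_extension_risk(summary, thr))
    except MissingEvidenceError:
        pass
    try:
        entries.append(assess_aneurysm_risk(summary, thr))
    except MissingEvidenceError:
        pass
    entries.append(assess_occlusion_risk(summary, thr))
    return RiskAssessment(regime=summary.regime, wall_tag=summary.wall_tag,
                          entries=entries)


def compile_risk_report(summaries: list[ConditionSummary],
                        thresholds: RiskThresholds | None = None
                        ) -> list[RiskAssessment]:
    """One assessment per condition, deterministically ordered by
    (pressure regime, wall regime) regardless of input order."""
    if not summaries:
        raise ValueError("need at least one condition summary")
    ordered = sorted(summaries, key=lambda s: (_REGIME_ORDER.get(s.regime, 99),
                                               _WALL_ORDER.get(s.wall_tag, 99)))
    return [assess_condition(s, thresholds) for s in ordered]


def render_risk_report(assessments: list[RiskAssessment]) -> str:
    lines = []
    for a in assessments:
        lines.append(f"== {a.regime} / {a.wall_tag} ==")
        for e in a.entries:
            lines.append(f"  {e.name:<24s} {e.level.upper():<9s} "
                         + "; ".join(f"{k}={v}" for k, v in e.evidence.items()))
            if e.note:
                lines.append(f"    note: {e.note}")
    return "\n".join(lines) + "\n"
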