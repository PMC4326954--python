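"""Curated reference panel: twelve blood and whole-body physiology features
with literature-derived effect annotations and their observed evidence
pattern (per-sex trend direction and per-age-group lifespan correlations).

The panel encodes, as classifier inputs, the evidence summary of a
well-characterized inbred-strain aging study: declining adaptive-immunity
and red-cell features prognostic for long lifespan, rising neutrophils
prognostic for short lifespan, and a set of serum/whole-body features whose
early prognostic direction opposes their validated late-life trend.  It
serves as a worked end-to-end example and as the fixture for the
classification acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .classify import EvidenceBundle
from .data_model import Effect, EffectAnnotation, Sex
from .prognostic import PrognosticCell, PrognosticProfile, rebuild_direction
from .trends import TrendCall, TrendResult

__all__ = ["PanelFeature", "REFERENCE_PANEL", "panel_bundles", "panel_annotations"]

_AGE_GROUPS = (6.0, 12.0, 18.0, 24.0)
_S_AGE = 7.745966692414834  # sample SD of the four age groups


@dataclass(frozen=True)
class PanelFeature:
    """Evidence summary for one panel feature.

    ``trend_slope`` is the per-sex standardized slope (units/month, both
    sexes unless overridden); ``prognostic`` maps sex → {age → r} for the
    relevant cells only (non-listed cells are non-relevant).
    """

    name: str
    trend_slope: Mapping[str, float]
    prognostic: Mapping[str, Mapping[float, float]]
    early_effect: Effect
    late_effect: Effect
    label: str = ""


def _immune_decline(name: str) -> PanelFeature:
    return PanelFeature(
        name=name,
        trend_slope={"female": -0.03, "male": -0.03},
        prognostic={"female": {6.0: 0.45, 12.0: 0.45},
                    "male": {6.0: 0.25, 12.0: 0.25}},
        early_effect=Effect.beneficial,
        late_effect=Effect.beneficial,
        label="anti-immunosenescent",
    )


def _red_cell(name: str) -> PanelFeature:
    return PanelFeature(
        name=name,
        trend_slope={"female": -0.03, "male": -0.03},
        prognostic={"female": {12.0: 0.25},
                    "male": {6.0: 0.45, 12.0: 0.45}},
        early_effect=Effect.beneficial,
        late_effect=Effect.beneficial,
        label="anti-anaemic",
    )


def _early_short_late_benefit(name: str, label: str,
                              ages=(6.0,)) -> PanelFeature:
    return PanelFeature(
        name=name,
        trend_slope={"female": -0.03, "male": -0.03},
        prognostic={"female": {a: -0.40 for a in ages},
                    "male": {a: -0.40 for a in ages}},
        early_effect=Effect.deleterious,
        late_effect=Effect.beneficial,
        label=label,
    )


REFERENCE_PANEL: tuple[PanelFeature, ...] = (
    _immune_decline("B cells"),
    _immune_decline("LYMPH"),
    _red_cell("RBC"),
    _red_cell("HGB"),
    _red_cell("HCT"),
    PanelFeature(
        name="Mg",
        trend_slope={"female": -0.04, "male": -0.02},
        prognostic={"female": {12.0: 0.40}, "male": {12.0: 0.40}},
        early_effect=Effect.beneficial,
        late_effect=Effect.beneficial,
        label="anti-inflammatory",
    ),
    PanelFeature(
        name="NEUT",
        trend_slope={"female": 0.03, "male": 0.03},
        prognostic={"female": {6.0: -0.40, 12.0: -0.40},
                    "male": {6.0: -0.40, 12.0: -0.40}},
        early_effect=Effect.deleterious,
        late_effect=Effect.deleterious,
        label="pro-inflammatory",
    ),
    _early_short_late_benefit("Fe", "anti-anaemic late, oxidative damage early",
                              ages=(12.0,)),
    _early_short_late_benefit("CHr", "anti-anaemic late, oxidative damage early",
                              ages=(12.0,)),
    PanelFeature(
        name="T4",
        trend_slope={"female": -0.03, "male": -0.03},
        prognostic={"female": {12.0: 0.45, 18.0: 0.40},
                    "male": {6.0: -0.45, 12.0: 0.25}},
        early_effect=Effect.deleterious,
        late_effect=Effect.beneficial,
        label="pro-anabolic early, pro-robustness late",
    ),
    _early_short_late_benefit("BMI", "pro-anabolic early, pro-robustness late"),
    _early_short_late_benefit("HR", "pro-anabolic early, pro-robustness late"),
)


def _trend(name: str, sex: Sex, slope: float) -> TrendResult:
    call = TrendCall.down if slope < 0 else TrendCall.up
    return TrendResult(feature=name, sex=sex, slope_m=slope, p_value=1e-4,
                       r_longitudinal=slope * _S_AGE, n=200, trend_call=call)


def _profile(name: str, sex: Sex, relevant_r: Mapping[float, float]) -> PrognosticProfile:
    cells = {}
    for age in _AGE_GROUPS:
        r = relevant_r.get(age)
        if r is None:
            cells[age] = PrognosticCell(feature=name, sex=sex, age_group=age,
                                        pearson_r=0.05, p_value=0.6, n=150,
                                        relevant=False)
        else:
            cells[age] = PrognosticCell(feature=name, sex=sex, age_group=age,
                                        pearson_r=r, p_value=1e-3, n=150,
                                        relevant=True)
    return rebuild_direction(PrognosticProfile(feature=name, sex=sex,
                                               cells=cells,
                                               direction_summary=None))


def panel_annotations() -> list[EffectAnnotation]:
    return [
        EffectAnnotation(feature_name=f.name, early_effect=f.early_effect,
                         late_effect=f.late_effect, label=f.label,
                         source="curated literature review")
        for f in REFERENCE_PANEL
    ]


def panel_bundles() -> list[EvidenceBundle]:
    """The reference panel as classifier-ready evidence bundles."""
    bundles = []
    for f in REFERENCE_PANEL:
        trend = {
            Sex(s): _trend(f.name, Sex(s), slope)
            for s, slope in f.trend_slope.items()
        }
        prognosis = {
            Sex(s): _profile(f.name, Sex(s), rmap)
            for s, rmap in f.prognostic.items()
        }
        annotation = EffectAnnotation(feature_name=f.name,
                                      early_effect=f.early_effect,
                                      late_effect=f.late_effect,
                                      label=f.label,
                                      source="curated literature review")
        bundles.append(EvidenceBundle(feature=f.name, trend=trend,
                                      prognosis=prognosis, annotation=annotation))
    return bundles
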