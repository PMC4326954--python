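import pytest

from agemarkers.classify import (
    Basis,
    ClassifierSettings,
    ClassLabel,
    EvidenceBundle,
    OverallClass,
    assign_qualifiers,
    classify,
    classify_features,
    filter_volatile_evidence,
    select_candidates,
    validate_longitudinal,
)
from agemarkers.data_model import Effect, EffectAnnotation, Sex
from agemarkers.errors import AnnotationError
from agemarkers.prognostic import (
    Direction,
    PrognosticCell,
    PrognosticProfile,
    rebuild_direction,
)
from agemarkers.reference import panel_bundles
from agemarkers.trends import TrendCall, TrendResult

AGES = (6.0, 12.0, 18.0, 24.0)


def trend(slope, p=0.001, sex=Sex.female, feature="x"):
    call = TrendCall.none if p >= 0.05 or slope == 0 else (
        TrendCall.down if slope < 0 else TrendCall.up)
    return TrendResult(feature=feature, sex=sex, slope_m=slope, p_value=p,
                       r_longitudinal=slope * 7.75, n=100, trend_call=call)


def profile(relevant_r, sex=Sex.female, feature="x"):
    """relevant_r: {age: r} for relevant cells; other ages non-relevant."""
    cells = {}
    for age in AGES:
        r = relevant_r.get(age)
        if r is None:
            cells[age] = PrognosticCell(feature=feature, sex=sex, age_group=age,
                                        pearson_r=0.05, p_value=0.7, n=100,
                                        relevant=False)
        else:
            cells[age] = PrognosticCell(feature=feature, sex=sex, age_group=age,
                                        pearson_r=r, p_value=0.001, n=100,
                                        relevant=True)
    return rebuild_direction(PrognosticProfile(feature=feature, sex=sex,
                                               cells=cells,
                                               direction_summary=None))


def annotation(early, late, feature="x"):
    return EffectAnnotation(feature_name=feature, early_effect=Effect(early),
                            late_effect=Effect(late))


def bundle(trend_slope=None, relevant_r=None, early=None, late=None,
           feature="x", trend_p=0.001):
    trends = {}
    if trend_slope is not None:
        trends[Sex.female] = trend(trend_slope, p=trend_p, feature=feature)
    prognosis = {Sex.female: profile(relevant_r or {}, feature=feature)}
    ann = annotation(early, late, feature) if early or late else None
    return EvidenceBundle(feature=feature, trend=trends, prognosis=prognosis,
                          annotation=ann)


class TestFilterVolatileEvidence:
    def test_isolated_late_cell_masked(self):
        p = filter_volatile_evidence(profile({24.0: 0.4}))
        assert p.direction_summary is Direction.none
        assert not p.cells[24.0].relevant
        assert p.cells[24.0].masked_reason

    def test_late_cell_with_early_support_kept(self):
        p = filter_volatile_evidence(profile({12.0: 0.4, 18.0: 0.4}))
        assert p.cells[18.0].relevant
        assert p.direction_summary is Direction.long

    def test_concordant_volatile_pair_kept(self):
        p = filter_volatile_evidence(profile({18.0: 0.4, 24.0: 0.35}))
        assert p.cells[18.0].relevant and p.cells[24.0].relevant

    def test_concordant_pair_clause_can_be_disabled(self):
        p = filter_volatile_evidence(profile({18.0: 0.4, 24.0: 0.35}),
                                     allow_concordant_pair=False)
        assert not p.cells[18.0].relevant and not p.cells[24.0].relevant

    def test_discordant_volatile_pair_masked(self):
        p = filter_volatile_evidence(profile({18.0: 0.4, 24.0: -0.35}))
        assert p.direction_summary is Direction.none

    def test_opposite_sign_early_support_does_not_rescue(self):
        p = filter_volatile_evidence(profile({6.0: 0.4, 24.0: -0.4}))
        assert p.cells[6.0].relevant
        assert not p.cells[24.0].relevant

    def test_non_volatile_cells_untouched(self):
        p = filter_volatile_evidence(profile({6.0: 0.4, 12.0: -0.4}))
        assert p.cells[6.0].relevant and p.cells[12.0].relevant


class TestValidateLongitudinal:
    def test_down_beneficial_pro(self):
        assert validate_longitudinal(
            trend(-0.03), annotation("beneficial", "beneficial")
        ) is OverallClass.pro_longevity

    def test_up_deleterious_anti(self):
        assert validate_longitudinal(
            trend(0.03), annotation("deleterious", "deleterious")
        ) is OverallClass.antilongevity

    def test_up_unknown_effect_age_only(self):
        assert validate_longitudinal(
            trend(0.03), annotation("unknown", "unknown")
        ) is OverallClass.age_only

    def test_mismatched_valence_age_only(self):
        assert validate_longitudinal(
            trend(0.03), annotation("beneficial", "beneficial")
        ) is OverallClass.age_only

    def test_no_annotation_age_only(self):
        assert validate_longitudinal(trend(-0.03), None) is OverallClass.age_only

    def test_requires_significant_trend(self):
        with pytest.raises(ValueError):
            validate_longitudinal(trend(0.0, p=0.9), None)


class TestSelectCandidates:
    def test_trend_only_no_annotation_excluded(self):
        assert select_candidates([bundle(trend_slope=0.03)]) == []

    def test_no_trend_relevant_cell_retained(self):
        (kept,) = select_candidates([bundle(relevant_r={12.0: 0.4})])
        assert kept.feature == "x"

    def test_trend_and_prognosis_retained(self):
        (kept,) = select_candidates(
            [bundle(trend_slope=-0.03, relevant_r={12.0: 0.4},
                    early="beneficial", late="beneficial")])
        assert kept.feature == "x"

    def test_validated_trend_without_prognosis_retained(self):
        (kept,) = select_candidates(
            [bundle(trend_slope=-0.03, early="beneficial", late="beneficial")])
        assert kept.feature == "x"

    def test_volatile_filter_applied_before_selection(self):
        assert select_candidates([bundle(relevant_r={24.0: 0.4})]) == []


class TestClassify:
    def test_corroborative_pro(self):
        c = classify(bundle(trend_slope=-0.03, relevant_r={12.0: 0.4},
                            early="beneficial", late="beneficial"))
        assert c.overall is OverallClass.pro_longevity
        assert c.basis is Basis.corroborative
        assert c.class_early is c.class_late is ClassLabel.pro_longevity

    def test_conflict_resolved_role_switch(self):
        # prognosis short early, validated downtrend beneficial late
        c = classify(bundle(trend_slope=-0.03, relevant_r={12.0: -0.4},
                            early="deleterious", late="beneficial"))
        assert c.overall is OverallClass.role_switching
        assert c.basis is Basis.conflicting_resolved
        assert c.class_early is ClassLabel.antilongevity
        assert c.class_late is ClassLabel.pro_longevity

    def test_prognostic_switch(self):
        c = classify(bundle(trend_slope=-0.03,
                            relevant_r={6.0: -0.4, 12.0: 0.4, 18.0: 0.4},
                            early="deleterious", late="beneficial"))
        assert c.overall is OverallClass.role_switching
        assert c.basis is Basis.prognostic_switch
        assert c.class_early is ClassLabel.antilongevity
        assert c.class_late is ClassLabel.pro_longevity

    def test_prognostic_only_provisional(self):
        c = classify(bundle(relevant_r={12.0: -0.4}))
        assert c.overall is OverallClass.antilongevity
        assert c.basis is Basis.prognostic_only
        assert c.provisional

    def test_longitudinal_only_provisional(self):
        c = classify(bundle(trend_slope=-0.03, early="beneficial",
                            late="beneficial"))
        assert c.overall is OverallClass.pro_longevity
        assert c.basis is Basis.longitudinal_only
        assert c.provisional

    def test_unvalidated_trend_with_prognosis_is_prognostic_only(self):
        c = classify(bundle(trend_slope=0.03, relevant_r={12.0: -0.4}))
        assert c.overall is OverallClass.antilongevity
        assert c.basis is Basis.prognostic_only

    def test_contradictory_annotation_raises(self):
        # conflict resolution demands differing early/late effects
        with pytest.raises(AnnotationError):
            classify(bundle(trend_slope=0.03, relevant_r={12.0: 0.4},
                            early="deleterious", late="deleterious"))

    def test_role_switch_invariant(self):
        for b in panel_bundles():
            c = classify(b, prefiltered=False)
            if c.overall is OverallClass.role_switching:
                assert c.class_early is not c.class_late
                assert ClassLabel.none not in (c.class_early, c.class_late)
            if c.overall in (OverallClass.pro_longevity,
                             OverallClass.antilongevity):
                assert c.class_early.value == c.overall.value
                assert c.class_late.value == c.overall.value

    def test_determinism(self):
        b = bundle(trend_slope=-0.03, relevant_r={12.0: 0.4},
                   early="beneficial", late="beneficial")
        assert classify(b) == classify(b)


class TestAssignQualifiers:
    def two_sex_bundle(self, r_female, r_male):
        prognosis = {
            Sex.female: profile({12.0: r_female} if r_female else {},
                                sex=Sex.female),
            Sex.male: profile({12.0: r_male} if r_male else {}, sex=Sex.male),
        }
        return EvidenceBundle(
            feature="x",
            trend={Sex.female: trend(-0.03), Sex.male: trend(-0.03, sex=Sex.male)},
            prognosis=prognosis,
            annotation=annotation("beneficial", "beneficial"),
        )

    def test_single_sex_qualifier(self):
        b = self.two_sex_bundle(0.4, None)
        c = assign_qualifiers(b, classify(b))
        assert "pronounced in female" in c.qualifiers

    def test_margin_adds_stronger_sex(self):
        b = self.two_sex_bundle(0.45, 0.25)
        c = assign_qualifiers(b, classify(b))
        assert "pronounced in female" in c.qualifiers

    def test_small_margin_no_sex_qualifier(self):
        b = self.two_sex_bundle(0.45, 0.42)
        c = assign_qualifiers(b, classify(b))
        assert not any(q.startswith("pronounced in") for q in c.qualifiers)

    def test_single_age_qualifier(self):
        b = bundle(trend_slope=-0.03, relevant_r={12.0: 0.4},
                   early="beneficial", late="beneficial")
        c = assign_qualifiers(b, classify(b))
        assert "pronounced at 12 M" in c.qualifiers

    def test_multiple_ages_no_qualifier(self):
        b = bundle(trend_slope=-0.03, relevant_r={6.0: 0.4, 12.0: 0.4},
                   early="beneficial", late="beneficial")
        c = assign_qualifiers(b, classify(b))
        assert not any(q.startswith("pronounced at") for q in c.qualifiers)


class TestClassifyFeatures:
    def test_completeness_every_feature_classified(self):
        bundles = [
            bundle(trend_slope=-0.03, relevant_r={12.0: 0.4},
                   early="beneficial", late="beneficial", feature="a"),
            bundle(trend_slope=0.03, feature="b"),     # trend only
            bundle(feature="c"),                        # nothing
        ]
        out = classify_features(bundles)
        assert set(out) == {"a", "b", "c"}
        assert out["a"].overall is OverallClass.pro_longevity
        assert out["b"].overall is OverallClass.age_only
        assert out["c"].overall is OverallClass.unclassified

    def test_age_only_accumulating_marker(self):
        # significant uptrend, no prognosis, no known effect: marker of age
        out = classify_features([bundle(trend_slope=0.04, feature="mem")])
        assert out["mem"].overall is OverallClass.age_only
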