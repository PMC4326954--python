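"""Rule-based biomarker classification.

Combines three kinds of evidence per feature:

* longitudinal evidence — a significant trend of the feature with age;
* prognostic evidence — relevant per-age-group correlations of the feature
  with strain life expectancy (after masking volatile old-age cells);
* a literature effect annotation that validates the longitudinal trend
  (a beneficial effect for a downtrend, a deleterious one for an uptrend).

Corroborating prognostic and validated-longitudinal evidence yields a
clear-cut pro-longevity or antilongevity call.  Conflicting evidence is
resolved as a role switch: the early class comes from the prognostic side
(anchored at the earliest relevant age), the late class from the validated
longitudinal side.  A sign switch across age groups within the prognostic
evidence alone also yields a role switch.  A significant trend without
prognostic evidence and without a validating effect is merely a marker of
age, not of aging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

from .data_model import Effect, EffectAnnotation, Sex
from .errors import AnnotationError
from .prognostic import (
    Direction,
    PrognosticCell,
    PrognosticProfile,
    rebuild_direction,
)
from .trends import TrendCall, TrendResult

__all__ = [
    "ClassLabel",
    "OverallClass",
    "Basis",
    "ClassifierSettings",
    "EvidenceBundle",
    "BiomarkerClassification",
    "filter_volatile_evidence",
    "validate_longitudinal",
    "select_candidates",
    "classify",
    "assign_qualifiers",
    "classify_features",
]


class ClassLabel(str, Enum):
    pro_longevity = "pro_longevity"
    antilongevity = "antilongevity"
    none = "none"


class OverallClass(str, Enum):
    pro_longevity = "pro_longevity"
    antilongevity = "antilongevity"
    role_switching = "role_switching"
    age_only = "age_only"
    unclassified = "unclassified"


class Basis(str, Enum):
    corroborative = "corroborative"
    conflicting_resolved = "conflicting_resolved"
    prognostic_switch = "prognostic_switch"
    longitudinal_only = "longitudinal_only"
    prognostic_only = "prognostic_only"


@dataclass(frozen=True)
class ClassifierSettings:
    """Thresholds of the classification stage (all configurable)."""

    volatile_ages: frozenset = frozenset({18.0, 20.0, 24.0})
    #: keep two concordant volatile cells even without earlier support
    allow_concordant_volatile_pair: bool = True
    qualifier_margin: float = 0.15


@dataclass(frozen=True)
class EvidenceBundle:
    """All evidence for one feature: per-sex trends and prognostic profiles
    plus an optional effect annotation."""

    feature: str
    trend: Mapping[Sex, TrendResult] = field(default_factory=dict)
    prognosis: Mapping[Sex, PrognosticProfile] = field(default_factory=dict)
    annotation: EffectAnnotation | None = None

    def __post_init__(self):
        if not self.trend and not self.prognosis:
            raise ValueError(f"bundle {self.feature!r}: at least one sex required")


@dataclass(frozen=True)
class BiomarkerClassification:
    feature: str
    class_early: ClassLabel
    class_late: ClassLabel
    overall: OverallClass
    basis: Basis | None
    qualifiers: tuple = ()
    provisional: bool = False


# ---------------------------------------------------------------------------
# Volatile old-age filter
# ---------------------------------------------------------------------------


def filter_volatile_evidence(profile: PrognosticProfile,
                             volatile_ages=frozenset({18.0, 20.0, 24.0}),
                             allow_concordant_pair: bool = True) -> PrognosticProfile:
    """Mask isolated or inconsistent relevant cells at the volatile old age
    groups.

    A relevant cell at a volatile age survives only if (a) some non-volatile
    age is relevant with the same sign, or (b) at least two volatile ages are
    relevant with the same sign (clause (b) can be disabled).  Masked cells
    get ``relevant=False`` with a reason; the direction summary is rebuilt.
    """
    volatile_ages = {float(a) for a in volatile_ages}
    rel = profile.relevant_cells()
    new_cells = dict(profile.cells)
    for cell in rel:
        if cell.age_group not in volatile_ages:
            continue
        sign = 1 if cell.pearson_r > 0 else -1
        stable_support = any(
            c.age_group not in volatile_ages
            and (1 if c.pearson_r > 0 else -1) == sign
            for c in rel
        )
        volatile_support = (
            allow_concordant_pair
            and sum(
                1
                for c in rel
                if c.age_group in volatile_ages
                and (1 if c.pearson_r > 0 else -1) == sign
            )
            >= 2
        )
        if not (stable_support or volatile_support):
            new_cells[cell.age_group] = replace(
                cell, relevant=False,
                masked_reason="isolated volatile-age evidence",
            )
    return rebuild_direction(replace(profile, cells=new_cells))


def _filter_bundle(bundle: EvidenceBundle, settings: ClassifierSettings) -> EvidenceBundle:
    filtered = {
        sex: filter_volatile_evidence(
            prof,
            volatile_ages=settings.volatile_ages,
            allow_concordant_pair=settings.allow_concordant_volatile_pair,
        )
        for sex, prof in bundle.prognosis.items()
    }
    return replace(bundle, prognosis=filtered)


# ---------------------------------------------------------------------------
# Longitudinal validation
# ---------------------------------------------------------------------------


def validate_longitudinal(trend: TrendResult,
                          annotation: EffectAnnotation | None) -> OverallClass:
    """Validate a significant trend against the annotated late effect.

    A downtrend of a feature with a beneficial effect is pro-longevity, an
    uptrend of a deleterious feature is antilongevity; anything else (no or
    unknown effect, mismatched valence) is evidence of age only.
    """
    if trend.trend_call is TrendCall.none:
        raise ValueError("validate_longitudinal requires a significant trend")
    if annotation is None:
        return OverallClass.age_only
    if trend.trend_call is TrendCall.down and annotation.late_effect is Effect.beneficial:
        return OverallClass.pro_longevity
    if trend.trend_call is TrendCall.up and annotation.late_effect is Effect.deleterious:
        return OverallClass.antilongevity
    return OverallClass.age_only


def _significant_trends(bundle: EvidenceBundle) -> list[TrendResult]:
    return [t for t in bundle.trend.values() if t.trend_call is not TrendCall.none]


def _validated_class(bundle: EvidenceBundle) -> ClassLabel:
    """Best validated longitudinal class across sexes (ClassLabel.none when
    no sex has a validating trend+effect pair); sexes with conflicting
    validated calls are resolved by the smaller trend p-value."""
    calls = []
    for t in sorted(_significant_trends(bundle), key=lambda t: t.p_value):
        v = validate_longitudinal(t, bundle.annotation)
        if v is OverallClass.pro_longevity:
            calls.append(ClassLabel.pro_longevity)
        elif v is OverallClass.antilongevity:
            calls.append(ClassLabel.antilongevity)
    return calls[0] if calls else ClassLabel.none


def _relevant_cells(bundle: EvidenceBundle) -> list[PrognosticCell]:
    return [
        c
        for prof in bundle.prognosis.values()
        for c in prof.cells.values()
        if c.relevant
    ]


def _sign_by_age(cells: Iterable[PrognosticCell]) -> dict[float, int]:
    """Net correlation sign of relevant cells at each age (pooled sexes)."""
    by_age: dict[float, float] = {}
    for c in cells:
        by_age[c.age_group] = by_age.get(c.age_group, 0.0) + c.pearson_r
    return {a: (1 if s > 0 else -1) for a, s in by_age.items() if s != 0}


def _label(sign: int) -> ClassLabel:
    return ClassLabel.pro_longevity if sign > 0 else ClassLabel.antilongevity


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def select_candidates(bundles: Iterable[EvidenceBundle],
                      settings: ClassifierSettings = ClassifierSettings()
                      ) -> list[EvidenceBundle]:
    """Keep features that can be classified as biomarkers of aging.

    After the volatile old-age filter, a feature is retained if it has at
    least one relevant prognostic cell in some sex, or a significant trend
    validated by a matching effect.  A trend alone marks age, not aging.
    """
    selected = []
    for bundle in bundles:
        fb = _filter_bundle(bundle, settings)
        if _relevant_cells(fb):
            selected.append(fb)
        elif _validated_class(fb) is not ClassLabel.none:
            selected.append(fb)
    return selected


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify(bundle: EvidenceBundle,
             settings: ClassifierSettings = ClassifierSettings(),
             prefiltered: bool = True) -> BiomarkerClassification:
    """Classify one candidate feature.

    Decision order: (1) a prognostic sign switch across age groups (either
    sex) is a role switch; (2) otherwise the prognostic class is compared
    with the validated longitudinal class — agreement is corroborative,
    disagreement resolves to a role switch with the early class from the
    prognostic side and the late class from the validated longitudinal
    side; (3) a single evidence type yields a provisional call.
    """
    if not prefiltered:
        bundle = _filter_bundle(bundle, settings)

    rel = _relevant_cells(bundle)
    val = _validated_class(bundle)

    # (1) sign switch within the prognostic evidence
    signs = _sign_by_age(rel)
    if len(set(signs.values())) > 1:
        ages = sorted(signs)
        early = signs[ages[0]]
        late = signs[ages[-1]]
        if late == early:  # interleaved pattern: latest dissenting age wins
            late = next(signs[a] for a in reversed(ages) if signs[a] != early)
        return BiomarkerClassification(
            feature=bundle.feature,
            class_early=_label(early),
            class_late=_label(late),
            overall=OverallClass.role_switching,
            basis=Basis.prognostic_switch,
        )

    prog = _label(next(iter(signs.values()))) if signs else ClassLabel.none

    # (2) both evidence types defined
    if prog is not ClassLabel.none and val is not ClassLabel.none:
        if prog == val:
            return BiomarkerClassification(
                feature=bundle.feature, class_early=prog, class_late=prog,
                overall=OverallClass(prog.value), basis=Basis.corroborative,
            )
        ann = bundle.annotation
        if (ann is not None and ann.early_effect is not Effect.unknown
                and ann.early_effect is ann.late_effect):
            raise AnnotationError(
                f"{bundle.feature}: identical early/late effects cannot "
                "support a role switch"
            )
        return BiomarkerClassification(
            feature=bundle.feature, class_early=prog, class_late=val,
            overall=OverallClass.role_switching, basis=Basis.conflicting_resolved,
        )

    # (3) single evidence type
    if prog is not ClassLabel.none:
        return BiomarkerClassification(
            feature=bundle.feature, class_early=prog, class_late=prog,
            overall=OverallClass(prog.value), basis=Basis.prognostic_only,
            provisional=True,
        )
    if val is not ClassLabel.none:
        return BiomarkerClassification(
            feature=bundle.feature, class_early=val, class_late=val,
            overall=OverallClass(val.value), basis=Basis.longitudinal_only,
            provisional=True,
        )
    return BiomarkerClassification(
        feature=bundle.feature, class_early=ClassLabel.none,
        class_late=ClassLabel.none, overall=OverallClass.unclassified,
        basis=None,
    )


def assign_qualifiers(bundle: EvidenceBundle,
                      classification: BiomarkerClassification,
                      settings: ClassifierSettings = ClassifierSettings()
                      ) -> BiomarkerClassification:
    """Annotate a classification with "pronounced in <sex>" / "pronounced at
    <age> M" qualifiers.

    The sex qualifier is added when evidence is relevant in exactly one sex,
    or when both sexes are relevant and one's strongest |r| exceeds the
    other's by at least the configured margin.  The age qualifier is added
    when exactly one age group carries relevant evidence for the deciding
    prognostic direction (skipped for prognostic switches, whose direction
    is age-dependent by definition).
    """
    qualifiers = []
    rel_by_sex = {
        sex: prof.relevant_cells() for sex, prof in bundle.prognosis.items()
    }
    rel_by_sex = {s: cells for s, cells in rel_by_sex.items() if cells}
    if len(rel_by_sex) == 1:
        qualifiers.append(f"pronounced in {next(iter(rel_by_sex)).value}")
    elif len(rel_by_sex) == 2:
        strength = {s: max(abs(c.pearson_r) for c in cells)
                    for s, cells in rel_by_sex.items()}
        (s1, m1), (s2, m2) = sorted(strength.items(), key=lambda kv: -kv[1])
        if m1 - m2 >= settings.qualifier_margin:
            qualifiers.append(f"pronounced in {s1.value}")

    if classification.basis is not Basis.prognostic_switch:
        deciding = None
        if classification.basis in (Basis.corroborative, Basis.prognostic_only):
            deciding = classification.class_early
        elif classification.basis is Basis.conflicting_resolved:
            deciding = classification.class_early  # the prognostic anchor
        if deciding in (ClassLabel.pro_longevity, ClassLabel.antilongevity):
            want = 1 if deciding is ClassLabel.pro_longevity else -1
            ages = {
                c.age_group
                for cells in rel_by_sex.values()
                for c in cells
                if (1 if c.pearson_r > 0 else -1) == want
            }
            if len(ages) == 1:
                qualifiers.append(f"pronounced at {next(iter(ages)):g} M")

    return replace(classification, qualifiers=tuple(qualifiers))


def classify_features(bundles: Iterable[EvidenceBundle],
                      settings: ClassifierSettings = ClassifierSettings()
                      ) -> dict[str, BiomarkerClassification]:
    """Classify every feature: candidates through the full rule set, the
    rest routed to age-only (trend without prognosis) or unclassified."""
    bundles = list(bundles)
    filtered = [_filter_bundle(b, settings) for b in bundles]
    candidates = {b.feature: b for b in select_candidates(bundles, settings)}
    out: dict[str, BiomarkerClassification] = {}
    for fb in filtered:
        if fb.feature in candidates:
            c = classify(candidates[fb.feature], settings)
            out[fb.feature] = assign_qualifiers(candidates[fb.feature], c, settings)
        elif _significant_trends(fb):
            out[fb.feature] = BiomarkerClassification(
                feature=fb.feature, class_early=ClassLabel.none,
                class_late=ClassLabel.none, overall=OverallClass.age_only,
                basis=None,
            )
        else:
            out[fb.feature] = BiomarkerClassification(
                feature=fb.feature, class_early=ClassLabel.none,
                class_late=ClassLabel.none, overall=OverallClass.unclassified,
                basis=None,
            )
    return out
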