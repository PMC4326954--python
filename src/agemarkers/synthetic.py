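"""Synthetic cohort generator with planted classification truth.

Generates strain-stratified longitudinal phenotype data with the structure
the analysis assumes: per-strain mean lifespans (with an optional capped
short-lived subset), separate sexes, discrete measurement age groups, and
features combining a linear age trend, a strain-lifespan-mediated prognostic
signal, and i.i.d. Gaussian noise:

    value(animal, age) = trend_slope * age + b(age) * z_strain + noise

where ``z_strain`` is the strain's standardized life expectancy (within
sex) and ``b(age) = noise_sd * r / sqrt(1 - r^2)`` calibrates the planted
population correlation ``r`` with lifespan at that age.  Role switches are
planted by letting ``r`` change sign across age groups.

The planted truth table applies the same rule semantics as the
classification engine to the noiseless parameters, so recovery is testable
end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import (
    BiomarkerClassification,
    ClassifierSettings,
    EvidenceBundle,
    classify_features,
)
from .data_model import (
    Effect,
    EffectAnnotation,
    PhenotypeRecord,
    Sex,
    StrainLifespan,
)
from .errors import ConfigurationError
from .prognostic import PrognosticCell, PrognosticProfile, rebuild_direction
from .trends import TrendCall, TrendResult

__all__ = [
    "FeatureSpec",
    "ShortLivedSpec",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "planted_truth",
    "load_cohort_config",
]

#: planted correlations beyond this are treated as infeasible to calibrate
MAX_PLANTED_R = 0.99


@dataclass(frozen=True)
class FeatureSpec:
    """Data-generating parameters of one synthetic feature."""

    name: str
    trend_slope: float = 0.0                  # units per month
    prognostic_r: Mapping[float, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    early_effect: Effect = Effect.unknown
    late_effect: Effect = Effect.unknown
    #: optional per-sex multipliers, e.g. {"female": {"slope": 1.5, "r": 1.0}}
    sex_modifier: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self):
        object.__setattr__(self, "early_effect", Effect(self.early_effect))
        object.__setattr__(self, "late_effect", Effect(self.late_effect))
        object.__setattr__(
            self, "prognostic_r",
            {float(a): float(r) for a, r in self.prognostic_r.items()})
        if not self.noise_sd > 0:
            raise ConfigurationError(f"{self.name}: noise_sd must be positive")
        for age, r in self.prognostic_r.items():
            if abs(r) >= 1:
                raise ConfigurationError(
                    f"{self.name}: |prognostic_r[{age}]| must be < 1"
                )

    def modifiers(self, sex: Sex) -> tuple[float, float]:
        mod = (self.sex_modifier or {}).get(sex.value, {})
        return float(mod.get("slope", 1.0)), float(mod.get("r", 1.0))


@dataclass(frozen=True)
class ShortLivedSpec:
    """Disease-truncated subset: lifespans capped, optionally with record
    dropout past the strain's life expectancy."""

    n_strains: int = 0
    lifespan_cap: float = 18.0
    dropout: bool = False


@dataclass(frozen=True)
class CohortConfig:
    n_strains: int = 30
    n_animals_per_strain_sex: int = 8
    age_groups: Sequence[float] = (6.0, 12.0, 18.0, 24.0)
    lifespan_mean: float = 26.0
    lifespan_sd: float = 5.0
    short_lived: ShortLivedSpec = field(default_factory=ShortLivedSpec)
    features: Sequence[FeatureSpec] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_strains <= 0 or self.n_animals_per_strain_sex <= 0:
            raise ConfigurationError("cohort sizes must be positive")
        ages = [float(a) for a in self.age_groups]
        if ages != sorted(ages) or len(set(ages)) != len(ages):
            raise ConfigurationError("age_groups must be strictly increasing")
        if self.short_lived.n_strains >= self.n_strains:
            raise ConfigurationError(
                "short_lived.n_strains must be smaller than n_strains"
            )
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate feature names in config")


@dataclass
class Cohort:
    """Generated cohort plus the planted truth table."""

    records: list
    lifespans: list
    annotations: list
    truth: dict                      # feature -> OverallClass
    short_lived_strains: tuple = ()

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"feature": f, "expected_class": c.value} for f, c in self.truth.items()]
        )


def _calibration_b(r: float, noise_sd: float, name: str) -> float:
    if abs(r) > MAX_PLANTED_R:
        raise ConfigurationError(
            f"{name}: planted correlation {r} infeasible for noise_sd {noise_sd}"
        )
    return noise_sd * r / math.sqrt(1.0 - r * r)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a deterministic cohort for the configured seed."""
    rng = np.random.default_rng(config.seed)
    strains = [f"S{i:02d}" for i in range(config.n_strains)]
    short = tuple(strains[: config.short_lived.n_strains])
    ages = [float(a) for a in config.age_groups]

    lifespans: list[StrainLifespan] = []
    life: dict[tuple[str, Sex], float] = {}
    for sex in (Sex.female, Sex.male):
        for s in strains:
            le = float(rng.normal(config.lifespan_mean, config.lifespan_sd))
            if s in short:
                cap = config.short_lived.lifespan_cap
                le = float(rng.uniform(0.55, 0.95) * cap)
            le = max(le, 4.0)
            life[(s, sex)] = le
            lifespans.append(StrainLifespan(strain=s, sex=sex, life_expectancy=le))

    records: list[PhenotypeRecord] = []
    for sex in (Sex.female, Sex.male):
        les = np.array([life[(s, sex)] for s in strains])
        z = (les - les.mean()) / les.std()  # population SD across strains
        zmap = dict(zip(strains, z))
        for s in strains:
            for i in range(config.n_animals_per_strain_sex):
                animal_id = f"{s}-{sex.value[0]}{i:02d}"
                for age in ages:
                    if config.short_lived.dropout and age > life[(s, sex)]:
                        continue
                    values = {}
                    for spec in config.features:
                        slope_mod, r_mod = spec.modifiers(sex)
                        r = float(spec.prognostic_r.get(age, 0.0)) * r_mod
                        b = _calibration_b(r, spec.noise_sd, spec.name)
                        values[spec.name] = (
                            spec.trend_slope * slope_mod * age
                            + b * zmap[s]
                            + float(rng.normal(0.0, spec.noise_sd))
                        )
                    records.append(
                        PhenotypeRecord(animal_id=animal_id, strain=s, sex=sex,
                                        age_months=age, values=values)
                    )

    annotations = [
        EffectAnnotation(feature_name=f.name, early_effect=f.early_effect,
                         late_effect=f.late_effect, source="synthetic")
        for f in config.features
        if f.early_effect is not Effect.unknown or f.late_effect is not Effect.unknown
    ]
    truth = planted_truth(config)
    return Cohort(records=records, lifespans=lifespans, annotations=annotations,
                  truth=truth, short_lived_strains=short)


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------


def _ideal_bundle(spec: FeatureSpec, config: CohortConfig,
                  r_min: float, slope_min: float) -> EvidenceBundle:
    """Noiseless evidence implied by a feature spec: trends are significant
    whenever the planted slope is materially nonzero, prognostic cells are
    relevant whenever the planted |r| clears the relevance threshold."""
    trend = {}
    prognosis = {}
    ages = [float(a) for a in config.age_groups]
    s_age = float(np.std(ages, ddof=1)) if len(ages) > 1 else 1.0
    for sex in (Sex.female, Sex.male):
        slope_mod, r_mod = spec.modifiers(sex)
        slope = spec.trend_slope * slope_mod
        significant = abs(slope) >= slope_min
        call = (TrendCall.down if slope < 0 else TrendCall.up) if significant \
            else TrendCall.none
        trend[sex] = TrendResult(
            feature=spec.name, sex=sex, slope_m=slope,
            p_value=0.0 if significant else 1.0,
            r_longitudinal=max(-1.0, min(1.0, slope * s_age)),
            n=0, trend_call=call,
        )
        cells = {}
        for age in ages:
            r = float(spec.prognostic_r.get(age, 0.0)) * r_mod
            cells[age] = PrognosticCell(
                feature=spec.name, sex=sex, age_group=age, pearson_r=r,
                p_value=0.0 if r != 0 else 1.0, n=0,
                relevant=abs(r) >= r_min,
            )
        prognosis[sex] = rebuild_direction(
            PrognosticProfile(feature=spec.name, sex=sex, cells=cells,
                              direction_summary=None)
        )
    annotation = None
    if spec.early_effect is not Effect.unknown or spec.late_effect is not Effect.unknown:
        annotation = EffectAnnotation(feature_name=spec.name,
                                      early_effect=spec.early_effect,
                                      late_effect=spec.late_effect)
    return EvidenceBundle(feature=spec.name, trend=trend, prognosis=prognosis,
                          annotation=annotation)


def planted_truth(config: CohortConfig, r_min: float = 0.2,
                  slope_min: float = 1e-12,
                  settings: ClassifierSettings = ClassifierSettings()
                  ) -> dict[str, object]:
    """Expected classification per feature, as a pure function of the specs.

    Applies the classification engine's own rule set to the idealized
    (noiseless) evidence so generator and engine share one semantics.
    Returns a map feature name → overall class.
    """
    bundles = [
        _ideal_bundle(spec, config, r_min=r_min, slope_min=slope_min)
        for spec in config.features
    ]
    classified = classify_features(bundles, settings)
    return {name: c.overall for name, c in classified.items()}


# ---------------------------------------------------------------------------
# Config file loading
# ---------------------------------------------------------------------------


def _feature_from_dict(d: Mapping) -> FeatureSpec:
    return FeatureSpec(
        name=str(d["name"]),
        trend_slope=float(d.get("trend_slope", 0.0)),
        prognostic_r={float(k): float(v)
                      for k, v in (d.get("prognostic_r") or {}).items()},
        noise_sd=float(d.get("noise_sd", 1.0)),
        early_effect=Effect(d.get("early_effect", "unknown")),
        late_effect=Effect(d.get("late_effect", "unknown")),
        sex_modifier=d.get("sex_modifier"),
    )


def cohort_config_from_dict(d: Mapping) -> CohortConfig:
    short = d.get("short_lived") or {}
    return CohortConfig(
        n_strains=int(d.get("n_strains", 30)),
        n_animals_per_strain_sex=int(d.get("n_animals_per_strain_sex", 8)),
        age_groups=tuple(float(a) for a in d.get("age_groups", (6, 12, 18, 24))),
        lifespan_mean=float(d.get("lifespan_mean", 26.0)),
        lifespan_sd=float(d.get("lifespan_sd", 5.0)),
        short_lived=ShortLivedSpec(
            n_strains=int(short.get("n_strains", 0)),
            lifespan_cap=float(short.get("lifespan_cap", 18.0)),
            dropout=bool(short.get("dropout", False)),
        ),
        features=tuple(_feature_from_dict(f) for f in d.get("features", ())),
        seed=int(d.get("seed", 0)),
    )


def load_cohort_config(path) -> CohortConfig:
    """Load a YAML cohort configuration mirroring the CohortConfig fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return cohort_config_from_dict(data)
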