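"""Domain types and tabular I/O shared by every pipeline stage.

The pipeline operates on per-animal phenotype records (one animal at one
measurement age, with a feature→value map) joined against a strain-level
life-expectancy table.  Missing values are first class: they are carried as
``NaN`` and never imputed; downstream operations use pairwise-complete
deletion and report the effective sample size.

Sexes are a hard stratum — no operation in this package ever pools them.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MergeError, SchemaError, TableParseError, ValidationError

__all__ = [
    "Sex",
    "Effect",
    "PhenotypeRecord",
    "MergedRecord",
    "StrainLifespan",
    "EffectAnnotation",
    "MergeResult",
    "DAYS_PER_MONTH",
    "MANDATORY_COLUMNS",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_lifespan_table",
    "write_lifespan_table",
    "read_effect_annotations",
    "write_effect_annotations",
    "merge_lifespan",
    "derive_absolute_counts",
    "records_to_frame",
    "frame_to_records",
    "feature_names",
]

#: Average month length used to convert day-based lifespans to months.
DAYS_PER_MONTH = 30.44

MANDATORY_COLUMNS = ("animal_id", "strain", "sex", "age_months")

_SEX_TOKENS = {
    "female": "female",
    "f": "female",
    "male": "male",
    "m": "male",
}


class Sex(str, Enum):
    """Biological sex stratum; analyses never pool across it."""

    female = "female"
    male = "male"


class Effect(str, Enum):
    """Literature-derived valence of a feature's effect on fitness."""

    beneficial = "beneficial"
    deleterious = "deleterious"
    unknown = "unknown"


def _coerce_sex(value, row=None) -> Sex:
    if isinstance(value, Sex):
        return value
    token = str(value).strip().lower()
    if token not in _SEX_TOKENS:
        where = "" if row is None else f" (row {row})"
        raise TableParseError(f"unknown sex token {value!r}{where}")
    return Sex(_SEX_TOKENS[token])


@dataclass(frozen=True)
class PhenotypeRecord:
    """One animal's measurements at one age group."""

    animal_id: str
    strain: str
    sex: Sex
    age_months: float
    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.age_months <= 0:
            raise ValidationError(
                f"record {self.animal_id!r}: age_months must be positive"
            )

    def value(self, feature: str) -> float:
        """Return the feature value, ``NaN`` if missing or absent."""
        v = self.values.get(feature, math.nan)
        return math.nan if v is None else float(v)

    def is_missing(self, feature: str) -> bool:
        return math.isnan(self.value(feature))


@dataclass(frozen=True)
class MergedRecord(PhenotypeRecord):
    """A phenotype record carrying its strain × sex life expectancy."""

    life_expectancy: float = math.nan
    event_observed: bool = True

    def __post_init__(self):
        super().__post_init__()
        if not self.life_expectancy > 0:
            raise ValidationError(
                f"record {self.animal_id!r}: life_expectancy must be positive"
            )


@dataclass(frozen=True)
class StrainLifespan:
    """Strain-level life expectancy, used as merge target and survival time."""

    strain: str
    sex: Sex
    life_expectancy: float
    event_observed: bool = True

    def __post_init__(self):
        if not self.life_expectancy > 0:
            raise ValidationError(
                f"strain {self.strain!r}/{self.sex}: life_expectancy must be positive"
            )


@dataclass(frozen=True)
class EffectAnnotation:
    """Curated early/late effect valence for one feature."""

    feature_name: str
    early_effect: Effect = Effect.unknown
    late_effect: Effect = Effect.unknown
    label: str = ""
    source: str = ""


@dataclass
class MergeResult:
    """Outcome of :func:`merge_lifespan` with the drop count reported."""

    records: list
    n_dropped: int = 0
    dropped_strains: tuple = ()

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def _parse_float(token: str) -> float:
    """Numeric cell parser: blank or non-numeric becomes NaN, never zero."""
    token = str(token).strip()
    if not token:
        return math.nan
    try:
        return float(token)
    except ValueError:
        return math.nan


def read_phenotype_table(path, schema: Sequence[str] | None = None) -> list[PhenotypeRecord]:
    """Read a phenotype CSV (header + one animal × age group per row).

    Parameters
    ----------
    path : path-like
        CSV with mandatory columns ``animal_id, strain, sex, age_months``
        followed by one column per feature.
    schema : sequence of str, optional
        Expected feature columns.  When given, every named column must be
        present; when omitted all non-mandatory columns are features.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column '{col}'")
    if schema is not None:
        absent = [f for f in schema if f not in df.columns]
        if absent:
            raise SchemaError(f"missing feature column(s): {', '.join(absent)}")
        features = list(schema)
    else:
        features = [c for c in df.columns if c not in MANDATORY_COLUMNS]

    records = []
    for idx, row in df.iterrows():
        sex = _coerce_sex(row["sex"], row=idx)
        try:
            age = float(row["age_months"])
        except ValueError as exc:
            raise TableParseError(
                f"row {idx}: cannot parse age_months {row['age_months']!r}"
            ) from exc
        values = {f: _parse_float(row[f]) for f in features}
        records.append(
            PhenotypeRecord(
                animal_id=str(row["animal_id"]),
                strain=str(row["strain"]),
                sex=sex,
                age_months=age,
                values=values,
            )
        )
    return records


def write_phenotype_table(records: Iterable[PhenotypeRecord], path,
                          features: Sequence[str] | None = None) -> None:
    """Write records to CSV; missing values become blank cells."""
    records = list(records)
    if features is None:
        features = feature_names(records)
    rows = []
    for r in records:
        row = {
            "animal_id": r.animal_id,
            "strain": r.strain,
            "sex": r.sex.value,
            "age_months": r.age_months,
        }
        for f in features:
            v = r.value(f)
            row[f] = "" if math.isnan(v) else v
        rows.append(row)
    pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS) + list(features)).to_csv(
        path, index=False
    )


def read_lifespan_table(path, unit: str = "months") -> list[StrainLifespan]:
    """Read a strain × sex life-expectancy CSV.

    Columns: ``strain, sex, life_expectancy`` and optionally
    ``event_observed``.  ``unit='days'`` converts durations to months by
    dividing by ``DAYS_PER_MONTH``.
    """
    if unit not in {"months", "days"}:
        raise ValidationError(f"unknown lifespan unit {unit!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("strain", "sex", "life_expectancy"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column '{col}'")
    out, seen = [], set()
    for idx, row in df.iterrows():
        sex = _coerce_sex(row["sex"], row=idx)
        try:
            le = float(row["life_expectancy"])
        except ValueError as exc:
            raise TableParseError(
                f"row {idx}: cannot parse life_expectancy {row['life_expectancy']!r}"
            ) from exc
        if unit == "days":
            le /= DAYS_PER_MONTH
        key = (str(row["strain"]), sex)
        if key in seen:
            raise ValidationError(f"duplicate lifespan entry for {key[0]!r}/{sex.value}")
        seen.add(key)
        event = True
        if "event_observed" in df.columns:
            token = str(row["event_observed"]).strip().lower()
            event = token not in {"0", "false", "no"}
        out.append(StrainLifespan(strain=key[0], sex=sex, life_expectancy=le,
                                  event_observed=event))
    return out


def write_lifespan_table(lifespans: Iterable[StrainLifespan], path) -> None:
    rows = [
        {
            "strain": l.strain,
            "sex": l.sex.value,
            "life_expectancy": l.life_expectancy,
            "event_observed": l.event_observed,
        }
        for l in lifespans
    ]
    pd.DataFrame(rows, columns=["strain", "sex", "life_expectancy", "event_observed"]
                 ).to_csv(path, index=False)


def read_effect_annotations(path) -> list[EffectAnnotation]:
    """Read the curated effect-annotation CSV
    (``feature_name, early_effect, late_effect, label, source``)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "feature_name" not in df.columns:
        raise SchemaError("missing mandatory column 'feature_name'")
    out, seen = [], set()
    for idx, row in df.iterrows():
        name = str(row["feature_name"])
        if name in seen:
            raise ValidationError(f"duplicate annotation for feature {name!r}")
        seen.add(name)

        def _effect(col):
            token = str(row.get(col, "")).strip().lower() or "unknown"
            try:
                return Effect(token)
            except ValueError as exc:
                raise TableParseError(f"row {idx}: unknown effect token {token!r}") from exc

        out.append(
            EffectAnnotation(
                feature_name=name,
                early_effect=_effect("early_effect"),
                late_effect=_effect("late_effect"),
                label=str(row.get("label", "")),
                source=str(row.get("source", "")),
            )
        )
    return out


def write_effect_annotations(annotations: Iterable[EffectAnnotation], path) -> None:
    rows = [
        {
            "feature_name": a.feature_name,
            "early_effect": a.early_effect.value,
            "late_effect": a.late_effect.value,
            "label": a.label,
            "source": a.source,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["feature_name", "early_effect", "late_effect",
                                "label", "source"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Merging and derivation
# ---------------------------------------------------------------------------


def merge_lifespan(records: Iterable[PhenotypeRecord],
                   lifespans: Iterable[StrainLifespan],
                   drop_unmatched: bool = False) -> MergeResult:
    """Attach each record's strain × sex life expectancy.

    Phenotype values are never altered.  With ``drop_unmatched`` unset, any
    record whose strain × sex has no lifespan entry raises :class:`MergeError`
    naming the strains; otherwise such records are dropped and counted.
    """
    table = {(l.strain, l.sex): l for l in lifespans}
    records = list(records)
    unmatched = sorted({r.strain for r in records if (r.strain, r.sex) not in table})
    if unmatched and not drop_unmatched:
        raise MergeError(
            "no life expectancy for strain(s): " + ", ".join(unmatched)
        )
    merged, dropped = [], 0
    for r in records:
        entry = table.get((r.strain, r.sex))
        if entry is None:
            dropped += 1
            continue
        merged.append(
            MergedRecord(
                animal_id=r.animal_id,
                strain=r.strain,
                sex=r.sex,
                age_months=r.age_months,
                values=r.values,
                life_expectancy=entry.life_expectancy,
                event_observed=entry.event_observed,
            )
        )
    return MergeResult(records=merged, n_dropped=dropped,
                       dropped_strains=tuple(unmatched))


def _derived_name(pct_feature: str) -> str:
    if pct_feature.startswith("pct"):
        return "n" + pct_feature[3:]
    return "n_" + pct_feature


def derive_absolute_counts(records: Iterable[PhenotypeRecord], total_feature: str,
                           pct_features: Sequence[str]) -> list[PhenotypeRecord]:
    """Add absolute counts computed from percentages of a total count.

    For each percentage feature ``pctX`` a new feature ``nX`` is added with
    value ``total × pct / 100``.  Missing inputs propagate to missing outputs.
    Negative totals or percentages outside [0, 100] raise
    :class:`ValidationError` naming the record.
    """
    out = []
    for r in records:
        total = r.value(total_feature)
        if not math.isnan(total) and total < 0:
            raise ValidationError(
                f"record {r.animal_id!r}: negative {total_feature} value {total}"
            )
        values = dict(r.values)
        for pf in pct_features:
            pct = r.value(pf)
            if not math.isnan(pct) and not (0.0 <= pct <= 100.0):
                raise ValidationError(
                    f"record {r.animal_id!r}: {pf}={pct} outside [0, 100]"
                )
            derived = math.nan
            if not math.isnan(total) and not math.isnan(pct):
                derived = total * pct / 100.0
            values[_derived_name(pf)] = derived
        out.append(dataclasses.replace(r, values=values))
    return out


# ---------------------------------------------------------------------------
# DataFrame bridge used by the analysis stages
# ---------------------------------------------------------------------------


def feature_names(records: Iterable[PhenotypeRecord]) -> list[str]:
    """Union of feature names in order of first appearance."""
    names: dict[str, None] = {}
    for r in records:
        for f in r.values:
            names.setdefault(f, None)
    return list(names)


def records_to_frame(records: Iterable[PhenotypeRecord]) -> pd.DataFrame:
    """Flatten records into an analysis DataFrame (one row per record)."""
    rows = []
    for r in records:
        row = {
            "animal_id": r.animal_id,
            "strain": r.strain,
            "sex": r.sex.value,
            "age_months": float(r.age_months),
        }
        if isinstance(r, MergedRecord):
            row["life_expectancy"] = float(r.life_expectancy)
            row["event_observed"] = bool(r.event_observed)
        row.update({f: r.value(f) for f in r.values})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame,
                     features: Sequence[str] | None = None) -> list[PhenotypeRecord]:
    """Inverse of :func:`records_to_frame` (merged columns produce
    :class:`MergedRecord`)."""
    reserved = set(MANDATORY_COLUMNS) | {"life_expectancy", "event_observed"}
    if features is None:
        features = [c for c in df.columns if c not in reserved]
    merged = "life_expectancy" in df.columns
    out = []
    for _, row in df.iterrows():
        values = {f: _parse_float(row[f]) if isinstance(row[f], str) else
                  (math.nan if pd.isna(row[f]) else float(row[f]))
                  for f in features}
        kwargs = dict(
            animal_id=str(row["animal_id"]),
            strain=str(row["strain"]),
            sex=_coerce_sex(row["sex"]),
            age_months=float(row["age_months"]),
            values=values,
        )
        if merged:
            out.append(MergedRecord(life_expectancy=float(row["life_expectancy"]),
                                    event_observed=bool(row.get("event_observed", True)),
                                    **kwargs))
        else:
            out.append(PhenotypeRecord(**kwargs))
    return out


def as_frame(data) -> pd.DataFrame:
    """Accept either a record list or an already-flattened DataFrame."""
    if isinstance(data, pd.DataFrame):
        return data
    if isinstance(data, MergeResult):
        return records_to_frame(data.records)
    return records_to_frame(data)
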