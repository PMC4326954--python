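"""Strain stratification: re-analysis without short-lived strains, and
per-strain trend-speed comparison against the pooled longer-lived reference.

The comparison statistic: the reference slope is fit on the pooled
longer-lived strains; each short-lived strain's slope is fit on its own
records (same standardization as the pooled cohort, so slopes are
comparable).  A strain is *opposite* when its slope's sign differs from the
reference and both are significantly nonzero; *faster* when same-signed,
at least ``ratio_threshold`` times the reference magnitude and the excess
clears ``z_threshold`` pooled standard errors; otherwise *concordant*
(*indeterminate* when either fit is degenerate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_model import PhenotypeRecord, Sex, StrainLifespan, as_frame
from .trends import standardize

__all__ = [
    "StrainTrend",
    "TrendComparison",
    "ComparisonCategory",
    "ExclusionResult",
    "exclude_strains",
    "flag_short_lived",
    "compare_trends",
]


class ComparisonCategory(str, Enum):
    concordant = "concordant"
    faster = "faster"
    opposite = "opposite"
    indeterminate = "indeterminate"


@dataclass(frozen=True)
class StrainTrend:
    strain: str
    feature: str
    sex: Sex
    slope: float
    se: float
    n: int


@dataclass(frozen=True)
class TrendComparison:
    strain: str
    feature: str
    sex: Sex
    category: ComparisonCategory
    strain_slope: float
    reference_slope: float
    reason: str | None = None


@dataclass
class ExclusionResult:
    records: list
    lifespans: list
    n_records_removed: int
    n_lifespans_removed: int
    unknown_strains: tuple = ()
    warnings: tuple = ()

    def __iter__(self):
        # allow ``records, lifespans = exclude_strains(...)``
        return iter((self.records, self.lifespans))


def exclude_strains(records: Iterable[PhenotypeRecord],
                    lifespans: Iterable[StrainLifespan],
                    excluded: Sequence[str]) -> ExclusionResult:
    """Remove all records and lifespan rows of the excluded strains.

    Unknown strains produce a warning and leave the input unchanged for that
    name.  If the exclusion empties a sex × age stratum that previously had
    records, a warning is attached for downstream reporting.
    """
    records = list(records)
    lifespans = list(lifespans)
    excluded = list(excluded)
    present = {r.strain for r in records} | {l.strain for l in lifespans}
    unknown = tuple(sorted(set(excluded) - present))
    for s in unknown:
        warnings.warn(f"excluded strain {s!r} not present in input", stacklevel=2)

    drop = set(excluded) & present
    kept_records = [r for r in records if r.strain not in drop]
    kept_lifespans = [l for l in lifespans if l.strain not in drop]

    notes = []
    before = {(r.sex, r.age_months) for r in records}
    after = {(r.sex, r.age_months) for r in kept_records}
    for sex, age in sorted(before - after, key=lambda t: (t[0].value, t[1])):
        notes.append(f"exclusion emptied stratum {sex.value} x {age:g} M")
    for note in notes:
        warnings.warn(note, stacklevel=2)

    return ExclusionResult(
        records=kept_records,
        lifespans=kept_lifespans,
        n_records_removed=len(records) - len(kept_records),
        n_lifespans_removed=len(lifespans) - len(kept_lifespans),
        unknown_strains=unknown,
        warnings=tuple(notes),
    )


def flag_short_lived(lifespans: Iterable[StrainLifespan],
                     quantile: float = 0.25) -> list[str]:
    """Convenience: strains whose mean life expectancy (across sexes) falls
    below the given quantile of the strain means."""
    by_strain: dict[str, list[float]] = {}
    for l in lifespans:
        by_strain.setdefault(l.strain, []).append(l.life_expectancy)
    means = {s: float(np.mean(v)) for s, v in by_strain.items()}
    cut = float(np.quantile(list(means.values()), quantile))
    return sorted(s for s, m in means.items() if m < cut)


def _ols(ages: np.ndarray, z: np.ndarray):
    """Slope, SE and n of z ~ age; None when degenerate."""
    mask = ~np.isnan(z)
    ages, z = ages[mask], z[mask]
    if len(z) < 3 or np.unique(ages).size < 2:
        return None
    fit = stats.linregress(ages, z)
    return float(fit.slope), float(fit.stderr), len(z)


def compare_trends(records, feature: str, sex, short_lived: Sequence[str],
                   z_threshold: float = 1.96,
                   ratio_threshold: float = 2.0) -> list[TrendComparison]:
    """Compare each short-lived strain's trend speed for one feature × sex
    against the pooled longer-lived reference."""
    df = as_frame(records)
    sex = Sex(sex)
    sub = df[df["sex"] == sex.value].copy()
    # one standardization over the whole sex cohort keeps slopes comparable
    sub[feature] = standardize(sub[feature].to_numpy(dtype=float))
    short = [s for s in short_lived if s in set(sub["strain"])]

    ref = sub[~sub["strain"].isin(short)]
    ref_fit = _ols(ref["age_months"].to_numpy(dtype=float),
                   ref[feature].to_numpy(dtype=float))

    out = []
    for strain in short:
        own = sub[sub["strain"] == strain]
        own_fit = _ols(own["age_months"].to_numpy(dtype=float),
                       own[feature].to_numpy(dtype=float))
        if ref_fit is None or own_fit is None:
            out.append(TrendComparison(
                strain=strain, feature=feature, sex=sex,
                category=ComparisonCategory.indeterminate,
                strain_slope=np.nan if own_fit is None else own_fit[0],
                reference_slope=np.nan if ref_fit is None else ref_fit[0],
                reason="degenerate fit",
            ))
            continue
        m_ref, se_ref, _ = ref_fit
        m_own, se_own, _ = own_fit
        category = ComparisonCategory.concordant
        opposite_signs = np.sign(m_own) != np.sign(m_ref) and m_own != 0 and m_ref != 0
        both_significant = (
            se_own > 0 and se_ref > 0
            and abs(m_own) / se_own >= z_threshold
            and abs(m_ref) / se_ref >= z_threshold
        )
        pooled_se = float(np.hypot(se_own, se_ref))
        if opposite_signs and both_significant:
            category = ComparisonCategory.opposite
        elif (
            not opposite_signs
            and m_ref != 0
            and abs(m_own) >= ratio_threshold * abs(m_ref)
            # signed excess in the reference direction, in pooled-SE units
            and pooled_se > 0
            and (m_own - m_ref) * np.sign(m_ref) / pooled_se >= z_threshold
        ):
            category = ComparisonCategory.faster
        out.append(TrendComparison(
            strain=strain, feature=feature, sex=sex, category=category,
            strain_slope=m_own, reference_slope=m_ref,
        ))
    return out
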