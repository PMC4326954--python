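"""Longitudinal trend detection.

Each feature is standardized per sex (mean 0, sample SD 1 over all ages
jointly) and regressed on age in months by ordinary least squares.  The
slope's two-sided t-test decides the trend call at level ``alpha``.  Because
the response is standardized in-sample, the slope converts to the Pearson
correlation between feature and age as ``r = slope * SD(age)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_model import Sex, as_frame
from .errors import (
    DegenerateFeatureError,
    InsufficientDataError,
    RankDeficiencyError,
    ValidationError,
)

__all__ = [
    "TrendCall",
    "TrendResult",
    "TrendOrdering",
    "standardize",
    "fit_trend",
    "slope_to_correlation",
    "order_features",
]


class TrendCall(str, Enum):
    down = "down"
    none = "none"
    up = "up"


@dataclass(frozen=True)
class TrendResult:
    """Longitudinal trend of one feature for one sex."""

    feature: str
    sex: Sex
    slope_m: float          # standardized units per month
    p_value: float
    r_longitudinal: float
    n: int
    trend_call: TrendCall


@dataclass(frozen=True)
class TrendOrdering:
    """Features sorted by ascending slope with the two chart delimiters.

    ``ordered_features[:delimiter_down]`` have a significant downtrend,
    ``ordered_features[delimiter_up:]`` a significant uptrend, the rest no
    trend.
    """

    ordered_features: tuple
    delimiter_down: int
    delimiter_up: int
    sex: Sex | None = None


def standardize(values) -> np.ndarray:
    """Center and scale to sample SD 1, preserving missing entries as NaN.

    Raises :class:`DegenerateFeatureError` for fewer than two non-missing
    values or zero spread: degenerate features are excluded and logged by
    callers, never silently zeroed.
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    if int(mask.sum()) < 2:
        raise DegenerateFeatureError("fewer than 2 non-missing values")
    sd = float(np.std(arr[mask], ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateFeatureError("constant values (zero spread)")
    out = np.full(arr.shape, np.nan)
    out[mask] = (arr[mask] - float(np.mean(arr[mask]))) / sd
    return out


def slope_to_correlation(slope_m: float, ages: Sequence[float]) -> float:
    """Convert a standardized-response OLS slope to the Pearson correlation
    between feature and age.

    With the response at sample SD 1 over the fitted subset, the identity
    ``r = slope * SD(age)`` (sample SD, same subset) holds exactly.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise DegenerateFeatureError("need at least 2 ages")
    s_age = float(np.std(ages, ddof=1))
    if s_age == 0.0:
        raise DegenerateFeatureError("zero age spread")
    return float(slope_m) * s_age


def fit_trend(data, feature: str, sex, alpha: float = 0.05) -> TrendResult:
    """OLS of the standardized feature on age in months for one sex.

    Pairwise-complete: rows with a missing feature value are dropped and the
    effective ``n`` is reported.  Requires ≥3 complete records at ≥2
    distinct ages.
    """
    df = as_frame(data)
    sex = Sex(sex)
    sub = df[(df["sex"] == sex.value) & df[feature].notna()]
    ages = sub["age_months"].to_numpy(dtype=float)
    values = sub[feature].to_numpy(dtype=float)
    n = len(values)
    if n < 3:
        raise InsufficientDataError(
            f"{feature}/{sex.value}: {n} complete records, need >= 3"
        )
    if np.unique(ages).size < 2:
        raise RankDeficiencyError(
            f"{feature}/{sex.value}: all records at a single age"
        )
    z = standardize(values)
    fit = stats.linregress(ages, z)
    slope = float(fit.slope)
    p = float(fit.pvalue)
    r = slope_to_correlation(slope, ages)
    if p < alpha and slope < 0:
        call = TrendCall.down
    elif p < alpha and slope > 0:
        call = TrendCall.up
    else:
        call = TrendCall.none
    return TrendResult(feature=feature, sex=sex, slope_m=slope, p_value=p,
                       r_longitudinal=r, n=n, trend_call=call)


def order_features(trends: Iterable[TrendResult]) -> TrendOrdering:
    """Sort features by ascending slope (ties broken by name) and place the
    two delimiters separating significant down-, no- and uptrends."""
    trends = list(trends)
    names = [t.feature for t in trends]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate feature names: {', '.join(dupes)}")
    sexes = {t.sex for t in trends}
    if len(sexes) > 1:
        raise ValidationError("order_features expects trends for a single sex")
    ordered = sorted(trends, key=lambda t: (t.slope_m, t.feature))
    n_down = sum(1 for t in ordered if t.trend_call is TrendCall.down)
    n_up = sum(1 for t in ordered if t.trend_call is TrendCall.up)
    return TrendOrdering(
        ordered_features=tuple(t.feature for t in ordered),
        delimiter_down=n_down,
        delimiter_up=len(ordered) - n_up,
        sex=next(iter(sexes)) if sexes else None,
    )
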