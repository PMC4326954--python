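"""Prognostic evidence: per age-group lifespan correlation and
proportional-hazards cross-checks.

For each feature × sex × age group the Pearson correlation between feature
value and strain life expectancy is computed over individual records (each
carries its strain's life expectancy).  A cell is *relevant* when
``|r| >= r_min`` and ``p < alpha`` (defaults 0.2 / 0.05).  A positive
correlation means high feature values are prognostic for a long lifespan.

Cox regressions use life expectancy as the survival time and the
standardized feature as covariate.  Ties are heavy by construction (all
animals of a strain share one lifespan), so Efron tie handling is the
default; Breslow is available by flag.  For display next to correlation
charts the coefficient's sign is inverted (``display_sign = -coefficient``)
so that "good for lifespan" points the same way in both panels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import Sex, as_frame
from .errors import (
    CollinearityError,
    DegenerateFeatureError,
    FitError,
    InsufficientDataError,
    SchemaError,
)
from .trends import standardize

__all__ = [
    "Direction",
    "PrognosticCell",
    "PrognosticProfile",
    "CoxResult",
    "correlate_lifespan",
    "build_profile",
    "summarize_direction",
    "cox_univariate",
    "cox_multivariate",
]

#: Cap applied to the coefficient when the partial likelihood is monotone.
SEPARATION_CAP = 20.0


class Direction(str, Enum):
    """Pooled sign pattern of the relevant prognostic cells."""

    long = "long"       # all relevant correlations positive
    short = "short"     # all relevant correlations negative
    switch = "switch"   # relevant correlations of both signs
    none = "none"       # no relevant cell


@dataclass(frozen=True)
class PrognosticCell:
    """Lifespan correlation of one feature at one sex × age group."""

    feature: str
    sex: Sex
    age_group: float
    pearson_r: float
    p_value: float
    n: int
    relevant: bool
    degenerate: bool = False
    masked_reason: str | None = None


@dataclass(frozen=True)
class PrognosticProfile:
    """Per-age-group prognostic cells of one feature × sex, with the pooled
    direction summary over relevant cells."""

    feature: str
    sex: Sex
    cells: Mapping[float, PrognosticCell]
    direction_summary: Direction
    supporting_ages: tuple = ()

    def relevant_cells(self) -> list[PrognosticCell]:
        return [c for c in self.cells.values() if c.relevant]


@dataclass(frozen=True)
class CoxResult:
    """Univariate (or per-covariate joint) proportional-hazards fit."""

    feature: str
    sex: Sex
    age_group: float
    coefficient: float      # log hazard per standardized unit
    se: float
    p_value: float
    n: int
    separation: bool = False
    n_strains: int | None = None

    @property
    def display_sign(self) -> float:
        """Negated coefficient: positive means good for lifespan."""
        return -self.coefficient


def _complete_cases(df: pd.DataFrame, sex: Sex, age_group: float,
                    columns: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    sub = df[(df["sex"] == sex.value) & (df["age_months"] == float(age_group))]
    return sub.dropna(subset=list(columns))


def correlate_lifespan(merged, feature: str, sex, age_group: float,
                       r_min: float = 0.2, alpha: float = 0.05) -> PrognosticCell:
    """Pearson correlation between feature value and life expectancy at one
    sex × age group.

    Degenerate inputs (constant feature or lifespan, or fewer than three
    complete pairs) yield a flagged non-relevant cell rather than an error,
    so sparse late age groups do not abort a pipeline run.
    """
    df = as_frame(merged)
    sex = Sex(sex)
    sub = _complete_cases(df, sex, age_group, [feature, "life_expectancy"])
    x = sub[feature].to_numpy(dtype=float)
    y = sub["life_expectancy"].to_numpy(dtype=float)
    n = len(x)
    common = dict(feature=feature, sex=sex, age_group=float(age_group), n=n)
    if n < 3:
        return PrognosticCell(pearson_r=math.nan, p_value=math.nan,
                              relevant=False, degenerate=True,
                              masked_reason="fewer than 3 complete pairs",
                              **common)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PrognosticCell(pearson_r=math.nan, p_value=math.nan,
                              relevant=False, degenerate=True,
                              masked_reason="constant feature or lifespan",
                              **common)
    r, p = stats.pearsonr(x, y)
    relevant = bool(abs(r) >= r_min and p < alpha)
    return PrognosticCell(pearson_r=float(r), p_value=float(p),
                          relevant=relevant, **common)


def summarize_direction(cells: Iterable[PrognosticCell]) -> tuple[Direction, tuple]:
    """Pool relevant cells into a direction summary plus supporting ages."""
    rel = [c for c in cells if c.relevant]
    if not rel:
        return Direction.none, ()
    ages = tuple(sorted({c.age_group for c in rel}))
    signs = {1 if c.pearson_r > 0 else -1 for c in rel}
    if signs == {1}:
        return Direction.long, ages
    if signs == {-1}:
        return Direction.short, ages
    return Direction.switch, ages


def build_profile(merged, feature: str, sex, age_groups: Sequence[float],
                  r_min: float = 0.2, alpha: float = 0.05) -> PrognosticProfile:
    """Assemble the per-age-group prognostic profile of one feature × sex."""
    sex = Sex(sex)
    cells = {
        float(a): correlate_lifespan(merged, feature, sex, a, r_min=r_min, alpha=alpha)
        for a in age_groups
    }
    direction, ages = summarize_direction(cells.values())
    return PrognosticProfile(feature=feature, sex=sex, cells=cells,
                             direction_summary=direction, supporting_ages=ages)


def rebuild_direction(profile: PrognosticProfile) -> PrognosticProfile:
    direction, ages = summarize_direction(profile.cells.values())
    return replace(profile, direction_summary=direction, supporting_ages=ages)


# ---------------------------------------------------------------------------
# Proportional hazards
# ---------------------------------------------------------------------------


def _breslow_neg_loglik(beta: np.ndarray, X: np.ndarray, T: np.ndarray,
                        E: np.ndarray) -> float:
    """Negative Breslow partial log-likelihood (tied times share the full
    risk set); O(n^2), adequate for per-cell sample sizes."""
    eta = X @ beta
    ll = 0.0
    for i in range(len(T)):
        if not E[i]:
            continue
        risk = T >= T[i]
        m = np.max(eta[risk])
        ll += eta[i] - (m + math.log(np.sum(np.exp(eta[risk] - m))))
    return -ll


def _fit_breslow(X: np.ndarray, T: np.ndarray, E: np.ndarray):
    p = X.shape[1]
    res = optimize.minimize(_breslow_neg_loglik, x0=np.zeros(p),
                            args=(X, T, E), method="BFGS")
    beta = res.x
    # observed information via central differences on the score
    h = 1e-5
    hess = np.zeros((p, p))
    for j in range(p):
        for k in range(p):
            bpp = beta.copy(); bpp[j] += h; bpp[k] += h
            bpm = beta.copy(); bpm[j] += h; bpm[k] -= h
            bmp = beta.copy(); bmp[j] -= h; bmp[k] += h
            bmm = beta.copy(); bmm[j] -= h; bmm[k] -= h
            hess[j, k] = (
                _breslow_neg_loglik(bpp, X, T, E)
                - _breslow_neg_loglik(bpm, X, T, E)
                - _breslow_neg_loglik(bmp, X, T, E)
                + _breslow_neg_loglik(bmm, X, T, E)
            ) / (4 * h * h)
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return beta, se


def _is_monotone_separated(x: np.ndarray, t: np.ndarray) -> int:
    """Return the concordance sign if the covariate perfectly ranks the
    survival times (monotone partial likelihood), else 0."""
    rho = stats.spearmanr(x, t).statistic
    if np.isfinite(rho) and abs(rho) >= 1.0 - 1e-12:
        return int(np.sign(rho))
    return 0


def _lifelines_fit(df: pd.DataFrame, covariates: Sequence[str]):
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df[list(covariates) + ["life_expectancy", "event_observed"]],
                    duration_col="life_expectancy", event_col="event_observed")
        except ConvergenceError as exc:
            raise FitError(f"proportional-hazards fit did not converge: {exc}") from exc
    return cph


def cox_univariate(merged, feature: str, sex, age_group: float,
                   ties: str = "efron") -> CoxResult:
    """Univariate proportional-hazards fit of life expectancy on the
    standardized feature at one sex × age group.

    Complete separation (feature perfectly ranks lifespan, tie-free) is
    flagged and reported with the concordant sign at a capped coefficient.
    """
    if ties not in {"efron", "breslow"}:
        raise FitError(f"unknown tie correction {ties!r}")
    df = as_frame(merged)
    sex = Sex(sex)
    sub = _complete_cases(df, sex, age_group, [feature, "life_expectancy"])
    n = len(sub)
    if n < 3:
        raise InsufficientDataError(
            f"{feature}/{sex.value}/{age_group}: {n} complete records, need >= 3"
        )
    if int(sub["event_observed"].sum()) < 2:
        raise InsufficientDataError(
            f"{feature}/{sex.value}/{age_group}: fewer than 2 observed events"
        )
    z = standardize(sub[feature].to_numpy(dtype=float))
    T = sub["life_expectancy"].to_numpy(dtype=float)
    E = sub["event_observed"].to_numpy(dtype=bool)
    common = dict(feature=feature, sex=sex, age_group=float(age_group), n=n,
                  n_strains=int(sub["strain"].nunique()))

    sep = _is_monotone_separated(z, T) if len(np.unique(T)) == len(T) else 0
    if sep:
        # monotone likelihood: |coefficient| -> inf; report capped with sign
        return CoxResult(coefficient=-sep * SEPARATION_CAP, se=math.inf,
                         p_value=math.nan, separation=True, **common)

    if ties == "breslow":
        beta, se = _fit_breslow(z.reshape(-1, 1), T, E)
        coef, s = float(beta[0]), float(se[0])
        p = 2 * stats.norm.sf(abs(coef / s)) if s > 0 else math.nan
        return CoxResult(coefficient=coef, se=s, p_value=float(p), **common)

    fit_df = pd.DataFrame({"x": z, "life_expectancy": T, "event_observed": E})
    cph = _lifelines_fit(fit_df, ["x"])
    return CoxResult(
        coefficient=float(cph.params_["x"]),
        se=float(cph.standard_errors_["x"]),
        p_value=float(cph.summary.loc["x", "p"]),
        **common,
    )


def _check_collinearity(X: np.ndarray, names: Sequence[str]) -> None:
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[-1] < 1e-8 * s[0]:
        null = np.abs(vt[-1])
        involved = [names[i] for i in np.flatnonzero(null > 1e-3)]
        raise CollinearityError(involved or names)


def cox_multivariate(merged, features: Sequence[str], sex, age_group: float,
                     ties: str = "efron") -> list[CoxResult]:
    """Joint proportional-hazards fit over complete cases (listwise deletion).

    Requires at least ``len(features) + 2`` complete rows; collinear
    covariates raise :class:`CollinearityError` naming the dependent set.
    Each returned result carries the effective row and strain counts.
    """
    features = list(features)
    if len(set(features)) != len(features):
        dupes = sorted({f for f in features if features.count(f) > 1})
        raise CollinearityError(dupes, f"duplicated covariate(s): {', '.join(dupes)}")
    df = as_frame(merged)
    sex = Sex(sex)
    sub = _complete_cases(df, sex, age_group, features + ["life_expectancy"])
    n = len(sub)
    if n < len(features) + 2:
        raise InsufficientDataError(
            f"{n} complete cases for {len(features)} covariates, "
            f"need >= {len(features) + 2}"
        )
    cols = {}
    for f in features:
        try:
            cols[f] = standardize(sub[f].to_numpy(dtype=float))
        except DegenerateFeatureError as exc:
            raise DegenerateFeatureError(f"{f}: {exc}") from exc
    X = np.column_stack([cols[f] for f in features])
    _check_collinearity(X, features)

    n_strains = int(sub["strain"].nunique())
    T = sub["life_expectancy"].to_numpy(dtype=float)
    E = sub["event_observed"].to_numpy(dtype=bool)

    if ties == "breslow":
        beta, se = _fit_breslow(X, T, E)
        out = []
        for i, f in enumerate(features):
            p = 2 * stats.norm.sf(abs(beta[i] / se[i])) if se[i] > 0 else math.nan
            out.append(CoxResult(feature=f, sex=sex, age_group=float(age_group),
                                 coefficient=float(beta[i]), se=float(se[i]),
                                 p_value=float(p), n=n, n_strains=n_strains))
        return out

    fit_df = pd.DataFrame(cols)
    fit_df["life_expectancy"] = T
    fit_df["event_observed"] = E
    cph = _lifelines_fit(fit_df, features)
    return [
        CoxResult(
            feature=f, sex=sex, age_group=float(age_group),
            coefficient=float(cph.params_[f]),
            se=float(cph.standard_errors_[f]),
            p_value=float(cph.summary.loc[f, "p"]),
            n=n, n_strains=n_strains,
        )
        for f in features
    ]
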