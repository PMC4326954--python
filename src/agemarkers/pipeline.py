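"""End-to-end pipeline orchestration.

Executes read/synthesize → merge → derive → trends → prognostics → cox →
classification → stratified re-run → trend comparison, writing CSV/JSON
outputs plus a deterministic run manifest (seed, thresholds, version, row
counts per stage).  Any stage failure aborts the run, removes partial
outputs and raises :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .charts import PanelKind, build_chart_spec, render_chart
from .classify import (
    BiomarkerClassification,
    ClassifierSettings,
    EvidenceBundle,
    classify_features,
)
from .data_model import (
    EffectAnnotation,
    Sex,
    derive_absolute_counts,
    feature_names,
    merge_lifespan,
    read_effect_annotations,
    read_lifespan_table,
    read_phenotype_table,
    records_to_frame,
    write_effect_annotations,
    write_lifespan_table,
    write_phenotype_table,
)
from .errors import AgemarkersError, ConfigurationError, PipelineError
from .prognostic import build_profile, cox_univariate
from .stratify import compare_trends, exclude_strains
from .synthetic import Cohort, cohort_config_from_dict, generate_cohort
from .trends import TrendResult, fit_trend, order_features

log = logging.getLogger("agemarkers")

__all__ = ["PipelineConfig", "PipelineResult", "load_pipeline_config", "run_pipeline"]

OUTPUT_FILES = (
    "trends.csv",
    "prognostic.csv",
    "cox.csv",
    "classification.csv",
    "classification_longlived.csv",
    "comparison.csv",
    "chartspec.json",
    "manifest.json",
    "truth.csv",
    "phenotypes.csv",
    "lifespans.csv",
    "annotations.csv",
)


@dataclass
class Thresholds:
    alpha: float = 0.05
    r_min: float = 0.2
    qualifier_margin: float = 0.15
    volatile_ages: tuple = (18.0, 20.0, 24.0)
    allow_concordant_volatile_pair: bool = True

    def classifier_settings(self) -> ClassifierSettings:
        return ClassifierSettings(
            volatile_ages=frozenset(float(a) for a in self.volatile_ages),
            allow_concordant_volatile_pair=self.allow_concordant_volatile_pair,
            qualifier_margin=self.qualifier_margin,
        )


@dataclass
class PipelineConfig:
    synthesize: Mapping | None = None
    inputs: Mapping | None = None          # phenotypes/lifespans/annotations paths
    derive_counts: Mapping | None = None   # {total_feature, pct_features}
    thresholds: Thresholds = field(default_factory=Thresholds)
    exclude_strains: tuple = ()
    short_lived_strains: tuple | None = None
    features: tuple | None = None          # subset to analyse; default: all
    run_cox: bool = True
    seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if (self.synthesize is None) == (self.inputs is None):
            raise ConfigurationError(
                "config must name exactly one of 'synthesize' or 'inputs'"
            )


def load_pipeline_config(source) -> PipelineConfig:
    """Build a pipeline config from a YAML path or a plain mapping."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    th = data.get("thresholds") or {}
    return PipelineConfig(
        synthesize=data.get("synthesize"),
        inputs=data.get("inputs"),
        derive_counts=data.get("derive_counts"),
        thresholds=Thresholds(
            alpha=float(th.get("alpha", 0.05)),
            r_min=float(th.get("r_min", 0.2)),
            qualifier_margin=float(th.get("qualifier_margin", 0.15)),
            volatile_ages=tuple(float(a) for a in th.get("volatile_ages", (18, 20, 24))),
            allow_concordant_volatile_pair=bool(
                th.get("allow_concordant_volatile_pair", True)),
        ),
        exclude_strains=tuple(data.get("exclude_strains") or ()),
        short_lived_strains=(tuple(data["short_lived_strains"])
                             if data.get("short_lived_strains") is not None else None),
        features=tuple(data["features"]) if data.get("features") else None,
        run_cox=bool(data.get("cox", True)),
        seed=data.get("seed"),
        out_dir=data.get("out_dir"),
    )


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    classifications: dict
    classifications_longlived: dict
    trends: dict
    profiles: dict
    cox: list
    comparisons: list
    chart_specs: list
    cohort: Cohort | None = None


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def _analysis_inputs(config: PipelineConfig, seed: int | None):
    if config.synthesize is not None:
        synth = dict(config.synthesize)
        if seed is not None:
            synth["seed"] = seed
        cohort = generate_cohort(cohort_config_from_dict(synth))
        return (cohort.records, cohort.lifespans, cohort.annotations, cohort)
    paths = config.inputs
    records = read_phenotype_table(paths["phenotypes"])
    lifespans = read_lifespan_table(paths["lifespans"], unit=paths.get("unit", "months"))
    annotations = (read_effect_annotations(paths["annotations"])
                   if paths.get("annotations") else [])
    return records, lifespans, annotations, None


def _analyse(df: pd.DataFrame, features: Sequence[str], age_groups: Sequence[float],
             annotations: Sequence[EffectAnnotation], thresholds: Thresholds,
             run_cox: bool):
    """Trends, profiles, optional Cox and final classification on one
    (already merged) analysis frame."""
    ann_map = {a.feature_name: a for a in annotations}
    settings = thresholds.classifier_settings()
    trends: dict[tuple[str, Sex], TrendResult] = {}
    profiles = {}
    skipped = []
    for feature in features:
        for sex in (Sex.female, Sex.male):
            try:
                trends[(feature, sex)] = fit_trend(df, feature, sex,
                                                   alpha=thresholds.alpha)
            except AgemarkersError as exc:
                skipped.append((feature, sex.value, str(exc)))
                continue
            profiles[(feature, sex)] = build_profile(
                df, feature, sex, age_groups,
                r_min=thresholds.r_min, alpha=thresholds.alpha,
            )
    for feature, sex, reason in skipped:
        log.info("skipping %s/%s: %s", feature, sex, reason)

    cox_results = []
    if run_cox:
        for (feature, sex) in profiles:
            for age in age_groups:
                try:
                    cox_results.append(cox_univariate(df, feature, sex, age))
                except AgemarkersError as exc:
                    log.info("cox skipped for %s/%s/%s: %s", feature, sex.value,
                             age, exc)

    bundles = []
    for feature in features:
        trend = {s: t for (f, s), t in trends.items() if f == feature}
        prog = {s: p for (f, s), p in profiles.items() if f == feature}
        if not trend and not prog:
            continue
        bundles.append(EvidenceBundle(feature=feature, trend=trend,
                                      prognosis=prog,
                                      annotation=ann_map.get(feature)))
    classifications = classify_features(bundles, settings)
    return trends, profiles, cox_results, classifications, skipped


def _trends_frame(trends) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": t.feature, "sex": t.sex.value, "slope": t.slope_m,
                "p_value": t.p_value, "r_longitudinal": t.r_longitudinal,
                "n": t.n, "trend_call": t.trend_call.value,
            }
            for t in trends.values()
        ]
    )


def _prognostic_frame(profiles) -> pd.DataFrame:
    rows = []
    for prof in profiles.values():
        for cell in prof.cells.values():
            rows.append({
                "feature": cell.feature, "sex": cell.sex.value,
                "age_group": cell.age_group, "pearson_r": cell.pearson_r,
                "p_value": cell.p_value, "n": cell.n,
                "relevant": cell.relevant, "degenerate": cell.degenerate,
            })
    return pd.DataFrame(rows)


def _cox_frame(cox_results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": c.feature, "sex": c.sex.value, "age_group": c.age_group,
                "coefficient": c.coefficient, "se": c.se, "p_value": c.p_value,
                "display_sign": c.display_sign, "n": c.n,
                "n_strains": c.n_strains, "separation": c.separation,
            }
            for c in cox_results
        ]
    )


def _classification_frame(classifications: Mapping[str, BiomarkerClassification]
                          ) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": c.feature,
                "overall": c.overall.value,
                "class_early": c.class_early.value,
                "class_late": c.class_late.value,
                "basis": c.basis.value if c.basis else "",
                "provisional": c.provisional,
                "qualifiers": "; ".join(c.qualifiers),
            }
            for c in classifications.values()
        ]
    )


def _comparison_frame(comparisons) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": c.strain, "feature": c.feature, "sex": c.sex.value,
                "category": c.category.value, "strain_slope": c.strain_slope,
                "reference_slope": c.reference_slope, "reason": c.reason or "",
            }
            for c in comparisons
        ]
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(config, out_dir=None, seed: int | None = None,
                 plots: bool = False) -> PipelineResult:
    """Run the full pipeline and write all outputs under ``out_dir``."""
    config = load_pipeline_config(config)
    out_dir = Path(out_dir or config.out_dir or ".")
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else config.seed
    written: list[Path] = []
    stage = "setup"
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages": {},
        "outputs": [],
    }

    def _write_csv(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)
        manifest["outputs"].append(name)

    try:
        stage = "input"
        records, lifespans, annotations, cohort = _analysis_inputs(config, seed)
        manifest["stages"]["input"] = {
            "rows": len(records), "lifespans": len(lifespans),
            "annotations": len(annotations),
        }
        write_phenotype_table(records, out_dir / "phenotypes.csv")
        written.append(out_dir / "phenotypes.csv")
        manifest["outputs"].append("phenotypes.csv")
        write_lifespan_table(lifespans, out_dir / "lifespans.csv")
        written.append(out_dir / "lifespans.csv")
        manifest["outputs"].append("lifespans.csv")
        write_effect_annotations(annotations, out_dir / "annotations.csv")
        written.append(out_dir / "annotations.csv")
        manifest["outputs"].append("annotations.csv")
        if cohort is not None:
            _write_csv(cohort.truth_frame(), "truth.csv")

        stage = "exclude"
        if config.exclude_strains:
            excl = exclude_strains(records, lifespans, config.exclude_strains)
            records, lifespans = excl.records, excl.lifespans
            manifest["stages"]["exclude"] = {
                "rows": len(records),
                "records_removed": excl.n_records_removed,
                "warnings": list(excl.warnings),
            }

        stage = "merge"
        merged = merge_lifespan(records, lifespans)
        manifest["stages"]["merge"] = {"rows": len(merged),
                                       "dropped": merged.n_dropped}

        stage = "derive"
        analysis_records = merged.records
        if config.derive_counts:
            analysis_records = derive_absolute_counts(
                analysis_records,
                total_feature=config.derive_counts["total_feature"],
                pct_features=list(config.derive_counts["pct_features"]),
            )
            manifest["stages"]["derive"] = {"rows": len(analysis_records)}

        df = records_to_frame(analysis_records)
        features = list(config.features or feature_names(analysis_records))
        age_groups = sorted(df["age_months"].unique().tolist())

        stage = "analysis"
        trends, profiles, cox_results, classifications, skipped = _analyse(
            df, features, age_groups, annotations, config.thresholds,
            config.run_cox,
        )
        manifest["stages"]["trends"] = {"rows": len(trends),
                                        "skipped": len(skipped)}
        manifest["stages"]["prognostic"] = {
            "rows": sum(len(p.cells) for p in profiles.values())
        }
        manifest["stages"]["cox"] = {"rows": len(cox_results)}
        manifest["stages"]["classification"] = {"rows": len(classifications)}
        _write_csv(_trends_frame(trends), "trends.csv")
        _write_csv(_prognostic_frame(profiles), "prognostic.csv")
        _write_csv(_cox_frame(cox_results), "cox.csv")
        _write_csv(_classification_frame(classifications), "classification.csv")

        stage = "stratified"
        short = (list(config.short_lived_strains)
                 if config.short_lived_strains is not None
                 else list(cohort.short_lived_strains) if cohort is not None
                 else [])
        short = [s for s in short if s not in set(config.exclude_strains)]
        classifications_ll: dict = {}
        if short:
            excl = exclude_strains(records, lifespans, short)
            merged_ll = merge_lifespan(excl.records, excl.lifespans)
            rec_ll = merged_ll.records
            if config.derive_counts:
                rec_ll = derive_absolute_counts(
                    rec_ll,
                    total_feature=config.derive_counts["total_feature"],
                    pct_features=list(config.derive_counts["pct_features"]),
                )
            df_ll = records_to_frame(rec_ll)
            ages_ll = sorted(df_ll["age_months"].unique().tolist())
            _, _, _, classifications_ll, _ = _analyse(
                df_ll, features, ages_ll, annotations, config.thresholds,
                run_cox=False,
            )
        manifest["stages"]["stratified"] = {"rows": len(classifications_ll),
                                            "excluded_strains": short}
        _write_csv(_classification_frame(classifications_ll),
                   "classification_longlived.csv")

        stage = "comparison"
        comparisons = []
        if short:
            for feature in features:
                for sex in (Sex.female, Sex.male):
                    try:
                        comparisons.extend(
                            compare_trends(df, feature, sex, short)
                        )
                    except AgemarkersError as exc:
                        log.info("comparison skipped for %s/%s: %s",
                                 feature, sex.value, exc)
        manifest["stages"]["comparison"] = {"rows": len(comparisons)}
        _write_csv(_comparison_frame(comparisons), "comparison.csv")

        stage = "charts"
        chart_specs = []
        for sex in (Sex.female, Sex.male):
            sex_trends = {f: t for (f, s), t in trends.items() if s == sex}
            if not sex_trends:
                continue
            ordering = order_features(sex_trends.values())
            for age in age_groups:
                cells = {}
                ok = True
                for f in sex_trends:
                    prof = profiles.get((f, sex))
                    cell = prof.cells.get(float(age)) if prof else None
                    if cell is None:
                        ok = False
                        break
                    r = 0.0 if math.isnan(cell.pearson_r) else cell.pearson_r
                    cells[f] = (r, cell.relevant)
                if ok:
                    chart_specs.append(build_chart_spec(
                        ordering, cells, PanelKind.lifespan_correlation,
                        dataset_label=f"{age:g} M",
                    ))
            cox_by_age: dict[float, dict] = {}
            for c in cox_results:
                if c.sex == sex:
                    cox_by_age.setdefault(c.age_group, {})[c.feature] = c
            for age, by_feature in sorted(cox_by_age.items()):
                if set(by_feature) == set(sex_trends):
                    cells = {
                        f: (c.coefficient,
                            (not math.isnan(c.p_value)) and c.p_value < config.thresholds.alpha)
                        for f, c in by_feature.items()
                    }
                    chart_specs.append(build_chart_spec(
                        ordering, cells, PanelKind.cox_display,
                        dataset_label=f"{age:g} M",
                    ))
        manifest["stages"]["charts"] = {"rows": len(chart_specs)}
        chart_path = out_dir / "chartspec.json"
        with open(chart_path, "w") as fh:
            json.dump([c.to_dict() for c in chart_specs], fh, indent=2,
                      sort_keys=True)
        written.append(chart_path)
        manifest["outputs"].append("chartspec.json")
        if plots:
            for i, spec in enumerate(chart_specs):
                render_chart(spec, out_dir / f"chart_{i:03d}.png")

        stage = "manifest"
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(manifest_path)

    except AgemarkersError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc

    return PipelineResult(
        out_dir=out_dir, manifest=manifest,
        classifications=classifications,
        classifications_longlived=classifications_ll,
        trends=trends, profiles=profiles, cox=cox_results,
        comparisons=comparisons, chart_specs=chart_specs, cohort=cohort,
    )
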