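"""End-to-end pipeline: simulate/read -> aggregate -> trends -> classify -> infer.

``run_pipeline`` chains every stage, writes all intermediate tables to the
output directory, and returns a :class:`RunReport` whose summary block mirrors
the shape of the study-style reporting: total locations, significant predator
trends (up/down), alternating count and percentage, excess-over-chance ratio,
and the model terms retained by stepwise selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from reefcascade import aggregate, cascade, inference, io, trends
from reefcascade.errors import (
    ConfigError,
    DegenerateResponseError,
    ReefCascadeError,
)
from reefcascade.simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("reefcascade")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NONCONVERGENCE = 3


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    surveys: Optional[Path] = None
    locations: Optional[Path] = None
    sim_config: Optional[SimulationConfig] = None
    alpha: float = 0.05
    method: str = "both"  # ols | ar1 | both
    seed: int = 0
    force: bool = False
    strict_validation: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.method not in ("ols", "ar1", "both"):
            raise ConfigError(f"unknown method {self.method!r}")
        have_files = self.surveys is not None and self.locations is not None
        if not have_files and self.sim_config is None:
            self.sim_config = SimulationConfig(seed=self.seed)


@dataclass
class RunReport:
    """Outputs and summary of one pipeline run."""

    outputs: dict[str, Path] = field(default_factory=dict)
    summary: dict[str, object] = field(default_factory=dict)
    excluded: list[dict] = field(default_factory=list)
    exit_code: int = EXIT_OK

    def summary_text(self) -> str:
        lines = [f"{k}={v}" for k, v in self.summary.items()]
        return "\n".join(lines) + "\n"


def _write(df: pd.DataFrame, path: Path, report: RunReport, key: str) -> None:
    df.to_csv(path, index=False)
    report.outputs[key] = path


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Stage errors propagate as :class:`ReefCascadeError` with the stage name.
    Locations excluded at any stage (failed validation, constant series) are
    recorded with a reason code in the report and the log.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    # --- stage: inputs -----------------------------------------------------
    if config.surveys is not None:
        records = io.read_survey_table(config.surveys)
        meta = io.read_location_table(config.locations)
        truth = None
    else:
        records, meta, truth = simulate_dataset(config.sim_config)
        _write(records, out / "surveys.csv", report, "surveys")
        io.write_location_table(meta, out / "locations.csv")
        report.outputs["locations"] = out / "locations.csv"
        _write(truth, out / "truth.csv", report, "truth")
    meta = io.resolve_start_years(meta)

    # --- stage: validation -------------------------------------------------
    vreport = io.validate_dataset(records, meta)
    _write(io.report_frame(vreport), out / "validation.csv", report, "validation")
    failed_locs = sorted({c.location_id for c in vreport.failures()})
    for c in vreport.failures():
        reason = (
            "too_short" if c.too_short else
            "too_few_surveys" if c.too_few_surveys else "constant"
        )
        report.excluded.append(
            {"location_id": c.location_id, "trophic_group": c.trophic_group,
             "stage": "validation", "reason": reason}
        )
        logger.warning(
            "excluding %s/%s: %s", c.location_id, c.trophic_group, reason
        )
    if failed_locs and config.strict_validation:
        report.exit_code = EXIT_VALIDATION
        return report
    records = records[~records["location_id"].isin(failed_locs)]
    if records.empty:
        raise ReefCascadeError("validation: no locations left to analyse")

    # --- stage: aggregation ------------------------------------------------
    series, replicates, constant = aggregate.build_location_series(records, meta)
    for loc, group in constant:
        report.excluded.append(
            {"location_id": loc, "trophic_group": group,
             "stage": "aggregation", "reason": "constant_series"}
        )
        logger.warning("constant series at %s/%s; trend set non-significant", loc, group)
    _write(aggregate.series_frame(series), out / "series.csv", report, "series")

    # --- stage: trends -----------------------------------------------------
    trend_results = trends.fit_all_trends(
        replicates, alpha=config.alpha, method=config.method
    )
    trends_df = trends.trends_frame(trend_results)
    _write(trends_df, out / "trends.csv", report, "trends")
    correlations = trends.all_pair_correlations(series)
    corr_df = trends.correlations_frame(correlations)
    _write(corr_df, out / "correlations.csv", report, "correlations")

    # --- stage: classification ----------------------------------------------
    primary = [t for t in trend_results if t.method == "ols"]
    complete_locs = {
        loc
        for loc in {t.location_id for t in primary}
        if sum(t.location_id == loc for t in primary) == 3
    }
    for loc in sorted({t.location_id for t in primary} - complete_locs):
        report.excluded.append(
            {"location_id": loc, "trophic_group": "", "stage": "classification",
             "reason": "incomplete_groups"}
        )
    classifications = cascade.classify_all(
        [t for t in primary if t.location_id in complete_locs]
    )
    _write(
        cascade.classifications_frame(classifications),
        out / "cascade.csv", report, "cascade",
    )
    prevalence_parts = [cascade.summarize_prevalence(classifications, grouping="all")]
    meta_regions = meta.copy()
    if "region" not in meta_regions.columns:
        region_map = records[["location_id", "region"]].drop_duplicates()
        meta_regions = meta_regions.merge(region_map, on="location_id", how="left")
    for grouping in ("region", "exploitation_status"):
        prevalence_parts.append(
            cascade.summarize_prevalence(classifications, meta_regions, grouping)
        )
    prevalence = pd.concat(prevalence_parts, ignore_index=True)
    _write(prevalence, out / "prevalence.csv", report, "prevalence")

    # --- stage: inference --------------------------------------------------
    nonconverged = False
    model_report_lines = []
    for pair in ("predator_herbivore", "herbivore_algae"):
        sub = corr_df[(corr_df["pair"] == pair) & corr_df["z"].notna()].merge(
            meta[["location_id", "latitude"]], on="location_id"
        )
        if len(sub) < 3:
            continue
        fit = inference.weighted_regression(sub, "z ~ latitude", weights="weight")
        frame = sub[["location_id", "latitude", "z", "weight"]].join(fit.fitted)
        _write(frame, out / f"wls_{pair}_latitude.csv", report, f"wls_{pair}")
        report.summary[f"wls_{pair}_latitude_coef"] = round(float(fit.params["latitude"]), 6)
        report.summary[f"wls_{pair}_latitude_p"] = round(float(fit.pvalues["latitude"]), 6)
        report.summary[f"wls_{pair}_r2"] = round(fit.r_squared, 6)
        model_report_lines.append(
            f"WLS {pair}: z ~ latitude  coef={fit.params['latitude']:.4f} "
            f"(se {fit.bse['latitude']:.4f}), R2={fit.r_squared:.4f}, "
            f"F({fit.f_df[0]:.0f},{fit.f_df[1]:.0f})={fit.f_stat:.3f}, p={fit.f_pvalue:.4f}, "
            f"n={fit.n_used} (excluded {fit.n_excluded} zero-weight)"
        )

    class_df = cascade.classifications_frame(classifications).merge(
        meta[["location_id", "latitude", "exploitation_status"]], on="location_id"
    )
    glm_data = class_df[class_df["predator_significant"]].copy()
    glm_data["alternating"] = glm_data["alternating"].astype(int)
    retained = "not_fit"
    if len(glm_data) >= 4 and glm_data["alternating"].nunique() == 2:
        terms = ["latitude"]
        if glm_data["exploitation_status"].nunique() > 1:
            terms.append(inference.EXPLOITATION_TERM)
        formula = "alternating ~ " + " + ".join(terms)
        try:
            full = inference.logistic_cascade_model(glm_data, formula=formula)
            final, trace = inference.backward_stepwise(full, glm_data, alpha=config.alpha)
            nonconverged = nonconverged or not final.converged
            glm_out = pd.DataFrame(
                {"coef": final.params, "se": final.bse, "p": final.pvalues}
            ).reset_index(names="term")
            _write(glm_out, out / "glm_cascade.csv", report, "glm_cascade")
            _write(trace.frame(), out / "stepwise_trace.csv", report, "stepwise_trace")
            retained = " + ".join(final.terms) or "intercept_only"
            model_report_lines.append(
                f"GLM alternating|predator-significant: retained terms: {retained}; "
                f"AIC={final.aic:.2f}; separation={final.separation_flag}"
            )
        except DegenerateResponseError as exc:
            model_report_lines.append(f"GLM skipped: {exc}")
    else:
        model_report_lines.append(
            "GLM skipped: needs >= 4 predator-significant locations with both outcomes"
        )

    covariate_models = inference.trend_vs_covariate_models(
        trends_df, meta, alpha=config.alpha
    )
    _write(
        covariate_models["category_means"],
        out / "trend_category_means.csv", report, "trend_category_means",
    )
    for group, models in covariate_models["models"].items():
        for name, (fit, trace) in models.items():
            model_report_lines.append(
                f"trend[{group}] ~ {name}: retained: "
                f"{' + '.join(fit.terms) or 'intercept only'} (AIC {fit.aic:.2f})"
            )

    # --- summary ------------------------------------------------------------
    ols_trends = trends_df[trends_df["method"] == "ols"]
    pred = ols_trends[ols_trends["trophic_group"] == "predators"]
    n_locations = pred["location_id"].nunique()
    n_up = int((pred["direction"] == "increasing").sum())
    n_down = int((pred["direction"] == "decreasing").sum())
    n_sig = n_up + n_down
    overall = prevalence[prevalence["group"] == "all"].iloc[0]
    ratio = cascade.excess_over_chance(n_sig, len(pred), config.alpha)
    report.summary.update(
        {
            "n_locations": int(n_locations),
            "n_predator_significant": n_sig,
            "n_predator_increasing": n_up,
            "n_predator_decreasing": n_down,
            "n_alternating": int(overall["n_alternating"]),
            "pct_alternating": (
                round(float(overall["pct_alternating"]), 4)
                if np.isfinite(overall["pct_alternating"]) else "undefined"
            ),
            "excess_over_chance": round(ratio, 4),
            "glm_retained_terms": retained,
            "n_excluded": len(report.excluded),
        }
    )
    if truth is not None:
        merged = cascade.classifications_frame(classifications).merge(
            truth[["location_id", "regime"]], on="location_id"
        )
        report.summary["n_true_cascade_regime"] = int(
            (merged["regime"] == "top_down_cascade").sum()
        )
        report.summary["n_cascade_recovered"] = int(
            merged[merged["regime"] == "top_down_cascade"]["alternating"].sum()
        )

    (out / "summary.txt").write_text(report.summary_text())
    report.outputs["summary"] = out / "summary.txt"
    human = ["Run report", "==========", ""]
    human += [f"{k}: {v}" for k, v in report.summary.items()]
    human += ["", "Models", "------"] + model_report_lines
    if report.excluded:
        human += ["", "Exclusions", "----------"]
        human += [
            f"{e['location_id']}/{e['trophic_group'] or '*'}: {e['stage']}: {e['reason']}"
            for e in report.excluded
        ]
    (out / "report.txt").write_text("\n".join(human) + "\n")
    report.outputs["report"] = out / "report.txt"
    if nonconverged:
        report.exit_code = EXIT_NONCONVERGENCE
    return report
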