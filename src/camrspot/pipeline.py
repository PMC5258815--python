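"""End-to-end pipeline: simulate/load → classify → trajectory → associate.

A pipeline run is a pure function of (input files, configuration, seed):
every stage writes deterministic CSV/JSON artifacts to the output
directory, so re-running an identical configuration reproduces identical
bytes.  Stages are requested by name; a stage whose prerequisites are
missing raises :class:`~camrspot.errors.PipelineError`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as cohort_io
from .classify import calls_to_frame, classify_cohort
from .errors import ConfigError, PipelineError
from .records import (
    AntigenClass,
    CohortTables,
    PositivityRule,
    TimePoint,
)
from .simulate import (
    SyntheticCohortConfig,
    generate_cohort,
    scenario_null,
    scenario_paper,
)
from .stats import association_report, fisher_exact_rxc
from .trajectory import (
    Outcome,
    TransitionGroup,
    compute_delta_egfr,
    dichotomize,
    label_transition,
)

logger = logging.getLogger("camrspot")

KNOWN_STAGES = (
    "simulate", "classify", "trajectory", "transitions", "associate",
    "predict", "lmm",
)

#: Stages run by default: the core descriptive pipeline.  The modelling
#: stages (predict, lmm) are opt-in because they are much heavier.
DEFAULT_STAGES = KNOWN_STAGES[:5]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    scenario: Optional[str] = "paper"  # paper | null | custom:<yaml path>
    patients_csv: Optional[str] = None
    egfr_csv: Optional[str] = None
    elispot_csv: Optional[str] = None
    seed: int = 0
    outdir: str = "camrspot_out"
    stages: tuple[str, ...] = DEFAULT_STAGES
    filters: tuple[str, ...] = ()
    window_months: float = 36.0
    t1_window: tuple[float, float] = (-1.0, 1.0)
    min_spots: int = 10
    background_multiplier: float = 2.0
    delta: float = 0.20

    def positivity_rule(self) -> PositivityRule:
        return PositivityRule(
            min_spots=self.min_spots,
            background_multiplier=self.background_multiplier,
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


def _resolve_scenario(scenario: str) -> SyntheticCohortConfig:
    if scenario == "paper":
        return scenario_paper()
    if scenario == "null":
        return scenario_null()
    if scenario.startswith("custom:"):
        with open(scenario.removeprefix("custom:"), encoding="utf-8") as fh:
            return SyntheticCohortConfig(**(yaml.safe_load(fh) or {}))
    raise ConfigError(f"unknown scenario {scenario!r}")


def _acquire_cohort(config: PipelineConfig) -> CohortTables:
    if "simulate" in config.stages:
        if config.scenario is None:
            raise ConfigError("simulate stage requires a scenario")
        cohort, _ = generate_cohort(_resolve_scenario(config.scenario), config.seed)
        return cohort
    if not (config.patients_csv and config.egfr_csv and config.elispot_csv):
        raise ConfigError("either simulate stage or three input CSVs required")
    return cohort_io.read_cohort(
        config.patients_csv, config.egfr_csv, config.elispot_csv
    )


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Run the requested stages; returns {'cohort': ..., 'paths': {...}, ...}."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    for stage in config.stages:
        if stage not in KNOWN_STAGES:
            raise ConfigError(f"unknown stage {stage!r}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    result: dict = {"config": config, "paths": paths}

    cohort = _acquire_cohort(config)
    if "simulate" in config.stages:
        cohort_paths = cohort_io.write_cohort(cohort, outdir)
        paths.update(cohort_paths)
    if config.filters:
        cohort, exclusions = cohort_io.apply_cohort_filters(
            cohort, config.filters, t1_window=config.t1_window
        )
        paths["exclusions"] = outdir / "exclusions.csv"
        exclusions.to_csv(paths["exclusions"], index=False)
        result["exclusions"] = exclusions
    result["cohort"] = cohort

    calls = None
    if "classify" in config.stages:
        calls = classify_cohort(cohort, config.positivity_rule(), config.delta)
        frame = calls_to_frame(calls)
        paths["classification"] = outdir / "classification.csv"
        frame.to_csv(paths["classification"], index=False)
        summary = (
            frame[frame["interpretable"] & (frame["antigen_class"] == "donor")]
            .groupby(["time_point", "coarse_category"])
            .size()
            .rename("n")
            .reset_index()
        )
        paths["pattern_counts"] = outdir / "pattern_counts.csv"
        summary.to_csv(paths["pattern_counts"], index=False)
        result["calls"] = calls
        result["pattern_counts"] = summary

    deltas, labels = None, None
    if "trajectory" in config.stages:
        deltas = []
        for series in cohort.egfr:
            try:
                deltas.append(
                    compute_delta_egfr(series, config.window_months, config.t1_window)
                )
            except Exception:
                logger.info("no ΔeGFR for patient %s", series.patient_id)
        subgroups = {p.patient_id: p.subgroup for p in cohort.patients}
        labels = dichotomize(deltas, subgroups)
        delta_df = pd.DataFrame(
            [
                {
                    "patient_id": d.patient_id,
                    "egfr_baseline": d.egfr_baseline,
                    "egfr_final": d.egfr_final,
                    "delta": d.delta,
                    "window_months": d.window_months,
                }
                for d in deltas
            ]
        )
        label_df = pd.DataFrame(
            [
                {
                    "patient_id": l.patient_id,
                    "label": l.label.value,
                    "subgroup_median": l.subgroup_median,
                }
                for l in labels
            ]
        )
        paths["delta_egfr"] = outdir / "delta_egfr.csv"
        paths["outcome_labels"] = outdir / "outcome_labels.csv"
        delta_df.to_csv(paths["delta_egfr"], index=False)
        label_df.to_csv(paths["outcome_labels"], index=False)
        result["deltas"], result["labels"] = deltas, labels

    if "transitions" in config.stages:
        if calls is None:
            raise PipelineError("transitions stage requires classify")
        if labels is None:
            raise PipelineError("transitions stage requires trajectory")
        time_points = {
            tp for (_, tp, _) in calls
        }
        if len(time_points) < 2:
            raise PipelineError("transitions require samples at both time points")
        transitions = []
        for p in cohort.patients:
            t1 = calls.get((p.patient_id, TimePoint.T1, AntigenClass.DONOR))
            t2 = calls.get((p.patient_id, TimePoint.T2, AntigenClass.DONOR))
            if t1 is None or t2 is None:
                continue
            transitions.append(label_transition(t1, t2))
        trans_df = pd.DataFrame(
            [
                {
                    "patient_id": t.patient_id,
                    "antigen_class": t.antigen_class.value,
                    "dsr_change": t.dsr_change.value if t.dsr_change else None,
                    "bdep_change": t.bdep_change.value if t.bdep_change else None,
                    "group": t.group.value,
                }
                for t in transitions
            ]
        )
        paths["transitions"] = outdir / "transitions.csv"
        trans_df.to_csv(paths["transitions"], index=False)
        result["transitions"] = transitions

        label_map = {l.patient_id: l.label for l in labels}
        groups = [
            TransitionGroup.REGULATED_AT_T2_FROM_NOB,
            TransitionGroup.REGULATED_AT_T2_FROM_B,
            TransitionGroup.UNREGULATED_AT_T2,
        ]
        table = []
        for g in groups:
            members = [
                t for t in transitions if t.group is g and t.patient_id in label_map
            ]
            stable = sum(
                1 for t in members if label_map[t.patient_id] is Outcome.STABLE
            )
            det = len(members) - stable
            table.append([stable, det])
        result["transition_table"] = table
        test = (
            fisher_exact_rxc(table)
            if all(sum(row) > 0 for row in table)
            else None
        )
        result["transition_test"] = test
        paths["transition_table"] = outdir / "transition_table.json"
        with open(paths["transition_table"], "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "groups": [g.value for g in groups],
                    "columns": ["stable", "deteriorating"],
                    "counts": table,
                    "fisher_p": test.p_value if test else None,
                },
                fh, indent=2, sort_keys=True,
            )

    if "associate" in config.stages:
        if calls is None or labels is None:
            raise PipelineError("associate stage requires classify and trajectory")
        reports = association_report(cohort, calls, labels)
        for outcome_name, report in reports.items():
            key = f"association_{outcome_name}"
            paths[key] = outdir / f"{key}.csv"
            report.to_csv(paths[key], index=False, float_format="%.6g")
        result["association"] = reports

    if "predict" in config.stages:
        if calls is None or labels is None:
            raise PipelineError("predict stage requires classify and trajectory")
        from .predict import ElasticNetSpec, elastic_net_select, patient_features

        features = patient_features(cohort, calls)
        label_map = {l.patient_id: l.label for l in labels}
        keep = [pid for pid in features.index if pid in label_map]
        X = features.loc[keep].dropna(axis=1, how="all").dropna()
        y = [int(label_map[pid] is Outcome.DETERIORATING) for pid in X.index]
        spec = ElasticNetSpec(
            alpha_grid=(0.5, 1.0), n_lambda=20, n_repeats=25, seed=config.seed
        )
        enet = elastic_net_select(X, y, spec)
        summary = pd.DataFrame({"coefficient": enet.coefficients})
        summary["selected"] = summary.index.isin(enet.selected)
        paths["elastic_net"] = outdir / "elastic_net_summary.csv"
        summary.to_csv(paths["elastic_net"], float_format="%.6g")
        paths["roc_points"] = outdir / "roc_points.csv"
        pd.DataFrame(
            {"fpr": enet.refit_roc.fpr, "tpr": enet.refit_roc.tpr}
        ).to_csv(paths["roc_points"], index=False, float_format="%.6g")
        result["elastic_net"] = enet

    if "lmm" in config.stages:
        if calls is None:
            raise PipelineError("lmm stage requires classify")
        from .predict import fit_lmm_egfr

        rows = []
        for series in cohort.egfr:
            call = calls.get((series.patient_id, TimePoint.T2, AntigenClass.DONOR))
            if call is None or not call.interpretable:
                continue
            for obs in series.observations:
                rows.append(
                    {
                        "patient_id": series.patient_id,
                        "time_years": obs.month / 12.0,
                        "egfr": obs.egfr,
                        "dsr_t2": int(call.dsr),
                    }
                )
        fit = fit_lmm_egfr(pd.DataFrame(rows))
        paths["lmm_summary"] = outdir / "lmm_summary.json"
        with open(paths["lmm_summary"], "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "intercept": fit.intercept,
                    "time_slope_per_year": fit.time_slope,
                    "dsr_t2_effect": fit.dsr_t2_effect,
                    "interaction_slope_per_year": fit.interaction_slope,
                    "interaction_p": fit.interaction_p,
                    "random_intercept_var": fit.random_intercept_var,
                    "residual_var": fit.residual_var,
                    "converged": fit.converged,
                    "singular": fit.singular,
                },
                fh, indent=2, sort_keys=True,
            )
        result["lmm"] = fit

    return result
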