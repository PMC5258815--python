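"""Cohort file I/O and patient-flow filters.

Three tidy UTF-8 CSVs describe a cohort:

* ``patients.csv`` — one row per patient (covariates, biopsy scores, DSA,
  treatment, outcome);
* ``egfr.csv`` — one row per eGFR/creatinine observation, months relative
  to the index biopsy;
* ``elispot.csv`` — long format, one row per patient × time point ×
  antigen class × depletion condition.

Missing values are empty cells, never sentinel numbers.  The exclusion
filters reproduce the patient-flow accounting of the study design (baseline
eGFR < 20 excluded, missing follow-up excluded, and the treated-subgroup
screens: no tubulitis, progressive creatinine rise on reciprocal plots).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ConfigError, IntegrityError, SchemaError
from .records import (
    AntigenClass,
    CohortTables,
    Condition,
    EgfrObservation,
    EgfrSeries,
    ElispotSample,
    HlaAbStatus,
    PatientRecord,
    Sex,
    Subgroup,
    TimePoint,
    Treatment,
    is_missing,
)

logger = logging.getLogger("camrspot")

PATIENT_COLUMNS = [
    "patient_id", "subgroup", "age_at_tx", "sex", "prior_rejection",
    "dialysis_months_pre_tx", "hla_ab_status", "dsa_mfi_t1", "dsa_mfi_t2",
    "pcr", "banff_g", "banff_ptc", "banff_cg", "banff_cv", "c4d_ptc",
    "c4d_glom", "ifta_pct", "tubulitis", "treatment", "graft_failed",
    "failure_month",
]
EGFR_COLUMNS = ["patient_id", "month", "egfr", "creatinine"]
ELISPOT_COLUMNS = [
    "patient_id", "time_point", "antigen_class", "condition", "spots",
    "background", "viable",
]

FILTER_RULES = (
    "egfr_lt_20_at_biopsy",
    "missing_followup",
    "tubulitis",
    "nonprogressive_creatinine",
)

_CONDITION_FIELD = {
    Condition.CD8DEP: "c_cd8dep",
    Condition.CD8CD19DEP: "c_cd8cd19dep",
    Condition.CD8CD25DEP: "c_cd8cd25dep",
    Condition.CD8CD25CD19DEP: "c_cd8cd25cd19dep",
}


def _require_columns(df: pd.DataFrame, required: Iterable[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")


def _parse_bool(value, context: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise IntegrityError(f"{context}: cannot parse boolean from {value!r}")


def _opt_float(value):
    return None if is_missing(value) else float(value)


def read_cohort(
    patients_path: str | Path,
    egfr_path: str | Path,
    elispot_path: str | Path,
    schema_version: str = "1",
) -> CohortTables:
    """Read and fully validate a cohort from its three CSV files."""
    if schema_version != "1":
        raise SchemaError(f"unknown schema_version {schema_version!r}")

    patients_df = pd.read_csv(patients_path, dtype={"patient_id": str})
    egfr_df = pd.read_csv(egfr_path, dtype={"patient_id": str})
    elispot_df = pd.read_csv(elispot_path, dtype={"patient_id": str})
    _require_columns(patients_df, PATIENT_COLUMNS, "patients.csv")
    _require_columns(egfr_df, EGFR_COLUMNS, "egfr.csv")
    _require_columns(elispot_df, ELISPOT_COLUMNS, "elispot.csv")

    patients = []
    for _, row in patients_df.iterrows():
        treatment = frozenset(
            Treatment(t) for t in str(row["treatment"]).split(";") if t
        ) if not is_missing(row["treatment"]) else frozenset()
        try:
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    subgroup=Subgroup(row["subgroup"]),
                    age_at_tx=float(row["age_at_tx"]),
                    sex=Sex(row["sex"]),
                    prior_rejection=_parse_bool(row["prior_rejection"], "patients.csv"),
                    dialysis_months_pre_tx=float(row["dialysis_months_pre_tx"]),
                    hla_ab_status=HlaAbStatus(row["hla_ab_status"]),
                    dsa_mfi_t1=_opt_float(row["dsa_mfi_t1"]),
                    dsa_mfi_t2=_opt_float(row["dsa_mfi_t2"]),
                    pcr=_opt_float(row["pcr"]),
                    banff_g=int(row["banff_g"]),
                    banff_ptc=int(row["banff_ptc"]),
                    banff_cg=int(row["banff_cg"]),
                    banff_cv=int(row["banff_cv"]),
                    c4d_ptc=_parse_bool(row["c4d_ptc"], "patients.csv"),
                    c4d_glom=_parse_bool(row["c4d_glom"], "patients.csv"),
                    ifta_pct=float(row["ifta_pct"]),
                    tubulitis=_parse_bool(row["tubulitis"], "patients.csv"),
                    treatment=treatment,
                    graft_failed=_parse_bool(row["graft_failed"], "patients.csv"),
                    failure_month=_opt_float(row["failure_month"]),
                )
            )
        except ValueError as exc:
            raise IntegrityError(
                f"patients.csv row for {row['patient_id']!r}: {exc}"
            ) from exc

    egfr_series = []
    for pid, group in egfr_df.groupby("patient_id", sort=True):
        group = group.sort_values("month", kind="stable")
        obs = tuple(
            EgfrObservation(
                month=float(r["month"]),
                egfr=float(r["egfr"]),
                creatinine=_opt_float(r["creatinine"]),
            )
            for _, r in group.iterrows()
        )
        months = [o.month for o in obs]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise IntegrityError(f"egfr.csv: non-monotone months for patient {pid}")
        try:
            egfr_series.append(EgfrSeries(patient_id=str(pid), observations=obs))
        except ValueError as exc:
            raise IntegrityError(f"egfr.csv patient {pid}: {exc}") from exc

    samples = []
    grouped = elispot_df.groupby(
        ["patient_id", "time_point", "antigen_class"], sort=True
    )
    for (pid, tp, ag), group in grouped:
        if group["condition"].duplicated().any():
            raise IntegrityError(
                f"elispot.csv: duplicate rows for ({pid}, {tp}, {ag})"
            )
        fields: dict = {
            "patient_id": str(pid),
            "time_point": TimePoint(tp),
            "antigen_class": AntigenClass(ag),
        }
        backgrounds = set()
        viable = True
        for _, r in group.iterrows():
            cond = Condition(r["condition"])
            fields[_CONDITION_FIELD[cond]] = (
                None if is_missing(r["spots"]) else int(r["spots"])
            )
            if not is_missing(r["background"]):
                backgrounds.add(int(r["background"]))
            viable = viable and _parse_bool(r["viable"], "elispot.csv")
        if len(backgrounds) > 1:
            raise IntegrityError(
                f"elispot.csv: inconsistent background for ({pid}, {tp}, {ag})"
            )
        fields["background"] = backgrounds.pop() if backgrounds else None
        fields["viable"] = viable
        try:
            samples.append(ElispotSample(**fields))
        except ValueError as exc:
            raise IntegrityError(f"elispot.csv ({pid}, {tp}, {ag}): {exc}") from exc

    try:
        cohort = CohortTables(
            patients=tuple(patients), egfr=tuple(egfr_series), elispot=tuple(samples)
        )
    except ValueError as exc:
        raise IntegrityError(str(exc)) from exc
    logger.info(
        "read cohort: %d patients, %d eGFR series, %d ELISPOT samples",
        len(patients), len(egfr_series), len(samples),
    )
    return cohort


def write_cohort(cohort: CohortTables, outdir: str | Path) -> dict[str, Path]:
    """Write the three cohort CSVs; returns {'patients': path, ...}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    patient_rows = []
    for p in sorted(cohort.patients, key=lambda p: p.patient_id):
        patient_rows.append(
            {
                "patient_id": p.patient_id,
                "subgroup": p.subgroup.value,
                "age_at_tx": p.age_at_tx,
                "sex": p.sex.value,
                "prior_rejection": p.prior_rejection,
                "dialysis_months_pre_tx": p.dialysis_months_pre_tx,
                "hla_ab_status": p.hla_ab_status.value,
                "dsa_mfi_t1": p.dsa_mfi_t1,
                "dsa_mfi_t2": p.dsa_mfi_t2,
                "pcr": p.pcr,
                "banff_g": p.banff_g,
                "banff_ptc": p.banff_ptc,
                "banff_cg": p.banff_cg,
                "banff_cv": p.banff_cv,
                "c4d_ptc": p.c4d_ptc,
                "c4d_glom": p.c4d_glom,
                "ifta_pct": p.ifta_pct,
                "tubulitis": p.tubulitis,
                "treatment": ";".join(sorted(t.value for t in p.treatment)),
                "graft_failed": p.graft_failed,
                "failure_month": p.failure_month,
            }
        )
    egfr_rows = [
        {
            "patient_id": s.patient_id,
            "month": o.month,
            "egfr": o.egfr,
            "creatinine": o.creatinine,
        }
        for s in sorted(cohort.egfr, key=lambda s: s.patient_id)
        for o in s.observations
    ]
    elispot_rows = []
    for s in sorted(
        cohort.elispot,
        key=lambda s: (s.patient_id, s.time_point.value, s.antigen_class.value),
    ):
        for cond, field in _CONDITION_FIELD.items():
            elispot_rows.append(
                {
                    "patient_id": s.patient_id,
                    "time_point": s.time_point.value,
                    "antigen_class": s.antigen_class.value,
                    "condition": cond.value,
                    "spots": getattr(s, field),
                    "background": s.background,
                    "viable": s.viable,
                }
            )

    paths = {
        "patients": outdir / "patients.csv",
        "egfr": outdir / "egfr.csv",
        "elispot": outdir / "elispot.csv",
    }
    pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS).to_csv(
        paths["patients"], index=False
    )
    pd.DataFrame(egfr_rows, columns=EGFR_COLUMNS).to_csv(paths["egfr"], index=False)
    pd.DataFrame(elispot_rows, columns=ELISPOT_COLUMNS).to_csv(
        paths["elispot"], index=False
    )
    return paths


def baseline_egfr(
    cohort: CohortTables, patient_id: str, t1_window: tuple[float, float] = (-1.0, 1.0)
) -> float | None:
    """Baseline eGFR: observation nearest month 0 at or before the t1 window end."""
    series = cohort.egfr_series(patient_id)
    if series is None:
        return None
    eligible = [o for o in series.observations if o.month <= t1_window[1]]
    if not eligible:
        return None
    return min(eligible, key=lambda o: abs(o.month)).egfr


def apply_cohort_filters(
    cohort: CohortTables,
    rules: Iterable[str],
    t1_window: tuple[float, float] = (-1.0, 1.0),
    creatinine_tolerance: float = 0.0,
) -> tuple[CohortTables, pd.DataFrame]:
    """Exclude patients per the named rules; returns (cohort, exclusion log).

    Each rule is a per-patient predicate evaluated on the input cohort, so
    filters commute and are idempotent.  The log has one row per
    (patient, rule) exclusion.
    """
    from .trajectory import reciprocal_creatinine_slope  # cycle avoidance

    rules = list(rules)
    for rule in rules:
        if rule not in FILTER_RULES:
            raise ConfigError(
                f"unknown filter rule {rule!r}; known: {', '.join(FILTER_RULES)}"
            )

    log_rows = []
    excluded: set[str] = set()
    for p in cohort.patients:
        series = cohort.egfr_series(p.patient_id)
        for rule in rules:
            hit = False
            if rule == "egfr_lt_20_at_biopsy":
                base = baseline_egfr(cohort, p.patient_id, t1_window)
                hit = base is not None and base < 20.0
            elif rule == "missing_followup":
                hit = series is None or not any(
                    o.month > t1_window[1] for o in series.observations
                )
            elif rule == "tubulitis":
                hit = p.tubulitis
            elif rule == "nonprogressive_creatinine":
                if series is None:
                    hit = True
                else:
                    try:
                        _, deteriorating = reciprocal_creatinine_slope(
                            series, tolerance=creatinine_tolerance
                        )
                        hit = not deteriorating
                    except Exception:
                        hit = True  # too few creatinine points to show progression
            if hit:
                excluded.add(p.patient_id)
                log_rows.append({"patient_id": p.patient_id, "rule": rule})

    kept = tuple(p for p in cohort.patients if p.patient_id not in excluded)
    filtered = CohortTables(
        patients=kept,
        egfr=tuple(s for s in cohort.egfr if s.patient_id not in excluded),
        elispot=tuple(s for s in cohort.elispot if s.patient_id not in excluded),
    )
    log = pd.DataFrame(log_rows, columns=["patient_id", "rule"])
    for pid in sorted(excluded):
        logger.info("excluded patient %s", pid)
    return filtered, log
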