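"""eGFR change, subgroup dichotomization, and longitudinal transitions.

ΔeGFR is the raw difference between the last eGFR inside the follow-up
window (36 months by default, matching a 3-year outcome horizon) and the
baseline value at the first ELISPOT.  Patients are split into
"deteriorating" vs "stable" around the median ΔeGFR *within* their biopsy
subgroup — a patient exactly at the median counts as deteriorating — and
the labels are then pooled.  Transition labels summarise how a patient's
phenotype call changed between the two assay time points.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .errors import InsufficientDataError, MissingFollowUpError
from .records import (
    AntigenClass,
    CoarseCategory,
    EgfrSeries,
    PhenotypeCall,
    Subgroup,
)

DEFAULT_WINDOW_MONTHS = 36.0
DEFAULT_T1_WINDOW = (-1.0, 1.0)


@dataclass(frozen=True)
class DeltaEgfr:
    patient_id: str
    egfr_baseline: float
    egfr_final: float
    delta: float
    window_months: float


class Outcome(str, enum.Enum):
    STABLE = "stable"
    DETERIORATING = "deteriorating"


@dataclass(frozen=True)
class OutcomeLabel:
    patient_id: str
    label: Outcome
    subgroup_median: float


class DsrChange(str, enum.Enum):
    MAINTAIN_NDSR = "maintain_NDSR"
    MAINTAIN_DSR = "maintain_DSR"
    TO_DSR = "to_DSR"
    TO_NDSR = "to_NDSR"


class BdepChange(str, enum.Enum):
    MAINTAIN_NO_B = "maintain_noB"
    MAINTAIN_B = "maintain_B"
    TO_B = "to_B"
    TO_NO_B = "to_noB"


class TransitionGroup(str, enum.Enum):
    """Three-way grouping of phenotype trajectories by the t2 state.

    A patient ends up "regulated" at t2 if the t2 call shows no response,
    regulation without B-dependence, or a regulated B-dependent response;
    the two regulated groups are split by whether the t1 call was already
    B-dependent.  An unregulated B-dependent t2 call forms its own group
    irrespective of the t1 pattern.
    """

    REGULATED_AT_T2_FROM_NOB = "regulated_at_t2_from_noB"
    REGULATED_AT_T2_FROM_B = "regulated_at_t2_from_B"
    UNREGULATED_AT_T2 = "unregulated_at_t2"
    NA = "NA"


@dataclass(frozen=True)
class TransitionLabel:
    patient_id: str
    antigen_class: AntigenClass
    dsr_change: Optional[DsrChange]
    bdep_change: Optional[BdepChange]
    group: TransitionGroup


def compute_delta_egfr(
    series: EgfrSeries,
    window_months: float = DEFAULT_WINDOW_MONTHS,
    t1_window: tuple[float, float] = DEFAULT_T1_WINDOW,
) -> DeltaEgfr:
    """ΔeGFR = last in-window eGFR minus baseline.

    Baseline is the observation nearest month 0 within the first-ELISPOT
    window; final is the last observation with month ≤ ``window_months``
    (for grafts failing earlier this is the last measured value — no
    imputation below it).
    """
    eligible = [o for o in series.observations if o.month <= t1_window[1]]
    if not eligible:
        raise MissingFollowUpError(
            f"patient {series.patient_id}: no baseline observation"
        )
    baseline = min(eligible, key=lambda o: abs(o.month))
    later = [
        o
        for o in series.observations
        if o.month > t1_window[1] and o.month <= window_months
    ]
    if not later:
        raise MissingFollowUpError(
            f"patient {series.patient_id}: no post-baseline observation"
        )
    final = later[-1]
    return DeltaEgfr(
        patient_id=series.patient_id,
        egfr_baseline=baseline.egfr,
        egfr_final=final.egfr,
        delta=final.egfr - baseline.egfr,
        window_months=window_months,
    )


def dichotomize(
    deltas: Iterable[DeltaEgfr], subgroups: Mapping[str, Subgroup]
) -> list[OutcomeLabel]:
    """Stable/deteriorating labels around the within-subgroup median ΔeGFR.

    The median uses the mean-of-central-pair convention for even n; a delta
    below **or equal to** the subgroup median is deteriorating.  Labels are
    pooled across subgroups afterwards.
    """
    deltas = list(deltas)
    by_subgroup: dict[Subgroup, list[DeltaEgfr]] = {}
    for d in deltas:
        if d.patient_id not in subgroups:
            raise KeyError(f"no subgroup for patient {d.patient_id}")
        by_subgroup.setdefault(subgroups[d.patient_id], []).append(d)
    for sg, members in by_subgroup.items():
        if not members:
            raise ValueError(f"empty subgroup {sg}")

    medians = {
        sg: float(np.median([d.delta for d in members]))
        for sg, members in by_subgroup.items()
    }
    labels = []
    for d in deltas:
        med = medians[subgroups[d.patient_id]]
        labels.append(
            OutcomeLabel(
                patient_id=d.patient_id,
                label=Outcome.DETERIORATING if d.delta <= med else Outcome.STABLE,
                subgroup_median=med,
            )
        )
    return labels


def label_transition(
    call_t1: PhenotypeCall, call_t2: PhenotypeCall
) -> TransitionLabel:
    """Transition summary for one patient/antigen across the two time points."""
    if call_t1.patient_id != call_t2.patient_id:
        raise ValueError("calls belong to different patients")
    if call_t1.antigen_class != call_t2.antigen_class:
        raise ValueError("calls belong to different antigen classes")
    if not (call_t1.interpretable and call_t2.interpretable):
        return TransitionLabel(
            patient_id=call_t1.patient_id,
            antigen_class=call_t1.antigen_class,
            dsr_change=None,
            bdep_change=None,
            group=TransitionGroup.NA,
        )

    dsr_change = {
        (False, False): DsrChange.MAINTAIN_NDSR,
        (True, True): DsrChange.MAINTAIN_DSR,
        (False, True): DsrChange.TO_DSR,
        (True, False): DsrChange.TO_NDSR,
    }[(call_t1.dsr, call_t2.dsr)]
    bdep_change = {
        (False, False): BdepChange.MAINTAIN_NO_B,
        (True, True): BdepChange.MAINTAIN_B,
        (False, True): BdepChange.TO_B,
        (True, False): BdepChange.TO_NO_B,
    }[(call_t1.b_dependent, call_t2.b_dependent)]

    if call_t2.coarse_category is CoarseCategory.BDEP_UNREGULATED:
        group = TransitionGroup.UNREGULATED_AT_T2
    elif call_t1.b_dependent:
        group = TransitionGroup.REGULATED_AT_T2_FROM_B
    else:
        group = TransitionGroup.REGULATED_AT_T2_FROM_NOB

    return TransitionLabel(
        patient_id=call_t1.patient_id,
        antigen_class=call_t1.antigen_class,
        dsr_change=dsr_change,
        bdep_change=bdep_change,
        group=group,
    )


def reciprocal_creatinine_slope(
    series: EgfrSeries, tolerance: float = 0.0
) -> tuple[float, bool]:
    """OLS slope of 1/creatinine against month, plus a deterioration flag.

    A falling 1/creatinine (slope < −tolerance) marks progressive loss of
    filtration — the classic "creeping creatinine" screen read off
    reciprocal creatinine plots.  Requires ≥3 creatinine observations.
    """
    points = [
        (o.month, 1.0 / o.creatinine)
        for o in series.observations
        if o.creatinine is not None and o.creatinine > 0
    ]
    if len(points) < 3:
        raise InsufficientDataError(
            f"patient {series.patient_id}: need >=3 creatinine observations"
        )
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    slope = float(np.polyfit(x, y, 1)[0])
    # guard against float noise in the exactly-flat case
    eps = 1e-9 * float(np.abs(y).mean())
    return slope, slope < -(tolerance + eps)
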