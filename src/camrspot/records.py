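"""Domain records for a chronic antibody-mediated rejection (CAMR) cohort.

The cohort model mirrors how such studies are actually tabulated: a patient
table of covariates (biopsy subgroup, Banff scores, C4d, proteinuria, DSA),
a longitudinal eGFR/creatinine table, and an IFN-γ ELISPOT table with one
spot count per depletion condition.  ELISPOT wells are loaded with 4×10⁵
CD8-depleted responder PBMC, so all spot counts are per 4×10⁵ PBMC.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class Subgroup(str, enum.Enum):
    """Biopsy context: surveillance protocol biopsy vs biopsy for cause."""

    PROTCL = "PROTCL"
    BFC = "BFC"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class HlaAbStatus(str, enum.Enum):
    NONE = "none"
    NON_DSA = "non-DSA"
    DSA = "DSA"


class Treatment(str, enum.Enum):
    TAC_SWITCH = "tac_switch"
    MMF = "mmf"
    RITUXIMAB = "rituximab"
    STEROIDS = "steroids"
    NONE = "none"


class TimePoint(str, enum.Enum):
    """t1 = within a month of index biopsy; t2 = 9–12 months later."""

    T1 = "t1"
    T2 = "t2"


class AntigenClass(str, enum.Enum):
    DONOR = "donor"
    CMV = "CMV"
    VZV = "VZV"
    CONTROL = "control"


class Condition(str, enum.Enum):
    """The four depletion conditions of the assay, in canonical order.

    CD8 cells are always depleted (the readout is indirect CD4 reactivity);
    CD19 (B cell) and CD25 (activated/regulatory T cell) depletions are
    crossed to reveal B-dependence and regulation.
    """

    CD8DEP = "cd8dep"
    CD8CD19DEP = "cd8cd19dep"
    CD8CD25DEP = "cd8cd25dep"
    CD8CD25CD19DEP = "cd8cd25cd19dep"


#: Canonical condition order used for positivity quadruples.
CONDITION_ORDER = (
    Condition.CD8DEP,
    Condition.CD8CD19DEP,
    Condition.CD8CD25DEP,
    Condition.CD8CD25CD19DEP,
)


class FinePattern(str, enum.Enum):
    """The nine observed positivity patterns, plus OTHER for the rest.

    Names encode what the pattern shows: DSR status and whether B-cell
    depletion lowers (Bdep) or raises (Breg) the response, with or without
    CD25+ cells present.
    """

    NO_RESPONSE = "no_response"
    BREG_CD25_PRESENT = "breg_cd25_present"
    BREG_PRESENT_AND_ABSENT = "breg_present_and_absent"
    BREG_CD25_ABSENT = "breg_cd25_absent"
    BREG_PRESENT_BDEP_ABSENT = "breg_present_bdep_absent"
    BDEP_CD25_ABSENT = "bdep_cd25_absent"
    BDEP_PRESENT_BREG_ABSENT = "bdep_present_breg_absent"
    BDEP_PRESENT_AND_ABSENT = "bdep_present_and_absent"
    BDEP_CD25_PRESENT = "bdep_cd25_present"
    OTHER = "other"


class CoarseCategory(str, enum.Enum):
    """Four-way functional grouping of the fine patterns."""

    NO_RESPONSE_NO_REG = "no_response_no_reg"
    REGULATED_NO_BDEP = "regulated_no_bdep"
    BDEP_REGULATED = "bdep_regulated"
    BDEP_UNREGULATED = "bdep_unregulated"


class DepletionFlag(str, enum.Enum):
    """Relative-change (≥20 %) depletion-effect flags."""

    BDEP_CD25_PRESENT = "Bdep_cd25present"
    BREG_CD25_PRESENT = "Breg_cd25present"
    BDEP_CD25_ABSENT = "Bdep_cd25absent"
    BREG_CD25_ABSENT = "Breg_cd25absent"
    TREG = "Treg"


class PatientRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    subgroup: Subgroup
    age_at_tx: float
    sex: Sex
    prior_rejection: bool
    dialysis_months_pre_tx: float
    hla_ab_status: HlaAbStatus
    dsa_mfi_t1: Optional[float] = None
    dsa_mfi_t2: Optional[float] = None
    pcr: Optional[float] = None  # protein-to-creatinine ratio, mg/mmol
    banff_g: int
    banff_ptc: int
    banff_cg: int
    banff_cv: int
    c4d_ptc: bool
    c4d_glom: bool
    ifta_pct: float
    tubulitis: bool
    treatment: frozenset[Treatment] = frozenset()
    graft_failed: bool = False
    failure_month: Optional[float] = None

    @field_validator("dsa_mfi_t1", "dsa_mfi_t2")
    @classmethod
    def _mfi_nonnegative(cls, v):
        if v is not None and v < 0:
            raise ValueError("DSA MFI must be >= 0 when present")
        return v

    @field_validator("ifta_pct")
    @classmethod
    def _ifta_range(cls, v):
        if not 0 <= v <= 100:
            raise ValueError("ifta_pct must lie in [0, 100]")
        return v

    @field_validator("banff_g", "banff_ptc", "banff_cg", "banff_cv")
    @classmethod
    def _banff_ordinal(cls, v):
        if v not in (0, 1, 2, 3):
            raise ValueError("Banff scores are ordinal 0-3")
        return v

    @model_validator(mode="after")
    def _failure_consistency(self):
        if self.graft_failed != (self.failure_month is not None):
            raise ValueError("failure_month present iff graft_failed")
        return self


class EgfrObservation(BaseModel):
    model_config = ConfigDict(frozen=True)

    month: float  # relative to index biopsy
    egfr: float  # ml/min per 1.73 m^2
    creatinine: Optional[float] = None  # µmol/l

    @field_validator("egfr")
    @classmethod
    def _egfr_positive(cls, v):
        if not v > 0:
            raise ValueError("egfr must be > 0")
        return v


class EgfrSeries(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    observations: tuple[EgfrObservation, ...]

    @model_validator(mode="after")
    def _validate_series(self):
        months = [o.month for o in self.observations]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError("observation months must be strictly increasing")
        if not any(m <= 1.0 for m in months):
            raise ValueError("need at least one observation at or before month 1")
        return self


class ElispotSample(BaseModel):
    """Spot counts for one patient × time point × antigen class.

    One count per depletion condition, plus the no-antigen background well.
    Nonviable samples (failed thaw etc.) may carry missing counts.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    time_point: TimePoint
    antigen_class: AntigenClass
    c_cd8dep: Optional[int] = None
    c_cd8cd19dep: Optional[int] = None
    c_cd8cd25dep: Optional[int] = None
    c_cd8cd25cd19dep: Optional[int] = None
    background: Optional[int] = None
    viable: bool = True

    @field_validator(
        "c_cd8dep", "c_cd8cd19dep", "c_cd8cd25dep", "c_cd8cd25cd19dep", "background"
    )
    @classmethod
    def _counts_nonnegative(cls, v):
        if v is not None and v < 0:
            raise ValueError("spot counts must be nonnegative")
        return v

    @model_validator(mode="after")
    def _viable_counts(self):
        if self.viable and any(
            c is None
            for c in (
                self.c_cd8dep,
                self.c_cd8cd19dep,
                self.c_cd8cd25dep,
                self.c_cd8cd25cd19dep,
                self.background,
            )
        ):
            raise ValueError("viable sample must carry all counts")
        return self

    def counts(self) -> tuple[Optional[int], ...]:
        """Counts in canonical condition order."""
        return (
            self.c_cd8dep,
            self.c_cd8cd19dep,
            self.c_cd8cd25dep,
            self.c_cd8cd25cd19dep,
        )


class PositivityRule(BaseModel):
    """Per-well positivity: count ≥ min_spots and ≥ multiplier × background."""

    model_config = ConfigDict(frozen=True)

    min_spots: int = 10
    background_multiplier: float = 2.0

    @field_validator("min_spots")
    @classmethod
    def _min_spots_nonneg(cls, v):
        if v < 0:
            raise ValueError("min_spots must be >= 0")
        return v

    @field_validator("background_multiplier")
    @classmethod
    def _mult_ge_one(cls, v):
        if v < 1:
            raise ValueError("background_multiplier must be >= 1")
        return v


class PhenotypeCall(BaseModel):
    """Classification of one interpretable ELISPOT sample."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    time_point: TimePoint
    antigen_class: AntigenClass
    interpretable: bool
    dsr: Optional[bool] = None
    positivity: Optional[tuple[bool, bool, bool, bool]] = None
    flags: frozenset[DepletionFlag] = frozenset()
    fine_pattern: Optional[FinePattern] = None
    coarse_category: Optional[CoarseCategory] = None
    b_dependent: Optional[bool] = None

    @model_validator(mode="after")
    def _consistency(self):
        if self.interpretable:
            if self.positivity is None or self.fine_pattern is None:
                raise ValueError("interpretable call must carry pattern fields")
            if self.dsr != self.positivity[0]:
                raise ValueError("dsr must equal CD8-depleted positivity")
            expected_b = self.coarse_category in (
                CoarseCategory.BDEP_REGULATED,
                CoarseCategory.BDEP_UNREGULATED,
            )
            if self.b_dependent != expected_b:
                raise ValueError("b_dependent inconsistent with coarse category")
        return self


class CohortTables(BaseModel):
    """A validated cohort: patients + eGFR series + ELISPOT samples."""

    model_config = ConfigDict(frozen=True)

    patients: tuple[PatientRecord, ...]
    egfr: tuple[EgfrSeries, ...]
    elispot: tuple[ElispotSample, ...]

    @model_validator(mode="after")
    def _referential_integrity(self):
        ids = {p.patient_id for p in self.patients}
        if len(ids) != len(self.patients):
            raise ValueError("duplicate patient_id in patient table")
        for series in self.egfr:
            if series.patient_id not in ids:
                raise ValueError(f"egfr series for unknown patient {series.patient_id}")
        seen = set()
        for s in self.elispot:
            if s.patient_id not in ids:
                raise ValueError(f"elispot sample for unknown patient {s.patient_id}")
            key = (s.patient_id, s.time_point, s.antigen_class)
            if key in seen:
                raise ValueError(f"duplicate elispot sample {key}")
            seen.add(key)
        return self

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def egfr_series(self, patient_id: str) -> Optional[EgfrSeries]:
        for s in self.egfr:
            if s.patient_id == patient_id:
                return s
        return None

    def elispot_sample(
        self, patient_id: str, time_point: TimePoint, antigen_class: AntigenClass
    ) -> Optional[ElispotSample]:
        for s in self.elispot:
            if (
                s.patient_id == patient_id
                and s.time_point == time_point
                and s.antigen_class == antigen_class
            ):
                return s
        return None

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def is_missing(value) -> bool:
    """True for None, NaN, or empty-string cells."""
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False
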